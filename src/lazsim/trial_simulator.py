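"""Synthetic two-arm growth-trial generator.

Simulates randomized controlled trials whose endpoint is length-for-age
z-score (LAZ) measured at birth and at 6, 12, 18 and 24 months.  A child's
LAZ trajectory is a single draw from a multivariate normal distribution
whose per-visit means, SDs and inter-visit correlations are taken from a
South-Asian birth-cohort population; the defaults are exposed as
:func:`PopulationParams.maled_bangladesh`.

The intervention is an additive, cumulative mean shift (+0.05 LAZ per six
months by default) applied to treated children only.  Arm allocation is
Bernoulli per child, either fair (balanced scenario) or with success
probability a linear function of baseline LAZ (imbalanced scenario), which
engineers a systematic baseline difference between arms of roughly 0.12 LAZ.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PopulationParams",
    "EffectProfile",
    "AllocationRule",
    "TrialData",
    "build_covariance",
    "draw_growth_curves",
    "allocate_arms",
    "apply_intervention",
    "simulate_trial",
    "corr_from_lower_triangle",
    "DEFAULT_TIMEPOINTS",
    "PROB_CLAMP",
]

DEFAULT_TIMEPOINTS: tuple[float, ...] = (0.0, 6.0, 12.0, 18.0, 24.0)

# Birth-cohort LAZ moments (means, SDs, correlations between visit ages).
_MALED_MU = (-1.10, -1.19, -1.66, -1.95, -2.03)
_MALED_SIGMA = (1.03, 0.97, 0.93, 0.93, 0.94)
_MALED_CORR_LOWER = (
    (0.61,),
    (0.47, 0.87),
    (0.46, 0.80, 0.90),
    (0.44, 0.76, 0.88, 0.95),
)

_DEFAULT_DELTA = (0.0, 0.05, 0.10, 0.15, 0.20)

# Allocation probabilities are clipped to this range before the Bernoulli
# draw.  With baseline LAZ ~ N(-1.10, 1.03) and slope -0.03 the linear
# probability leaves (0.01, 0.99) only beyond ~15 SDs, so the clamp is a
# numerical safety net that never binds in practice.
PROB_CLAMP: tuple[float, float] = (0.01, 0.99)


def corr_from_lower_triangle(lower: Sequence[Sequence[float]]) -> np.ndarray:
    """Assemble a full correlation matrix from its strict lower triangle.

    ``lower[i]`` holds the correlations of timepoint ``i + 1`` with all
    earlier timepoints, mirroring how such tables are usually printed.
    """
    t = len(lower) + 1
    corr = np.eye(t)
    for i, row in enumerate(lower, start=1):
        if len(row) != i:
            raise ValueError(
                f"lower-triangle row {i - 1} must have {i} entries, got {len(row)}"
            )
        corr[i, :i] = row
        corr[:i, i] = row
    return corr


@dataclass(frozen=True, eq=False)
class PopulationParams:
    """Per-timepoint LAZ moments and the inter-timepoint correlation matrix.

    Parameters
    ----------
    timepoints : visit ages in months, strictly increasing, baseline first.
    mu : mean LAZ at each timepoint (z-score units).
    sigma : SD of LAZ at each timepoint (z-score units), all positive.
    corr : symmetric correlation matrix with unit diagonal.

    Positive semi-definiteness of ``corr`` is checked when the sampling
    covariance is assembled (:func:`build_covariance`), not at construction.
    """

    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    mu: tuple[float, ...] = _MALED_MU
    sigma: tuple[float, ...] = _MALED_SIGMA
    corr: np.ndarray = field(default_factory=lambda: corr_from_lower_triangle(_MALED_CORR_LOWER))

    def __post_init__(self) -> None:
        object.__setattr__(self, "timepoints", tuple(float(t) for t in self.timepoints))
        object.__setattr__(self, "mu", tuple(float(m) for m in self.mu))
        object.__setattr__(self, "sigma", tuple(float(s) for s in self.sigma))
        corr = np.array(self.corr, dtype=float)
        object.__setattr__(self, "corr", corr)

        t = len(self.timepoints)
        if not (len(self.mu) == len(self.sigma) == t) or corr.shape != (t, t):
            raise ValueError(
                "timepoints, mu, sigma and corr must share one dimension; got "
                f"{t}, {len(self.mu)}, {len(self.sigma)}, {corr.shape}"
            )
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if any(s <= 0 for s in self.sigma):
            raise ValueError("all sigma must be positive")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have a unit diagonal")
        if np.any(np.abs(corr) > 1 + 1e-12):
            raise ValueError("correlation entries must lie in [-1, 1]")

    @classmethod
    def maled_bangladesh(cls) -> "PopulationParams":
        """The default birth-cohort parameterization (MAL-ED Bangladesh site)."""
        return cls()

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints)

    def index_of(self, timepoint: float) -> int:
        """Column index of a visit age, raising for unknown ages."""
        try:
            return self.timepoints.index(float(timepoint))
        except ValueError:
            raise ValueError(
                f"unknown timepoint {timepoint}; known: {self.timepoints}"
            ) from None

    def corr_lower_triangle(self) -> list[list[float]]:
        return [list(self.corr[i, :i]) for i in range(1, self.n_timepoints)]

    def to_config(self) -> dict:
        return {
            "timepoints": list(self.timepoints),
            "mu": list(self.mu),
            "sigma": list(self.sigma),
            "corr_lower_triangle": self.corr_lower_triangle(),
        }

    @classmethod
    def from_config(cls, block: dict) -> "PopulationParams":
        return cls(
            timepoints=tuple(block["timepoints"]),
            mu=tuple(block["mu"]),
            sigma=tuple(block["sigma"]),
            corr=corr_from_lower_triangle(block["corr_lower_triangle"]),
        )


@dataclass(frozen=True)
class EffectProfile:
    """Cumulative additive intervention effect on LAZ per timepoint.

    The baseline entry must be exactly zero: randomization happens at birth,
    so nothing can have acted on the baseline measurement.
    """

    delta: tuple[float, ...] = _DEFAULT_DELTA

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta", tuple(float(d) for d in self.delta))
        if not self.delta:
            raise ValueError("effect profile cannot be empty")
        if self.delta[0] != 0.0:
            raise ValueError(
                f"intervention effect at baseline must be 0, got {self.delta[0]}"
            )

    @classmethod
    def default(cls) -> "EffectProfile":
        """+0.05 LAZ per six months, cumulating to +0.20 at 24 months."""
        return cls()

    @classmethod
    def null(cls, n_timepoints: int = 5) -> "EffectProfile":
        return cls(delta=(0.0,) * n_timepoints)

    def at(self, params: PopulationParams, timepoint: float) -> float:
        return self.delta[params.index_of(timepoint)]

    def to_config(self) -> dict:
        return {"delta": list(self.delta)}

    @classmethod
    def from_config(cls, block: dict) -> "EffectProfile":
        return cls(delta=tuple(block["delta"]))


@dataclass(frozen=True)
class AllocationRule:
    """Bernoulli arm-allocation rule.

    Each child is assigned to the intervention arm with probability
    ``intercept + slope * baseline_laz``, clipped to ``PROB_CLAMP``.  The
    balanced rule is the fair coin (intercept 0.5, slope 0); the default
    imbalanced rule, 0.47 - 0.03 * LAZ0, preferentially allocates shorter
    children to the intervention arm.
    """

    kind: str = "balanced"
    intercept: float = 0.5
    slope: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("balanced", "imbalanced"):
            raise ValueError(f"kind must be 'balanced' or 'imbalanced', got {self.kind!r}")
        if self.kind == "balanced" and (self.intercept != 0.5 or self.slope != 0.0):
            raise ValueError("a balanced rule requires intercept 0.5 and slope 0")

    @classmethod
    def balanced(cls) -> "AllocationRule":
        return cls(kind="balanced", intercept=0.5, slope=0.0)

    @classmethod
    def imbalanced(cls, intercept: float = 0.47, slope: float = -0.03) -> "AllocationRule":
        return cls(kind="imbalanced", intercept=intercept, slope=slope)

    @classmethod
    def imbalanced_reversed(cls) -> "AllocationRule":
        """Sign-flipped slope: the baseline imbalance favours the intervention arm."""
        return cls(kind="imbalanced", intercept=0.47, slope=0.03)

    def probability(self, baseline_laz) -> np.ndarray:
        """Allocation probability for each child, clipped to ``PROB_CLAMP``."""
        z = np.asarray(baseline_laz, dtype=float)
        return np.clip(self.intercept + self.slope * z, *PROB_CLAMP)

    def to_config(self) -> dict:
        return {"kind": self.kind, "intercept": self.intercept, "slope": self.slope}

    @classmethod
    def from_config(cls, block: dict) -> "AllocationRule":
        return cls(
            kind=block["kind"],
            intercept=float(block.get("intercept", 0.5)),
            slope=float(block.get("slope", 0.0)),
        )


@dataclass(frozen=True, eq=False)
class TrialData:
    """One simulated trial: the LAZ matrix, the arm vector and provenance.

    ``laz`` has one row per child and one column per timepoint; ``arm`` is
    0 for control and 1 for intervention; ``seed_record`` stores whatever
    seed object produced the trial so it can be recreated in isolation.
    """

    laz: np.ndarray
    arm: np.ndarray
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    seed_record: object = None

    def __post_init__(self) -> None:
        laz = np.asarray(self.laz, dtype=float)
        arm = np.asarray(self.arm)
        object.__setattr__(self, "laz", laz)
        object.__setattr__(self, "arm", arm)
        object.__setattr__(self, "timepoints", tuple(float(t) for t in self.timepoints))
        if laz.ndim != 2 or laz.shape[1] != len(self.timepoints):
            raise ValueError("laz must be (n_children, n_timepoints)")
        if arm.shape != (laz.shape[0],):
            raise ValueError("arm must have one entry per child")
        if not np.isin(arm, (0, 1)).all():
            raise ValueError("arm must contain only 0/1")
        if not np.isfinite(laz).all():
            raise ValueError("laz has missing or non-finite values")

    @property
    def n(self) -> int:
        return self.laz.shape[0]

    @property
    def baseline(self) -> np.ndarray:
        return self.laz[:, 0]

    def index_of(self, timepoint: float) -> int:
        try:
            return self.timepoints.index(float(timepoint))
        except ValueError:
            raise ValueError(
                f"unknown timepoint {timepoint}; known: {self.timepoints}"
            ) from None

    def outcome(self, timepoint: float) -> np.ndarray:
        return self.laz[:, self.index_of(timepoint)]

    def to_dataframe(self) -> pd.DataFrame:
        cols = {f"laz_{int(t)}": self.laz[:, j] for j, t in enumerate(self.timepoints)}
        return pd.DataFrame(
            {"child_id": np.arange(self.n), "arm": self.arm.astype(int), **cols}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialData":
        df = pd.read_csv(path)
        laz_cols = [c for c in df.columns if c.startswith("laz_")]
        timepoints = tuple(float(c.split("_", 1)[1]) for c in laz_cols)
        return cls(
            laz=df[laz_cols].to_numpy(dtype=float),
            arm=df["arm"].to_numpy(dtype=int),
            timepoints=timepoints,
        )


def build_covariance(params: PopulationParams) -> np.ndarray:
    """Sampling covariance Sigma[s, t] = corr[s, t] * sigma[s] * sigma[t].

    Raises
    ------
    ValueError
        If the assembled matrix is not positive semi-definite; the message
        carries the offending eigenvalue, signalling an inconsistent
        user-supplied correlation matrix.
    """
    sigma = np.asarray(params.sigma)
    cov = params.corr * np.outer(sigma, sigma)
    eigenvalues = np.linalg.eigvalsh(cov)
    tol = -1e-10 * max(1.0, float(eigenvalues[-1]))
    if eigenvalues[0] < tol:
        raise ValueError(
            "correlation matrix is not positive semi-definite: "
            f"covariance eigenvalue {eigenvalues[0]:.6g} < 0"
        )
    return cov


def cholesky_factor(cov: np.ndarray) -> np.ndarray:
    """A factor F with F @ F.T == cov; falls back to an eigenfactor when
    the covariance is singular (e.g. perfectly correlated timepoints)."""
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cov)
        return v * np.sqrt(np.clip(w, 0.0, None))


def draw_growth_curves(
    params: PopulationParams,
    n: int,
    rng: np.random.Generator,
    *,
    factor: np.ndarray | None = None,
) -> np.ndarray:
    """Draw ``n`` i.i.d. LAZ trajectories from the population distribution.

    ``factor`` may carry a pre-computed ``cholesky_factor(build_covariance(params))``
    to amortize the decomposition across many replicate draws.
    """
    if not isinstance(n, numbers.Integral) or n < 2:
        raise ValueError(f"need at least 2 children to later fit regressions, got n={n}")
    if factor is None:
        factor = cholesky_factor(build_covariance(params))
    z = rng.standard_normal((int(n), params.n_timepoints))
    return np.asarray(params.mu) + z @ factor.T


def allocate_arms(
    baseline_laz, rule: AllocationRule, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli arm assignment from the (possibly baseline-dependent) rule."""
    z = np.asarray(baseline_laz, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("baseline LAZ must be finite")
    p = rule.probability(z)
    return (rng.random(z.shape[0]) < p).astype(np.int64)


def apply_intervention(
    curves: np.ndarray, arm, effect: EffectProfile
) -> np.ndarray:
    """Add the cumulative effect profile to intervention-arm rows.

    Control rows (and the baseline column, whose effect is pinned at zero)
    are returned bit-identical to the input.
    """
    curves = np.asarray(curves, dtype=float)
    arm = np.asarray(arm)
    if curves.shape[0] != arm.shape[0]:
        raise ValueError("curves and arm must have one row/entry per child")
    delta = np.asarray(effect.delta)
    if delta.shape[0] != curves.shape[1]:
        raise ValueError("effect profile length must match the number of timepoints")
    if delta[0] != 0.0:
        raise ValueError("intervention effect at baseline must be 0")
    out = curves.copy()
    out[arm == 1] += delta
    return out


def simulate_trial(
    params: PopulationParams,
    effect: EffectProfile,
    rule: AllocationRule,
    n: int,
    seed,
    *,
    factor: np.ndarray | None = None,
) -> TrialData:
    """Simulate one complete trial: draw curves, allocate arms on the
    pre-effect baseline, then inject the intervention effect.

    ``seed`` may be anything ``numpy.random.default_rng`` accepts (an int or
    a ``SeedSequence``); the same seed reproduces the trial bit for bit.
    """
    rng = np.random.default_rng(seed)
    curves = draw_growth_curves(params, n, rng, factor=factor)
    arm = allocate_arms(curves[:, 0], rule, rng)
    laz = apply_intervention(curves, arm, effect)
    return TrialData(laz=laz, arm=arm, timepoints=params.timepoints, seed_record=seed)
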