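"""The five baseline-handling regression strategies.

Every strategy is an ordinary least-squares fit; they differ only in the
response and in whether baseline LAZ enters as a covariate:

====================  =========================================================
FINAL                 LAZ_i ~ arm
ADJUST (ANCOVA)       LAZ_i ~ arm + LAZ_0
DELTA (change score)  (LAZ_i - LAZ_0) ~ arm
DELTA_ADJUST          (LAZ_i - LAZ_0) ~ arm + LAZ_0
RESIDUALS             two steps: LAZ_i ~ LAZ_0, then its residuals ~ arm
====================  =========================================================

The intervention effect is the coefficient on the arm indicator.  ADJUST and
DELTA_ADJUST are exact reparameterizations of each other (subtract LAZ_0 from
both sides); RESIDUALS coincides with them whenever arm and baseline are
sample-orthogonal, and agrees to reporting precision in randomized trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import stdtr, stdtrit

from .trial_simulator import TrialData

__all__ = ["Method", "METHODS", "LinearFit", "FitResult", "least_squares", "estimate_effect"]


class Method(str, Enum):
    """The closed enumeration of baseline-handling strategies."""

    FINAL = "FINAL"
    ADJUST = "ADJUST"
    DELTA = "DELTA"
    DELTA_ADJUST = "DELTA+ADJUST"
    RESIDUALS = "RESIDUALS"

    @classmethod
    def parse(cls, label: str) -> "Method":
        key = str(label).strip().upper().replace("+", "_").replace("-", "_")
        try:
            return cls[key]
        except KeyError:
            raise ValueError(
                f"unknown method {label!r}; choose from {[m.name for m in cls]}"
            ) from None

    def __str__(self) -> str:  # CSV/CLI display uses the printed label
        return self.value


METHODS: tuple[Method, ...] = tuple(Method)


@dataclass(frozen=True, eq=False)
class LinearFit:
    """Coefficient record of one OLS fit (intercept always first)."""

    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    residuals: np.ndarray
    df_resid: int
    sigma2: float

    def __getitem__(self, name: str) -> float:
        return float(self.coef[self.names.index(name)])


def least_squares(response, predictors, names=None) -> LinearFit:
    """OLS with an intercept, via a QR factorization.

    Standard errors use the unbiased residual-variance estimator and
    two-sided p-values come from the t distribution on ``n - k - 1`` degrees
    of freedom (k predictors plus an intercept).

    Raises
    ------
    ValueError
        For missing values, too few observations, or a rank-deficient design
        (the error names the collinear column).
    """
    y = np.asarray(response, dtype=float)
    cols = [np.asarray(p, dtype=float) for p in predictors]
    if names is None:
        names = tuple(f"x{i + 1}" for i in range(len(cols)))
    names = ("intercept",) + tuple(names)
    n = y.shape[0]
    if any(c.shape != (n,) for c in cols):
        raise ValueError("all predictors must be vectors of the response's length")
    X = np.column_stack([np.ones(n)] + cols)
    if not (np.isfinite(y).all() and np.isfinite(X).all()):
        raise ValueError("least_squares requires finite, non-missing values")
    k = X.shape[1]
    if n <= k:
        raise ValueError(f"need more observations ({n}) than coefficients ({k})")

    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = max(n, k) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    if (diag <= tol).any():
        bad = names[int(np.argmin(diag))]
        raise ValueError(f"design matrix is rank-deficient: column {bad!r} is collinear")
    coef = solve_triangular(r, q.T @ y)
    residuals = y - X @ coef
    df = n - k
    sigma2 = float(residuals @ residuals) / df
    r_inv = solve_triangular(r, np.eye(k))
    se = np.sqrt(sigma2 * np.einsum("ij,ij->i", r_inv, r_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stats = np.where(se > 0, coef / np.where(se > 0, se, 1.0), np.inf * np.sign(coef))
        t_stats = np.where((se == 0) & (coef == 0), 0.0, t_stats)
    p = 2.0 * stdtr(df, -np.abs(t_stats))
    return LinearFit(
        names=names,
        coef=coef,
        se=se,
        p_values=p,
        residuals=residuals,
        df_resid=df,
        sigma2=sigma2,
    )


@dataclass(frozen=True, eq=False)
class FitResult:
    """One strategy's intervention-effect estimate for one trial/timepoint."""

    method: Method
    timepoint: float
    beta1: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    coefficients: LinearFit | None = None
    stage1: LinearFit | None = None

    def to_row(self) -> dict:
        return {
            "timepoint": self.timepoint,
            "method": str(self.method),
            "beta1": self.beta1,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_used": self.n_used,
        }


@lru_cache(maxsize=None)
def _t_critical(df: int, alpha: float) -> float:
    return float(stdtrit(df, 1.0 - alpha / 2.0))


def estimate_effect(
    trial: TrialData,
    timepoint: float,
    method: Method | str,
    alpha: float = 0.05,
    *,
    keep_fit: bool = True,
) -> FitResult:
    """Estimate the intervention effect at a post-baseline timepoint.

    Returns the arm coefficient with its Wald ``t``-based confidence interval
    ``beta1 +/- t_{df, 1-alpha/2} * se`` and two-sided p-value.
    """
    method = Method.parse(method) if not isinstance(method, Method) else method
    j = trial.index_of(timepoint)
    if j == 0:
        raise ValueError("the baseline timepoint is not a post-baseline endpoint")
    arm = trial.arm
    if arm.min() == arm.max():
        raise ValueError("trial has a single arm; the intervention effect is undefined")
    x = arm.astype(float)
    y = trial.laz[:, j]
    b = trial.baseline
    stage1 = None
    if method is Method.FINAL:
        fit = least_squares(y, [x], ("arm",))
    elif method is Method.ADJUST:
        fit = least_squares(y, [x, b], ("arm", "baseline"))
    elif method is Method.DELTA:
        fit = least_squares(y - b, [x], ("arm",))
    elif method is Method.DELTA_ADJUST:
        fit = least_squares(y - b, [x, b], ("arm", "baseline"))
    elif method is Method.RESIDUALS:
        # Two-step procedure as literally written: the second-stage SE takes
        # no degrees-of-freedom correction for the estimated first stage.
        stage1 = least_squares(y, [b], ("baseline",))
        fit = least_squares(stage1.residuals, [x], ("arm",))
    else:  # pragma: no cover - closed enumeration
        raise ValueError(f"unknown method {method!r}")

    i = fit.names.index("arm")
    beta1 = float(fit.coef[i])
    se = float(fit.se[i])
    half_width = _t_critical(fit.df_resid, alpha) * se
    return FitResult(
        method=method,
        timepoint=float(timepoint),
        beta1=beta1,
        se=se,
        ci_low=beta1 - half_width,
        ci_high=beta1 + half_width,
        p_value=float(fit.p_values[i]),
        n_used=trial.n,
        coefficients=fit if keep_fit else None,
        stage1=stage1 if keep_fit else None,
    )
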