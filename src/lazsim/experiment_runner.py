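"""Orchestration of the full simulation study.

A study is a grid of (scenario, enrolment) cells.  Within each cell the
runner simulates ``n_replicates`` trials, applies every requested strategy
at every requested post-baseline timepoint to the SAME trials (pairing the
methods replicate by replicate), and collapses the fits into operating
characteristics with analytic companion columns.

Randomness contract: one master seed per experiment; the trial for replicate
r of cell (scenario, n) is generated from
``SeedSequence(master_seed, spawn_key=(scenario_code, n, r))``, so every
single trial can be recreated in isolation and cell results do not depend on
execution order.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.isotonic import IsotonicRegression

from . import analytic_oracle
from .estimators import METHODS, Method, estimate_effect
from .evaluation import baseline_imbalance_test, summarize_replicates
from .trial_simulator import (
    AllocationRule,
    EffectProfile,
    PopulationParams,
    build_covariance,
    cholesky_factor,
    simulate_trial,
)

__all__ = [
    "SCENARIOS",
    "ExperimentConfig",
    "ResultsTable",
    "replicate_seed",
    "run_cell",
    "run_grid",
    "power_curves",
    "smallest_n_reaching",
    "find_sample_size_for_power",
    "imbalance_diagnostics",
    "write_results",
    "read_results",
    "rounded_view",
    "reproduce_table2",
]

SCENARIOS: dict[str, Callable[[], AllocationRule]] = {
    "balanced": AllocationRule.balanced,
    "imbalanced": AllocationRule.imbalanced,
    "imbalanced_reversed": AllocationRule.imbalanced_reversed,
}
_SCENARIO_CODES = {"balanced": 1, "imbalanced": 2, "imbalanced_reversed": 3}

_POSTBASELINE = (6.0, 12.0, 18.0, 24.0)


@dataclass(frozen=True)
class ExperimentConfig:
    """Full specification of a simulation experiment."""

    scenarios: tuple[str, ...] = ("balanced", "imbalanced")
    n_grid: tuple[int, ...] = tuple(range(100, 1501, 100))
    n_replicates: int = 1000
    master_seed: int = 20230713
    alpha: float = 0.05
    timepoints: tuple[float, ...] = _POSTBASELINE
    methods: tuple[Method, ...] = METHODS
    power_target: float = 0.80
    n_search_max: int = 12_000
    n_search_step: int = 100

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenarios", tuple(self.scenarios))
        object.__setattr__(self, "n_grid", tuple(int(n) for n in self.n_grid))
        object.__setattr__(self, "timepoints", tuple(float(t) for t in self.timepoints))
        object.__setattr__(
            self, "methods", tuple(Method.parse(m) for m in self.methods)
        )
        unknown = set(self.scenarios) - set(SCENARIOS)
        if unknown:
            raise ValueError(f"unknown scenarios {sorted(unknown)}; known: {sorted(SCENARIOS)}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.power_target < 1.0:
            raise ValueError("power_target must lie in (0, 1)")
        if any(n < 2 for n in self.n_grid):
            raise ValueError("every grid enrolment must be >= 2")
        if any(n < 100 for n in self.n_grid):
            import warnings

            warnings.warn("grid enrolments below 100 give very noisy cells", stacklevel=2)

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["methods"] = [m.name for m in self.methods]
        for key in ("scenarios", "n_grid", "timepoints"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; known keys: {sorted(known)}"
            )
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class ResultsTable:
    """One row per (scenario, n, timepoint, method), plus run metadata."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def cell(self, scenario: str, n: int, timepoint: float, method: Method | str) -> pd.Series:
        m = str(Method.parse(method))
        t = self.table
        rows = t[
            (t.scenario == scenario)
            & (t.n == n)
            & (t.timepoint == float(timepoint))
            & (t.method == m)
        ]
        if len(rows) != 1:
            raise KeyError(f"expected one row for {(scenario, n, timepoint, m)}, found {len(rows)}")
        return rows.iloc[0]


def replicate_seed(
    master_seed: int, scenario: str, n: int, replicate: int
) -> np.random.SeedSequence:
    """Deterministic per-trial substream, keyed by cell identity (not loop order)."""
    return np.random.SeedSequence(
        int(master_seed), spawn_key=(_SCENARIO_CODES[scenario], int(n), int(replicate))
    )


def _log(log, msg: str) -> None:
    if log:
        print(msg, file=sys.stderr, flush=True)


def run_cell(
    scenario: str,
    n: int,
    config: ExperimentConfig,
    params: PopulationParams | None = None,
    effect: EffectProfile | None = None,
    *,
    factor: np.ndarray | None = None,
    methods: Sequence[Method] | None = None,
    timepoints: Sequence[float] | None = None,
):
    """Simulate one (scenario, n) cell and fit all method/timepoint pairs.

    Returns ``(fits, imbalance)`` where ``fits[(method, timepoint)]`` is the
    list of per-replicate FitResults (paired across methods: every method saw
    the same trials) and ``imbalance`` is the list of per-trial
    baseline-imbalance diagnostics.
    """
    params = params or PopulationParams.maled_bangladesh()
    effect = effect if effect is not None else EffectProfile.default()
    rule = SCENARIOS[scenario]()
    methods = tuple(methods if methods is not None else config.methods)
    timepoints = tuple(timepoints if timepoints is not None else config.timepoints)
    if factor is None:
        factor = cholesky_factor(build_covariance(params))

    fits = {(m, t): [] for m in methods for t in timepoints}
    imbalance = []
    for r in range(config.n_replicates):
        seed = replicate_seed(config.master_seed, scenario, n, r)
        trial = simulate_trial(params, effect, rule, n, seed, factor=factor)
        imbalance.append(baseline_imbalance_test(trial, config.alpha))
        for m in methods:
            for t in timepoints:
                fits[(m, t)].append(
                    estimate_effect(trial, t, m, config.alpha, keep_fit=False)
                )
    return fits, imbalance


def _oracle_columns(
    scenario: str,
    n: int,
    timepoint: float,
    method: Method,
    params: PopulationParams,
    effect: EffectProfile,
) -> dict:
    rule = SCENARIOS[scenario]()
    delta0 = analytic_oracle.expected_baseline_imbalance(params, rule)
    return {
        "oracle_baseline_imbalance": delta0,
        "oracle_bias": analytic_oracle.expected_bias(method, timepoint, params, delta0),
        "oracle_variance_factor": analytic_oracle.variance_factor(method, timepoint, params),
        "oracle_power": analytic_oracle.approximate_power(
            method, timepoint, n, params, effect
        ),
    }


def run_grid(
    config: ExperimentConfig,
    params: PopulationParams | None = None,
    effect: EffectProfile | None = None,
    *,
    log: bool = False,
) -> ResultsTable:
    """Run the full scenario x enrolment grid and summarize every cell."""
    params = params or PopulationParams.maled_bangladesh()
    effect = effect if effect is not None else EffectProfile.default()
    factor = cholesky_factor(build_covariance(params))

    rows = []
    for scenario in config.scenarios:
        for n in config.n_grid:
            t0 = time.perf_counter()
            fits, imbalance = run_cell(
                scenario, n, config, params, effect, factor=factor
            )
            prop_sig = float(np.mean([i.significant for i in imbalance]))
            mean_diff = float(np.mean([i.mean_difference for i in imbalance]))
            for m in config.methods:
                for t in config.timepoints:
                    summary = summarize_replicates(
                        fits[(m, t)],
                        true_effect=effect.at(params, t),
                        alpha=config.alpha,
                        scenario=scenario,
                        n=n,
                        prop_significant_imbalance=prop_sig,
                        mean_baseline_difference=mean_diff,
                    )
                    rows.append(
                        {**summary.to_row(), **_oracle_columns(scenario, n, t, m, params, effect)}
                    )
            _log(
                log,
                f"[lazsim] {scenario} n={n}: {config.n_replicates} replicates in "
                f"{time.perf_counter() - t0:.1f}s",
            )
    table = pd.DataFrame(rows)
    metadata = {
        "master_seed": config.master_seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "package_version": _package_version(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    return ResultsTable(table=table, metadata=metadata)


def power_curves(
    config: ExperimentConfig,
    scenario: str,
    methods: Sequence[Method | str],
    timepoint: float,
    params: PopulationParams | None = None,
    effect: EffectProfile | None = None,
    *,
    n_values: Sequence[int] | None = None,
    stop_when_reached: int = 0,
    log: bool = False,
) -> pd.DataFrame:
    """Simulated power for several methods at one timepoint, over a grid of n.

    All methods are evaluated on the same trials per n.  If
    ``stop_when_reached`` is positive, the walk up the grid stops early once
    every method's raw power has been at or above ``config.power_target`` for
    that many consecutive grid points.
    """
    params = params or PopulationParams.maled_bangladesh()
    effect = effect if effect is not None else EffectProfile.default()
    methods = tuple(Method.parse(m) for m in methods)
    if n_values is None:
        n_values = range(
            config.n_search_step, config.n_search_max + 1, config.n_search_step
        )
    factor = cholesky_factor(build_covariance(params))
    rule = SCENARIOS[scenario]()

    records = []
    streak = 0
    for n in n_values:
        rejected = {m: 0 for m in methods}
        for r in range(config.n_replicates):
            seed = replicate_seed(config.master_seed, scenario, n, r)
            trial = simulate_trial(params, effect, rule, n, seed, factor=factor)
            for m in methods:
                fit = estimate_effect(trial, timepoint, m, config.alpha, keep_fit=False)
                rejected[m] += fit.p_value < config.alpha
        powers = {str(m): rejected[m] / config.n_replicates for m in methods}
        records.append({"n": int(n), **powers})
        _log(log, f"[lazsim] power {scenario} {timepoint}m n={n}: {powers}")
        if stop_when_reached > 0:
            streak = streak + 1 if all(p >= config.power_target for p in powers.values()) else 0
            if streak >= stop_when_reached:
                break
    return pd.DataFrame(records)


def smallest_n_reaching(
    n_values: Sequence[int], powers: Sequence[float], target: float
) -> int | None:
    """Smallest grid n whose isotonically smoothed power reaches ``target``.

    Isotonic (monotone non-decreasing) regression removes Monte Carlo
    non-monotonicity before thresholding; returns None when the target is
    never reached on the grid.
    """
    n_arr = np.asarray(list(n_values), dtype=float)
    p_arr = np.asarray(list(powers), dtype=float)
    smoothed = IsotonicRegression(increasing=True).fit_transform(n_arr, p_arr)
    hits = np.nonzero(smoothed >= target - 1e-12)[0]
    return int(n_arr[hits[0]]) if hits.size else None


def find_sample_size_for_power(
    config: ExperimentConfig,
    scenario: str,
    method: Method | str,
    timepoint: float,
    params: PopulationParams | None = None,
    effect: EffectProfile | None = None,
    *,
    stop_when_reached: int = 3,
    log: bool = False,
) -> int | None:
    """Smallest enrolment (to the nearest grid step) reaching the power target.

    Returns None (the "not reached" sentinel) if the cap ``n_search_max`` is
    hit first.  Requires a nonzero simulated effect at the timepoint.
    """
    params = params or PopulationParams.maled_bangladesh()
    effect = effect if effect is not None else EffectProfile.default()
    if effect.at(params, timepoint) == 0.0:
        raise ValueError(
            "the simulated effect is zero at this timepoint; power never exceeds alpha"
        )
    method = Method.parse(method)
    curve = power_curves(
        config,
        scenario,
        (method,),
        timepoint,
        params,
        effect,
        stop_when_reached=stop_when_reached,
        log=log,
    )
    return smallest_n_reaching(curve["n"], curve[str(method)], config.power_target)


def imbalance_diagnostics(
    scenario: str,
    n: int,
    n_replicates: int,
    master_seed: int,
    params: PopulationParams | None = None,
    effect: EffectProfile | None = None,
    alpha: float = 0.05,
) -> dict:
    """Baseline-imbalance summary over replicates for one (scenario, n) cell.

    Returns the mean arm difference in baseline LAZ (intervention minus
    control, averaged over trials), the fraction of trials whose imbalance is
    statistically significant, and the closed-form expectation for reference.
    """
    params = params or PopulationParams.maled_bangladesh()
    effect = effect if effect is not None else EffectProfile.default()
    rule = SCENARIOS[scenario]()
    factor = cholesky_factor(build_covariance(params))
    config = ExperimentConfig(
        scenarios=(scenario,), n_grid=(n,), n_replicates=n_replicates,
        master_seed=master_seed, alpha=alpha,
    )
    diffs, sig = [], []
    for r in range(n_replicates):
        seed = replicate_seed(master_seed, scenario, n, r)
        trial = simulate_trial(params, effect, rule, n, seed, factor=factor)
        res = baseline_imbalance_test(trial, alpha)
        diffs.append(res.mean_difference)
        sig.append(res.significant)
    return {
        "scenario": scenario,
        "n": n,
        "n_replicates": n_replicates,
        "mean_baseline_difference": float(np.mean(diffs)),
        "prop_significant_imbalance": float(np.mean(sig)),
        "oracle_baseline_imbalance": analytic_oracle.expected_baseline_imbalance(
            params, rule
        ),
    }


_COLUMN_ORDER = [
    "scenario", "n", "timepoint", "method", "true_effect", "median_estimate",
    "ui_low", "ui_high", "bias", "mean_se", "power", "coverage", "n_replicates",
    "prop_significant_imbalance", "mean_baseline_difference",
    "oracle_baseline_imbalance", "oracle_bias", "oracle_variance_factor",
    "oracle_power",
]


def write_results(results: ResultsTable, path) -> None:
    """CSV at full precision plus a sidecar ``<path>.meta.json`` metadata file."""
    path = Path(path)
    if results.table.empty:
        raise ValueError("refusing to write an empty results table")
    cols = [c for c in _COLUMN_ORDER if c in results.table.columns]
    cols += [c for c in results.table.columns if c not in cols]
    results.table[cols].to_csv(path, index=False)
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(results.metadata, fh, indent=2, sort_keys=True)


def read_results(path) -> ResultsTable:
    path = Path(path)
    table = pd.read_csv(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    metadata = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            metadata = json.load(fh)
    return ResultsTable(table=table, metadata=metadata)


def rounded_view(results: ResultsTable) -> pd.DataFrame:
    """Two-decimal presentation mirroring the published table layout:
    timepoint, model, simulated effect, median estimate, 95% UI, bias,
    mean SE, power, coverage."""
    t = results.table
    out = pd.DataFrame(
        {
            "timepoint": t["timepoint"].map(lambda v: f"{int(v)} m"),
            "model": t["method"],
            "simulated_effect": t["true_effect"].round(2),
            "median_estimate": t["median_estimate"].round(2),
            "ui_low": t["ui_low"].round(2),
            "ui_high": t["ui_high"].round(2),
            "bias": t["bias"].round(2),
            "mean_se": t["mean_se"].round(2),
            "power": t["power"].round(2),
            "coverage": t["coverage"].round(2),
        }
    )
    # round() leaves negative zeros behind (-0.001 -> -0.0); normalize them
    num = out.select_dtypes("number").columns
    out[num] = out[num] + 0.0
    return out


def reproduce_table2(
    n: int = 1000,
    n_replicates: int = 1000,
    master_seed: int = 20230713,
    *,
    log: bool = False,
) -> ResultsTable:
    """One-shot reproduction of the imbalanced-scenario operating
    characteristics at n = 1000 (all five methods, all four endpoints)."""
    config = ExperimentConfig(
        scenarios=("imbalanced",),
        n_grid=(n,),
        n_replicates=n_replicates,
        master_seed=master_seed,
    )
    return run_grid(config, log=log)


def _package_version() -> str:
    from . import __version__

    return __version__
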