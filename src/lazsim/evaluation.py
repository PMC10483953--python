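"""Operating characteristics of an estimator over Monte Carlo replicates.

Summaries follow the reporting conventions of simulation studies of trial
estimators: the median effect estimate with a 95% uncertainty interval (the
2.5th/97.5th percentiles of the replicate estimates), bias relative to the
simulated truth, the mean standard error, power (fraction of two-sided
p < alpha) and coverage (fraction of CIs containing the truth).  A separate
diagnostic tests each trial for a statistically significant baseline
imbalance by regressing baseline LAZ on the arm indicator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .estimators import FitResult, Method, least_squares
from .trial_simulator import TrialData

__all__ = ["ScenarioSummary", "ImbalanceResult", "summarize_replicates", "baseline_imbalance_test"]


@dataclass(frozen=True)
class ScenarioSummary:
    """Operating characteristics of one (method, timepoint, scenario, n) cell."""

    scenario: str
    n: int
    timepoint: float
    method: Method
    true_effect: float
    median_estimate: float
    ui_low: float
    ui_high: float
    bias: float
    mean_se: float
    power: float
    coverage: float
    n_replicates: int
    prop_significant_imbalance: float = float("nan")
    mean_baseline_difference: float = float("nan")

    def to_row(self) -> dict:
        return {
            "scenario": self.scenario,
            "n": self.n,
            "timepoint": self.timepoint,
            "method": str(self.method),
            "true_effect": self.true_effect,
            "median_estimate": self.median_estimate,
            "ui_low": self.ui_low,
            "ui_high": self.ui_high,
            "bias": self.bias,
            "mean_se": self.mean_se,
            "power": self.power,
            "coverage": self.coverage,
            "n_replicates": self.n_replicates,
            "prop_significant_imbalance": self.prop_significant_imbalance,
            "mean_baseline_difference": self.mean_baseline_difference,
        }


def summarize_replicates(
    fits: Sequence[FitResult],
    true_effect: float,
    alpha: float = 0.05,
    *,
    scenario: str = "",
    n: int | None = None,
    prop_significant_imbalance: float = float("nan"),
    mean_baseline_difference: float = float("nan"),
) -> ScenarioSummary:
    """Collapse one replicate set of fits into a ScenarioSummary.

    Percentiles use the standard linear-interpolation convention; bias is the
    MEDIAN estimate minus the truth.  ``fits`` must all come from the same
    method/timepoint cell.
    """
    if len(fits) == 0:
        raise ValueError("cannot summarize an empty replicate set")
    if len(fits) < 2:
        raise ValueError("need at least 2 replicates to form percentiles")
    methods = {f.method for f in fits}
    timepoints = {f.timepoint for f in fits}
    if len(methods) != 1 or len(timepoints) != 1:
        raise ValueError("all fits in a replicate set must share method and timepoint")

    betas = np.array([f.beta1 for f in fits])
    ses = np.array([f.se for f in fits])
    ps = np.array([f.p_value for f in fits])
    lo = np.array([f.ci_low for f in fits])
    hi = np.array([f.ci_high for f in fits])

    median = float(np.median(betas))
    ui_low, ui_high = np.percentile(betas, [2.5, 97.5])
    return ScenarioSummary(
        scenario=scenario,
        n=int(n if n is not None else fits[0].n_used),
        timepoint=float(fits[0].timepoint),
        method=fits[0].method,
        true_effect=float(true_effect),
        median_estimate=median,
        ui_low=float(ui_low),
        ui_high=float(ui_high),
        bias=median - float(true_effect),
        mean_se=float(ses.mean()),
        power=float((ps < alpha).mean()),
        coverage=float(((lo <= true_effect) & (true_effect <= hi)).mean()),
        n_replicates=len(fits),
        prop_significant_imbalance=prop_significant_imbalance,
        mean_baseline_difference=mean_baseline_difference,
    )


@dataclass(frozen=True)
class ImbalanceResult:
    """Baseline-imbalance diagnostic for a single trial."""

    mean_difference: float  # mean baseline LAZ, intervention minus control
    p_value: float
    significant: bool


def baseline_imbalance_test(trial: TrialData, alpha: float = 0.05) -> ImbalanceResult:
    """OLS of baseline LAZ on the arm indicator.

    The slope is the arm difference in mean baseline LAZ; the flag marks a
    two-sided p below ``alpha``.  A zero-variance baseline (no information)
    is reported as p = 1, never significant.
    """
    arm = trial.arm
    if arm.min() == arm.max():
        raise ValueError("baseline imbalance is undefined for a single-arm trial")
    b = trial.baseline
    fit = least_squares(b, [arm.astype(float)], ("arm",))
    slope = fit["arm"]
    if fit.sigma2 == 0.0:
        return ImbalanceResult(mean_difference=slope, p_value=1.0, significant=False)
    p = float(fit.p_values[fit.names.index("arm")])
    return ImbalanceResult(mean_difference=slope, p_value=p, significant=p < alpha)
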