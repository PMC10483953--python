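"""Closed-form expectations used to validate the Monte Carlo engine.

These are first-order population calculations, not the implementation under
test: the simulator plus the OLS strategies are the ground truth, and these
formulas provide an independent check on the engine's bias, imbalance and
variance behaviour.

Notation: for endpoint timepoint i, ``beta_slope(i) = rho_{0i} * sigma_i /
sigma_0`` is the population regression slope of the endpoint on baseline.
Under a linear allocation probability p(z) = a + b*z applied to a normal
baseline, the induced arm difference in mean baseline LAZ (delta0) has an
exact conditional-expectation form, and to first order in delta0 the
strategies' biases are

* FINAL:        beta_slope(i) * delta0
* DELTA:        (beta_slope(i) - 1) * delta0
* ADJUST family: 0   (the baseline coefficient is estimated, absorbing delta0)

RESIDUALS carries a second-order term of order delta0^2 / sigma_0^2 (and
delta_i * delta0 / sigma_0^2) that vanishes at reporting precision; it is
declared zero here.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .estimators import Method
from .trial_simulator import AllocationRule, EffectProfile, PopulationParams

__all__ = [
    "baseline_outcome_slope",
    "expected_baseline_imbalance",
    "expected_bias",
    "variance_factor",
    "approximate_power",
]

_ADJUSTED = (Method.ADJUST, Method.DELTA_ADJUST, Method.RESIDUALS)


def baseline_outcome_slope(params: PopulationParams, timepoint: float) -> float:
    """Population slope of endpoint LAZ on baseline LAZ: rho * sigma_i / sigma_0."""
    j = params.index_of(timepoint)
    return float(params.corr[0, j]) * params.sigma[j] / params.sigma[0]


def expected_baseline_imbalance(params: PopulationParams, rule: AllocationRule) -> float:
    """Expected mean(LAZ0 | arm=1) - mean(LAZ0 | arm=0) under linear selection.

    For Z ~ N(mu0, sigma0^2) and allocation probability p(Z) = a + b*Z,
    E[Z * p(Z)] = a*mu0 + b*(mu0^2 + sigma0^2) and the marginal allocation
    probability is pbar = a + b*mu0, so the arm-conditional means are
    E[Z*p]/pbar and E[Z*(1-p)]/(1-pbar).  The clamp on p is ignored (it
    binds only ~15 SDs out).
    """
    mu0, s0 = params.mu[0], params.sigma[0]
    a, b = rule.intercept, rule.slope
    pbar = a + b * mu0
    if not 0.0 < pbar < 1.0:
        raise ValueError(f"marginal allocation probability {pbar} outside (0, 1)")
    e_zp = a * mu0 + b * (mu0**2 + s0**2)
    return e_zp / pbar - (mu0 - e_zp) / (1.0 - pbar)


def expected_bias(
    method: Method | str,
    timepoint: float,
    params: PopulationParams,
    delta0: float,
) -> float:
    """First-order expected bias of the arm coefficient given a baseline
    imbalance ``delta0`` (intervention minus control mean baseline LAZ)."""
    method = Method.parse(method) if not isinstance(method, Method) else method
    slope = baseline_outcome_slope(params, timepoint)
    if method is Method.FINAL:
        return slope * delta0
    if method is Method.DELTA:
        return (slope - 1.0) * delta0
    if method in _ADJUSTED:
        return 0.0
    raise ValueError(f"unknown method {method!r}")  # pragma: no cover


def variance_factor(
    method: Method | str, timepoint: float, params: PopulationParams
) -> float:
    """Per-arm residual variance of the analyzed outcome.

    FINAL analyzes the raw endpoint (sigma_i^2); DELTA the change score
    (sigma_i^2 + sigma_0^2 - 2 rho sigma_i sigma_0); the adjusted family the
    baseline-conditional endpoint (sigma_i^2 (1 - rho^2)).  With a 50/50
    split, Var(beta1) ~= 4 * variance_factor / n.
    """
    method = Method.parse(method) if not isinstance(method, Method) else method
    j = params.index_of(timepoint)
    s_i, s_0 = params.sigma[j], params.sigma[0]
    rho = float(params.corr[0, j])
    if method is Method.FINAL:
        return s_i**2
    if method is Method.DELTA:
        return s_i**2 + s_0**2 - 2.0 * rho * s_i * s_0
    if method in _ADJUSTED:
        return s_i**2 * (1.0 - rho**2)
    raise ValueError(f"unknown method {method!r}")  # pragma: no cover


def approximate_power(
    method: Method | str,
    timepoint: float,
    n: int,
    params: PopulationParams,
    effect: EffectProfile,
    alpha: float = 0.05,
) -> float:
    """Normal-approximation power for an even two-arm split of ``n`` children:
    Phi(|delta_i| / sqrt(4 * variance_factor / n) - z_{1-alpha/2})."""
    delta = effect.at(params, timepoint)
    v = variance_factor(method, timepoint, params)
    se = np.sqrt(4.0 * v / n)
    z = norm.ppf(1.0 - alpha / 2.0)
    return float(norm.cdf(abs(delta) / se - z))
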