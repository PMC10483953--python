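"""Tests of the five baseline-handling strategies and the OLS core.

statsmodels serves as the independent oracle for coefficients, standard
errors and p-values; a hand-coded normal-equations solve checks the
strategies on a tiny fixed fixture.
"""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from lazsim import (
    AllocationRule,
    EffectProfile,
    Method,
    METHODS,
    PopulationParams,
    TrialData,
    estimate_effect,
    least_squares,
    simulate_trial,
)

# A fixed 8-child fixture: columns are LAZ at 0, 6, 12, 18, 24 months.
FIXTURE_LAZ = np.array(
    [
        [-0.52, -0.71, -1.10, -1.45, -1.52],
        [-1.80, -1.65, -2.02, -2.31, -2.40],
        [-1.05, -1.20, -1.55, -1.90, -2.01],
        [-0.10, -0.35, -0.90, -1.20, -1.33],
        [-2.40, -2.10, -2.60, -2.85, -2.95],
        [-1.33, -1.40, -1.72, -2.05, -2.10],
        [-0.75, -0.80, -1.30, -1.60, -1.70],
        [-1.62, -1.55, -1.95, -2.20, -2.33],
    ]
)
FIXTURE_ARM = np.array([0, 1, 0, 1, 1, 0, 1, 0])
FIXTURE = TrialData(laz=FIXTURE_LAZ, arm=FIXTURE_ARM)


def _normal_equations_beta(y, columns):
    """Brute-force OLS via the normal equations (independent of the package path)."""
    X = np.column_stack([np.ones(len(y))] + list(columns))
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestLeastSquares:
    def test_hand_computed_two_group_slope(self):
        fit = least_squares([1.0, 2.0, 3.0, 4.0], [[0.0, 0.0, 1.0, 1.0]], ("x",))
        assert fit["intercept"] == pytest.approx(1.5)
        assert fit["x"] == pytest.approx(2.0)

    def test_perfect_fit_has_zero_residuals(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = least_squares(x, [x], ("x",))
        assert fit["x"] == pytest.approx(1.0)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)

    def test_intercept_only_recovers_mean(self):
        y = np.array([2.0, 4.0, 9.0])
        fit = least_squares(y, [])
        assert fit["intercept"] == pytest.approx(y.mean())

    def test_collinear_column_named_in_error(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="twice_x"):
            least_squares(x, [x, 2 * x], ("x", "twice_x"))

    def test_matches_statsmodels(self, small_trial):
        y = small_trial.outcome(18)
        x = small_trial.arm.astype(float)
        b = small_trial.baseline
        fit = least_squares(y, [x, b], ("arm", "baseline"))
        ref = sm.OLS(y, sm.add_constant(np.column_stack([x, b]))).fit()
        np.testing.assert_allclose(fit.coef, ref.params, rtol=1e-10)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-10)
        np.testing.assert_allclose(fit.p_values, ref.pvalues, rtol=1e-8)
        assert fit.df_resid == ref.df_resid


class TestEstimateEffect:
    @pytest.mark.parametrize("method", METHODS, ids=lambda m: m.name)
    def test_fixture_matches_normal_equations(self, method):
        y = FIXTURE.outcome(24)
        x = FIXTURE_ARM.astype(float)
        b = FIXTURE.baseline
        if method is Method.FINAL:
            expected = _normal_equations_beta(y, [x])[1]
        elif method is Method.ADJUST:
            expected = _normal_equations_beta(y, [x, b])[1]
        elif method is Method.DELTA:
            expected = _normal_equations_beta(y - b, [x])[1]
        elif method is Method.DELTA_ADJUST:
            expected = _normal_equations_beta(y - b, [x, b])[1]
        else:  # RESIDUALS
            c0, c1 = _normal_equations_beta(y, [b])
            resid = y - c0 - c1 * b
            expected = _normal_equations_beta(resid, [x])[1]
        result = estimate_effect(FIXTURE, 24, method)
        assert result.beta1 == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("method", METHODS, ids=lambda m: m.name)
    def test_matches_statsmodels_pipeline(self, small_trial, method):
        y = small_trial.outcome(12)
        x = small_trial.arm.astype(float)
        b = small_trial.baseline
        if method is Method.FINAL:
            ref = sm.OLS(y, sm.add_constant(x)).fit()
        elif method is Method.ADJUST:
            ref = sm.OLS(y, sm.add_constant(np.column_stack([x, b]))).fit()
        elif method is Method.DELTA:
            ref = sm.OLS(y - b, sm.add_constant(x)).fit()
        elif method is Method.DELTA_ADJUST:
            ref = sm.OLS(y - b, sm.add_constant(np.column_stack([x, b]))).fit()
        else:
            stage1 = sm.OLS(y, sm.add_constant(b)).fit()
            ref = sm.OLS(stage1.resid, sm.add_constant(x)).fit()
        result = estimate_effect(small_trial, 12, method)
        idx = 1  # arm is always the first predictor after the intercept
        assert result.beta1 == pytest.approx(ref.params[idx], rel=1e-10)
        assert result.se == pytest.approx(ref.bse[idx], rel=1e-10)
        assert result.p_value == pytest.approx(ref.pvalues[idx], rel=1e-8)
        lo, hi = ref.conf_int()[idx]
        assert result.ci_low == pytest.approx(lo, rel=1e-8)
        assert result.ci_high == pytest.approx(hi, rel=1e-8)

    def test_adjust_and_delta_adjust_are_reparameterizations(self, params, effect):
        """Subtracting baseline from both sides leaves the arm coefficient and
        its SE untouched and shifts the baseline coefficient by exactly 1."""
        rule = AllocationRule.imbalanced()
        for seed in range(40):
            trial = simulate_trial(params, effect, rule, 150, seed=seed)
            for t in (6, 24):
                a = estimate_effect(trial, t, Method.ADJUST)
                d = estimate_effect(trial, t, Method.DELTA_ADJUST)
                assert d.beta1 == pytest.approx(a.beta1, rel=1e-10, abs=1e-12)
                assert d.se == pytest.approx(a.se, rel=1e-10)
                assert a.coefficients["baseline"] - d.coefficients["baseline"] == pytest.approx(
                    1.0, abs=1e-10
                )

    def test_final_is_difference_in_endpoint_means(self, small_trial):
        r = estimate_effect(small_trial, 24, Method.FINAL)
        y = small_trial.outcome(24)
        expected = y[small_trial.arm == 1].mean() - y[small_trial.arm == 0].mean()
        assert r.beta1 == pytest.approx(expected, rel=1e-12)

    def test_delta_is_difference_in_mean_change(self, small_trial):
        r = estimate_effect(small_trial, 18, Method.DELTA)
        change = small_trial.outcome(18) - small_trial.baseline
        expected = change[small_trial.arm == 1].mean() - change[small_trial.arm == 0].mean()
        assert r.beta1 == pytest.approx(expected, rel=1e-12)

    def test_residuals_equals_adjust_when_arm_baseline_orthogonal(self):
        """With the two arms mirrored over identical baseline values the
        arm/baseline sample covariance is exactly zero, where the two-step
        residuals estimator coincides with ANCOVA."""
        baseline = np.tile([-2.0, -1.5, -1.0, -0.5, 0.0], 2)
        arm = np.repeat([0, 1], 5)
        rng = np.random.default_rng(99)
        laz = np.column_stack([baseline] + [baseline * 0.5 + rng.normal(size=10) for _ in range(4)])
        trial = TrialData(laz=laz, arm=arm)
        res = estimate_effect(trial, 24, Method.RESIDUALS)
        adj = estimate_effect(trial, 24, Method.ADJUST)
        assert res.beta1 == pytest.approx(adj.beta1, abs=1e-10)

    def test_null_effect_estimates_center_on_zero(self, params):
        rule = AllocationRule.balanced()
        medians = {m: [] for m in METHODS}
        for seed in range(200):
            trial = simulate_trial(params, EffectProfile.null(), rule, 300, seed=900_000 + seed)
            for m in METHODS:
                medians[m].append(estimate_effect(trial, 24, m, keep_fit=False).beta1)
        for m, betas in medians.items():
            assert np.median(betas) == pytest.approx(0.0, abs=0.03)

    def test_single_arm_trial_rejected(self):
        trial = TrialData(laz=FIXTURE_LAZ, arm=np.zeros(8, dtype=int))
        with pytest.raises(ValueError, match="single arm"):
            estimate_effect(trial, 24, Method.FINAL)

    def test_baseline_timepoint_rejected(self, small_trial):
        with pytest.raises(ValueError, match="baseline"):
            estimate_effect(small_trial, 0, Method.FINAL)

    def test_ci_brackets_estimate_and_p_in_unit_interval(self, small_trial):
        for m in METHODS:
            r = estimate_effect(small_trial, 6, m)
            assert r.ci_low <= r.beta1 <= r.ci_high
            assert 0.0 <= r.p_value <= 1.0
            assert r.se > 0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**20), n=st.integers(10, 80))
    def test_algebraic_identities_hold_for_arbitrary_trials(self, seed, n):
        """For any trial: FINAL equals the raw endpoint mean difference,
        DELTA the mean-change difference, and ADJUST/DELTA+ADJUST coincide."""
        rng = np.random.default_rng(seed)
        laz = rng.normal(-1.5, 1.0, size=(n, 5))
        arm = np.zeros(n, dtype=int)
        arm[: n // 2] = 1
        rng.shuffle(arm)
        trial = TrialData(laz=laz, arm=arm)
        y, b = trial.outcome(24), trial.baseline
        final = estimate_effect(trial, 24, Method.FINAL, keep_fit=False)
        assert final.beta1 == pytest.approx(
            y[arm == 1].mean() - y[arm == 0].mean(), rel=1e-9, abs=1e-12
        )
        delta = estimate_effect(trial, 24, Method.DELTA, keep_fit=False)
        change = y - b
        assert delta.beta1 == pytest.approx(
            change[arm == 1].mean() - change[arm == 0].mean(), rel=1e-9, abs=1e-12
        )
        adj = estimate_effect(trial, 24, Method.ADJUST, keep_fit=False)
        dadj = estimate_effect(trial, 24, Method.DELTA_ADJUST, keep_fit=False)
        assert dadj.beta1 == pytest.approx(adj.beta1, rel=1e-10, abs=1e-12)
        assert dadj.se == pytest.approx(adj.se, rel=1e-10)
        for r in (final, delta, adj):
            assert r.ci_low <= r.beta1 <= r.ci_high
            assert 0.0 <= r.p_value <= 1.0

    def test_method_parsing(self):
        assert Method.parse("delta+adjust") is Method.DELTA_ADJUST
        assert Method.parse("FINAL") is Method.FINAL
        with pytest.raises(ValueError):
            Method.parse("ANCOVA-ish")
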