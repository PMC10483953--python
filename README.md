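# lazsim

Monte Carlo simulation lab for choosing how to handle **baseline
measurements** when analyzing two-arm randomized trials of child linear
growth, where the endpoint is length-for-age z-score (LAZ) measured at
birth and at 6, 12, 18 and 24 months.

## Who this is for

Trialists and biostatisticians writing the a-priori statistical analysis
plan of a growth trial face a concrete choice: compare only the endpoint
(FINAL), analyze the change from baseline (DELTA), or adjust for baseline
in the regression (ADJUST / ANCOVA, with its algebraic twins DELTA+ADJUST
and the two-step RESIDUALS method). The choice changes the sample size
needed, and — if randomization leaves the arms imbalanced at baseline —
whether the estimate is biased at all (Lord's paradox). `lazsim` quantifies
these trade-offs by simulation under a realistic LAZ data-generating model.

## The model

Each child's LAZ trajectory is a draw from a multivariate normal with
birth-cohort moments (means −1.10 … −2.03, SDs 1.03 … 0.94, baseline-to-
endpoint correlations falling from 0.61 at 6 m to 0.44 at 24 m). The
intervention adds a cumulative +0.05 LAZ per six months. Children are
allocated to arms by a fair coin (balanced scenario) or with probability
0.47 − 0.03·LAZ₀ (imbalanced scenario, which shifts the intervention arm
≈0.13 LAZ shorter at baseline). Each strategy estimates the intervention
effect β₁ at an endpoint LAZᵢ by OLS:

```
FINAL:         LAZ_i            = β0 + β1·x
ADJUST:        LAZ_i            = β0 + β1·x + β2·LAZ_0
DELTA:         LAZ_i − LAZ_0    = β0 + β1·x
DELTA+ADJUST:  LAZ_i − LAZ_0    = β0 + β1·x + β2·LAZ_0
RESIDUALS:     LAZ_i = β0 + β2·LAZ_0,  then  residuals = β3 + β1·x
```

Over replicate trials the package reports each strategy's median estimate
with a 95% uncertainty interval, bias, mean standard error, power,
coverage, and the enrolment needed for 80% power. See `docs/methods.md`
for the full model, assumptions and numerical choices.

## Worked example

Analyze one simulated imbalanced trial of 1000 children at the 24-month
endpoint (true effect +0.20 LAZ):

```python
import lazsim as lz

trial = lz.simulate_trial(
    lz.PopulationParams.maled_bangladesh(),
    lz.EffectProfile.default(),
    lz.AllocationRule.imbalanced(),
    n=1000, seed=42,
)
imb = lz.baseline_imbalance_test(trial)
print(f"baseline difference (arm1-arm0): {imb.mean_difference:+.3f} LAZ, p = {imb.p_value:.3f}")
for m in ("FINAL", "DELTA", "ADJUST"):
    r = lz.estimate_effect(trial, 24, m)
    print(f"{m:>6}: beta1 = {r.beta1:+.3f}  (95% CI {r.ci_low:+.3f} to {r.ci_high:+.3f}), p = {r.p_value:.4f}")
```

```
baseline difference (arm1-arm0): -0.125 LAZ, p = 0.055
 FINAL: beta1 = +0.067  (95% CI -0.052 to +0.186), p = 0.2697
 DELTA: beta1 = +0.192  (95% CI +0.062 to +0.322), p = 0.0037
ADJUST: beta1 = +0.120  (95% CI +0.013 to +0.226), p = 0.0280
```

The intervention arm happens to start 0.125 LAZ shorter — not even
statistically detectable in this trial — yet FINAL and DELTA already
disagree by 0.125 LAZ, straddling the covariate-adjusted estimate. One
trial is noisy; the systematic picture comes from 1000 replicates:

```python
results = lz.reproduce_table2(n_replicates=1000, master_seed=20230713)
print(lz.rounded_view(results))
```

selected rows (truth 0.05 at 6 m, 0.20 at 24 m):

```
timepoint   model   simulated_effect  median_estimate  bias  mean_se  power  coverage
6 m         FINAL   0.05              -0.03            -0.08  0.06    0.07   0.78
6 m         DELTA   0.05               0.11             0.06  0.06    0.47   0.83
6 m         ADJUST  0.05               0.05             0.00  0.05    0.18   0.94
24 m        FINAL   0.20               0.15            -0.05  0.06    0.70   0.86
24 m        DELTA   0.20               0.28             0.08  0.07    0.99   0.80
24 m        ADJUST  0.20               0.20             0.00  0.05    0.97   0.96
```

Under baseline imbalance, FINAL underestimates (at 6 m it lands on the
wrong side of the null), DELTA overestimates, and the adjusted family is
unbiased with nominal coverage and the smallest standard errors. In the
balanced scenario, reaching 80% power at the 18-month endpoint takes about
1200 children with FINAL and 1500 with DELTA, but only 900–1000 with the
adjusted methods (`lazsim samplesize --method ADJUST --timepoint 18`).

A command-line interface wraps the library: `lazsim run --config cfg.yaml
--out results.csv` (scenario grids), `lazsim samplesize`, `lazsim table2`
(the one-shot reproduction above) and `lazsim oracle` (closed-form
companion quantities).

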