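# Methods

## The question the simulations answer

A two-arm randomized trial measures a continuous growth outcome —
length-for-age z-score (LAZ) — at enrolment (birth) and again at follow-up
visits. The analyst must decide how the baseline measurement enters the
primary analysis. `lazsim` compares five ordinary-least-squares strategies
for estimating the intervention effect β₁ at a post-baseline endpoint LAZᵢ:

| label        | model                                   |
|--------------|-----------------------------------------|
| FINAL        | LAZᵢ = β₀ + β₁x                          |
| ADJUST       | LAZᵢ = β₀ + β₁x + β₂·LAZ₀                |
| DELTA        | LAZᵢ − LAZ₀ = β₀ + β₁x                   |
| DELTA+ADJUST | LAZᵢ − LAZ₀ = β₀ + β₁x + β₂·LAZ₀         |
| RESIDUALS    | LAZᵢ = β₀ + β₂·LAZ₀, then residuals = β₃ + β₁x |

where x is the arm indicator and LAZ₀ the baseline measurement. ADJUST and
DELTA+ADJUST are exact reparameterizations (subtract LAZ₀ from both sides);
RESIDUALS coincides with them exactly when arm and baseline are
sample-orthogonal and to reporting precision in randomized trials. DELTA is
ADJUST with the baseline coefficient pinned at 1; FINAL discards the
baseline entirely. When the arms differ at baseline, DELTA and FINAL
disagree systematically — the change-score / covariate-adjustment conflict
known as Lord's paradox.

## The data-generating model

Each child's LAZ trajectory over visit ages (0, 6, 12, 18, 24) months is one
draw from a multivariate normal with per-visit means
μ = (−1.10, −1.19, −1.66, −1.95, −2.03), SDs
σ = (1.03, 0.97, 0.93, 0.93, 0.94), and correlation matrix with lower
triangle (0.61; 0.47, 0.87; 0.46, 0.80, 0.90; 0.44, 0.76, 0.88, 0.95).
These moments describe a South-Asian birth cohort (the MAL-ED Bangladesh
site) and are treated as fixed simulation constants; the correlation
between baseline and endpoint falls from 0.61 at 6 months to 0.44 at
24 months, which is what drives the FINAL-vs-DELTA behaviour.

The intervention is an additive cumulative mean shift of +0.05 LAZ per six
months (0.05/0.10/0.15/0.20 at 6/12/18/24 months; 0.20 at 24 months is a
realistic effect size for nutrition/WASH efficacy trials), applied to
treated children after the correlated draw. There is no effect
heterogeneity and no effect on variance.

Arm allocation is Bernoulli per child:

* **balanced** — probability 0.5 for everyone;
* **imbalanced** — probability 0.47 − 0.03·LAZ₀, so shorter children are
  preferentially allocated to the intervention arm. For Z ~ N(μ₀, σ₀²) and
  p(Z) = a + b·Z, the induced arm difference in mean baseline LAZ has the
  exact form E[Z·p]/p̄ − E[Z·(1−p)]/(1−p̄) with p̄ = a + b·μ₀ and
  E[Z·p] = aμ₀ + b(μ₀² + σ₀²); at the defaults this evaluates to
  **−0.1273 LAZ** (intervention arm shorter).
* **imbalanced_reversed** — slope +0.03, flipping the direction of the
  imbalance relative to the effect.

Allocation probabilities are clipped to [0.01, 0.99] as a numerical guard;
the clip binds only ~15 SDs from the baseline mean. Allocation uses the
pre-effect baseline, which is identical to the observed baseline because the
effect at baseline is pinned at zero. Odd enrolments are split by the
Bernoulli draw itself (per-child randomization, no blocking).

What the generator does **not** emulate: dropout and missing visits,
anthropometric measurement error, non-normal LAZ distributions, cluster
randomization, effect heterogeneity. Passing tests therefore certify the
estimators' behaviour under clean multivariate-normal data with complete
follow-up, not their robustness to those real-data complications.

## Inference and operating characteristics

Every strategy is fitted by OLS (QR factorization); standard errors use the
unbiased residual-variance estimator and inference is t-based with
n − k − 1 degrees of freedom, Wald 95% CIs β₁ ± t·se. The two-step
RESIDUALS procedure uses the naive OLS standard error of the second stage,
with no degrees-of-freedom correction for the estimated first stage —
matching the procedure as practitioners run it.

Per (scenario, n, timepoint, method) cell, over replicates:

* **median estimate** and **95% UI** (2.5th/97.5th percentiles, linear
  interpolation);
* **bias** = median estimate − true effect (median by convention; the
  sampling distribution of β₁ is symmetric here, so mean-based closed forms
  are comparable);
* **mean SE**; **power** = fraction of two-sided p < α (α = 0.05, no
  directionality requirement); **coverage** = fraction of CIs containing
  the truth;
* the **baseline-imbalance diagnostic**: OLS of LAZ₀ on arm per trial, with
  the fraction of trials significant at α.

## Randomness and reproducibility

One master seed per experiment. The trial for replicate r of cell
(scenario, n) comes from `SeedSequence(master_seed, spawn_key=(scenario_code,
n, r))`, so any single trial is recreatable in isolation and cell results
are independent of execution order. All methods and timepoints are applied
to the *same* simulated trials (paired replicates), which makes
between-method comparisons exact per trial — e.g. β₁(DELTA+ADJUST) −
β₁(ADJUST) is identically zero throughout any run — and reduces the Monte
Carlo variance of power differences.

## Analytic oracle

`lazsim.analytic_oracle` provides first-order closed forms used only for
validation, never as the implementation: with β_slope(i) = ρ₀ᵢσᵢ/σ₀ and
baseline imbalance δ₀,

* expected bias: FINAL → β_slope·δ₀; DELTA → (β_slope − 1)·δ₀; the ANCOVA
  family → 0 (RESIDUALS carries a second-order term of order δ₀²/σ₀²,
  invisible at two decimals, declared zero);
* per-arm residual variance: FINAL σᵢ²; DELTA σᵢ² + σ₀² − 2ρσᵢσ₀; ANCOVA
  family σᵢ²(1 − ρ₀ᵢ²); with an even split Var(β₁) ≈ 4·V/n;
* normal-approximation power Φ(|δᵢ|/√(4V/n) − z₀.₉₇₅), which ignores the
  second tail (it returns 0.025, not 0.05, at the null) and any
  allocation-induced bias, so it is compared to simulation only in the
  balanced scenario.

At the defaults the 18-month variance factors are 0.865 (FINAL), 1.045
(DELTA) and 0.682 (ANCOVA family), implying FINAL and DELTA need ≈27% and
≈53% more children than ADJUST — the analytic shadow of the simulated
1200/1500 vs 900–1000 sample sizes.

## Sample-size search

Power is simulated on an enrolment grid (default step 100, cap 12,000,
1000 replicates per point), isotonic (monotone non-decreasing) regression
smooths the power-vs-n sequence, and the search returns the smallest grid n
whose smoothed power reaches the target (default 0.80), or a "not reached"
sentinel at the cap. Isotonic regression was chosen over display-oriented
scatterplot smoothers because it is deterministic, monotone and has an
unambiguous crossing. The walk up the grid stops once every requested
method's raw power has been at or above the target for three consecutive
grid points; the isotonic fit on the truncated sequence leaves the crossing
unchanged in practice because later points only pool upward.

## Numerical choices and degenerate inputs

* Rank-deficient designs raise with the name of the collinear column; a
  zero-variance baseline makes the imbalance diagnostic report p = 1 rather
  than dividing by zero; single-arm trials are rejected (the effect is
  undefined); fits require at least two more observations than coefficients.
* Covariance assembly re-checks positive semi-definiteness and reports the
  offending eigenvalue; a singular covariance (e.g. perfectly correlated
  visits) falls back from Cholesky to a clipped eigenfactorization.
* Percentiles use numpy's linear-interpolation convention; at 1000
  replicates the convention shifts UI bounds by < 0.001.
* Control-arm rows pass through the effect-injection step bit-identical.

## Problem sizes

The package's standard runs use 1000 replicates per cell — enough that the
binomial SE of a power estimate near 0.8 is ±0.013 and the SE of a median
estimate is ±0.002–0.004 — with enrolment grids of 100–1500 (scenario
tables) or 100–2000 (the 18-month sample-size search). The full
imbalanced-scenario table (20 cells × 1000 replicates of n = 1000) runs in
a few seconds on one core; the sample-size grid in well under a minute.

## Known limitations

* The oracle bias formulas are first-order in the baseline imbalance;
  simulation is the ground truth and the oracle a validation instrument.
* The normal-approximation power assumes an even split and no bias, so it
  is meaningful only under balanced allocation.
* Reproduction of the published imbalanced-scenario table is within Monte
  Carlo tolerance for 98 of 100 cell-metrics; the two exceptions (FINAL
  power at 18 and 24 months) are cells where the published power values are
  inconsistent with the published median and mean-SE columns of the same
  rows — the simulated values here agree with what those columns imply.
  Likewise the simulated fraction of detectably imbalanced n = 1000 trials
  is ≈50%, the exact test power at the slope-implied imbalance of 0.1273
  LAZ, slightly above a published ≈46% that corresponds to a 0.12 target
  imbalance.
* Mixed-effects models pooling multiple post-randomization endpoints,
  robust/sandwich errors and nonparametric tests are out of scope.
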