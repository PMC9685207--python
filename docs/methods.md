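# Methods

## Growth model

Tumor volumes are modeled on the natural-log scale, where exponential
growth is linear. For mouse *i* with treatment indicator *Tᵢ* ∈ {0, 1} and
measurement day *d*:

    log V_id = (β_int + γ·Tᵢ + b0ᵢ) + (β_day + β_effect·Tᵢ + b1ᵢ)·d + ε_id

with mouse-level random effects (b0ᵢ, b1ᵢ) ~ N₂(0, Ψ) and residuals
ε_id ~ N(0, σ²) independent across records. Mice are independent; there are
no cage/batch effects, no dropout, and no intra-mouse serial correlation
beyond the random line. With one mouse per arm the random effects are
confounded with the fixed effects and the model reduces to ordinary linear
regression on intercept + day + treatment (+ day×treatment).

Parameters, units and defaults (cohort medians from NSCLC PDX efficacy
experiments; quartiles define the named effect/variation categories):

| parameter | meaning | unit | default |
|---|---|---|---|
| β_int | log baseline volume | log mm³ | 5.135 |
| β_day | control log-growth rate | 1/day | 0.076 |
| β_effect | treated − control growth rate | 1/day | −0.02 (small −0.010, large −0.044) |
| γ | treatment effect on baseline | — | 0 |
| σ | residual SD | log mm³ | 0.155 |
| τ₀ | random-intercept SD | log mm³ | 0.28 |
| τ₁ | random-slope SD | 1/day | 0.009 (small 0.005, large 0.013) |
| τ₀₁ | intercept–slope association | — | 0.034 (as correlation) |

**τ₀₁ interpretation.** The value 0.034 cannot be a covariance — it exceeds
τ₀·τ₁ = 0.00252, which would make Ψ indefinite — so the package interprets
it as the intercept–slope *correlation*, the only internally consistent
reading. It is configurable as a covariance (with positive-semidefiniteness
validation). The choice affects only simulated trajectories: the
slope-difference power below involves neither τ₀ nor τ₀₁, and a simulation
test confirms power is invariant to τ₀.

**Schedules.** Twice-weekly measurement uses the within-week day offsets
{0, 4} tiled at 7-day intervals (the canonical 4-week schedule is
0, 4, 7, 11, 14, 18, 21, 25). Three-times-weekly uses {0, 2, 4}, the
Mon/Wed/Fri analogue of the same pattern; no published day list exists for
this frequency, so the offsets are configurable
(`make_schedule(..., offsets=...)`). The choice moves Sxx and hence the
three-times-weekly power cells by a little (about 0.01–0.03).

## Analytic power

For a balanced design where every mouse is measured on the same days with
day sum-of-squares Sxx = Σ(d − d̄)², the per-mouse OLS slope is normal
around its arm's mean growth rate with variance

    v = τ₁² + σ²/Sxx

The treated-minus-control difference of group mean slopes has SE
√(2v/n) for n mice per arm, giving two-sided power at level α:

    power = Φ(|β_effect|/SE − z_{1−α/2}) + Φ(−|β_effect|/SE − z_{1−α/2})

The far-tail term is negligible except near the null, where it makes
power(β_effect = 0) = α exact. Sample-size inversion starts from
n₀ = ⌈2(z_{1−α/2} + z_{target})²·v / β_effect²⌉ and refines by integer
search against the full expression, so the returned n is the minimal
integer achieving the target (the far-tail term can shift the boundary by
one).

## Monte-Carlo power and test choices

`simulate_power` repeats simulate → fit → test and reports the rejection
fraction with its binomial standard error. The test applied per replicate
is where the statistics require care; three facts, each verified
empirically in the test suite, drove the design:

1. **The 1×1×1 OLS t-test cannot see τ₁.** With one mouse per arm the
   mouse's random slope is confounded with its arm's growth rate, so the
   OLS standard error contains only σ²/Sxx. When τ₁ > 0 the test is badly
   anticonservative for the population-level null (measured type-I ≈ 0.19
   at nominal .05 under the default parameters) and its power bears no
   relation to the formula above. A 1×1×1 design can only be interpreted
   when the variance components are known from prior replicated data —
   that is the premise of the whole screening layout — so for n = 1 the
   power engine defaults to a z-test of the observed slope difference
   against the *known* variance 2(τ₁² + σ²/Sxx). This test is exact, its
   simulated power converges to the analytic formula, and its type-I error
   is calibrated under the population null with τ₁ > 0. The naive OLS
   t-test (df = N_obs − N_fixed) remains available (`test="ols-t"`) and is
   what `fit_growth_model` reports for real 1×1×1 data, where the true
   components are unknown; it is calibrated only under its own reduced
   model (τ₁ = 0), and the suite checks both calibrations.

2. **Wald z from a numerically fitted LMM is unreliable at PDX scales.**
   With τ₁ ~ 0.009 and n = 3–6 mice per arm, the likelihood maximum for
   the slope variance frequently sits on the zero boundary, where the
   Hessian-based SE of the interaction degenerates (observed: median
   SE inflation 1.4×, upper quartile ~10× against the exact SE), and plain
   Wald z has measured type-I ≈ 0.12 at nominal .05. For balanced complete
   data the fixed-effect slope contrast from the LMM *equals* the
   difference of group means of per-mouse OLS slopes (GLS weights cancel
   under balance; asserted numerically), and those per-mouse slopes are
   i.i.d. normal within arm — so the exact test is the two-sample t on
   per-mouse slopes with 2(n−1) df. That is the default inference for
   balanced replicated designs (measured type-I 0.054/0.204 at nominal
   .05/.20); Wald z is retained for unbalanced data (`test="wald-z"`),
   where no exact test exists.

3. **Engines.** `fit_growth_model` fits the LMM with statsmodels MixedLM
   (ML by default so likelihoods are comparable; REML optional), with a
   non-convergence ladder over optimizers (lbfgs → bfgs → powell) and
   covariance structures (full → independent random effects → slope only),
   recording any fallback in the result. A closed-form engine
   (`engine="closed-form"`) for balanced complete data computes identical
   fixed effects from per-mouse OLS summaries and Swamy-type moment
   estimates of (σ, τ₀, τ₁, τ₀₁) — between-mouse covariance of fitted
   (intercept, slope) minus the sampling contribution σ²(X'X)⁻¹, projected
   to the PSD cone — without an optimizer. Inference (the slope-contrast
   t) is identical between engines; `simulate_power` uses the closed form
   for speed, and an equivalence test pins the two engines together.

## Synthetic-data generator

`simulate_experiment` draws each mouse's (b0, b1) from Ψ via Cholesky and
adds i.i.d. N(0, σ²) residuals at every scheduled day, on the log scale
directly. One seed per experiment; per-mouse substreams are spawned with
`numpy.random.SeedSequence`, so output is bit-reproducible and a mouse's
trajectory does not depend on group size. The generator emulates the
balanced, complete, common-schedule data the model analyzes. Real PDX data
differ in ways the generator deliberately omits: staggered enrollment and
irregular measurement days, humane-endpoint truncation (large tumors exit
early, a form of informative dropout), volumes recorded with
device-specific error, and possible non-lognormal growth. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to those features.

## Numerical choices and degenerate inputs

- Power is computed with scipy's normal CDF; no approximation beyond the
  normal theory itself.
- σ = τ₀ = τ₁ = 0 simulates deterministic lines; the slope-contrast t then
  has SE 0 and the test reports p = 0 for any nonzero difference.
- `required_sample_size` refuses β_effect = 0 (no finite n) and validates
  target power in (0, 1).
- Trajectory CSVs reject duplicate (mouse, day) rows, missing columns, and
  non-positive volumes under log transform.
- Moment estimates of Ψ are projected to positive semidefinite by
  eigenvalue clipping; correlations are reported as 0 when either SD
  estimate is 0.

## Fidelity to the published tables

With the printed parameter values the analytic engine reproduces the
48-cell power grid to within ±0.035 (most cells ±0.01) and all required
sample sizes to within ±1 mouse. Two cells of the published grid
(4wk/twice-weekly/average-τ₁: large effect at α = .05, printed 0.82 vs
computed 0.788; small effect at α = .2, printed 0.25 vs 0.285) and the
small-effect worst-case n (printed 21 vs computed 20, achieved power
0.801) sit just outside the rounding of the printed inputs: they are
consistent with an unrounded median τ̂₁ slightly below 0.009 (≈ 0.0085
reproduces 0.82) and/or a conservative ceiling in the original sample-size
calculation. The corresponding tests assert the printed values with these
caveats stated.

## Problem sizes

Monte-Carlo checks in the test suite use 2,000 replicates per grid cell
for formula-vs-simulation cross-validation (3σ binomial bands), 10,000
replicates for type-I calibration, and 1,000 replicates at n = 6 per arm
(the cohort's average replicate count) for parameter-recovery bias. These
sizes give Monte-Carlo standard errors of 0.002–0.011 on a power scale,
comfortably below every tolerance asserted.

## Limitations

- Two arms only, equal group sizes, two-sided tests; no multi-model
  (many-PDX-per-drug) power.
- The analytic formula assumes balance and a common schedule; unbalanced
  real data fall back to Wald-z LMM inference with no exactness guarantee.
- Categorical response criteria (mRECIST-style) and endpoint/AUC analyses
  are out of scope; the package addresses growth-rate contrasts only.
- Retrospective per-experiment power requires a user-supplied coefficient
  table (one row per experiment); the package validates and processes it
  but ships no cohort data.
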