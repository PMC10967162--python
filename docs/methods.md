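# Methods

## Model

Incident falls for participant *i* are modelled as NB2 negative-binomial
counts with a log link:

    Y_i ~ NB(mean μ_i, dispersion θ),   Var[Y_i] = μ_i + μ_i²/θ
    log μ_i = α + β_{level(i)} + log t_i

`level(i)` is the prior 12-month fall count coded as a factor
{0, 1, 2, 3, 4, 5+} with 0 the reference, `t_i` the person-years of
follow-up entering as an offset. θ is the *size* parameter (larger θ =
less overdispersion), matching the convention of R's `glm.nb`, which is
what the NB2 gamma-Poisson sampler in the cohort generator also uses
(gamma frailty with shape θ and mean 1). This parameterisation choice
is load-bearing: statsmodels estimates the inverse quantity
`alpha = 1/θ`, so the fit wrapper converts the point estimate and maps
the standard error by the delta method, `se(θ) = se(alpha)/alpha²`.
Wald standard errors come from the observed information of the joint
(coefficients, dispersion) maximum-likelihood fit; θ's CI is reported on
the linear θ scale, consistent with the symmetric intervals the source
analyses print.

The two-stage combined analysis fits this model separately per cohort
(stage 1), then pools each coefficient across cohorts (stage 2) under
the additive random-effects model `y_i ~ N(μ, se_i² + τ²)` with
inverse-variance weights `w_i = 1/(se_i² + τ²)`. τ² is estimated by
restricted maximum likelihood: Fisher scoring on τ², convergence when
the step falls below 1e-10·(1+τ²), at most 100 iterations, estimate
floored at zero; if scoring cycles, a bounded scalar maximisation of the
restricted likelihood takes over (both paths agree with a brute-force
grid maximiser to 2e-4 in the tests). Heterogeneity is reported as
Higgins I² in its τ²-based form, `I² = 100·τ²/(τ² + s²)`, with
`s² = (k−1)Σw/( (Σw)² − Σw² )` built from fixed-effect weights — the
appropriate form when τ² is REML-estimated; the (Q−df)/Q form is
exposed (`i2_from_q`) for comparison only. Confidence intervals use
the plain 1.96 normal quantile; the Knapp–Hartung small-sample
adjustment is available behind a flag but is not the default because
the published overall intervals are only reproduced by the plain-z
method. θ is pooled on the linear scale for the same reason (log-scale
pooling available as an option). Pooled coefficients are assembled into
an "overall" model whose covariance is diagonal — each coefficient is
pooled independently, so no cross-coefficient covariance is available
at stage 2 by construction.

When the second stage is rerun on the *printed* first-stage table, each
cohort's link-scale SE is recovered from its published 95% CI as
`(ln hi − ln lo)/(2·1.96)` (linear difference for θ). Rounding of the
printed inputs caps the achievable agreement: the recomputed overall
column matches print to within 0.005 on the rate-ratio scale and I² to
within ~0.1 point for the homogeneous rows and ~0.1 point for the
baseline row (89.31 recomputed vs 89.24 printed).

## Synthetic cohorts

The generator emulates the three source cohorts at their published
marginal structure: n = 630 / 370 / 855; baseline rates 0.43 / 0.83 /
0.61 falls per person-year; the published per-level rate ratios;
θ = 1.06 / 0.66 / 1.18; follow-up fixed at 1 year for the first and
third cohorts and uniform on [1/12, 1] years for the second (its
participants only had to remain enrolled for a month, hence the offset).
Two quantities are *not* published and are package assumptions:

- **Prior-fall level probabilities.** Chosen so the implied mean
  prior-fall count matches the reported cohort means (1.03 / 1.45 /
  0.73) given the 5+ rule below; e.g. (0.577, 0.18, 0.10, 0.05, 0.03,
  0.063) for the first cohort. They are configurable in the YAML specs
  and should be treated as plausible placeholders, not study values.
- **Raw counts inside "5+".** Drawn as 5 + Geometric(0.5) failures
  (mean 6). Only the level enters the model, so this is cosmetic.

One global seed expands into per-cohort substreams via
`SeedSequence(seed, spawn_key=(cohort_index,))`, masked to 31 bits — a
stable derivation across platforms and runs.

What the generator does **not** emulate: intervention arms, recall error
in retrospective fall ascertainment, within-person correlation between
prior and incident falls beyond the level effect, any covariate
structure (age, sex, fear of falling), or informative loss to follow-up.
Consequently, passing simulation tests show that the *pipeline* recovers
what it assumes; they say nothing about how well the NB2 factor model
describes real fall data.

## Validation and calibration

The mean absolute prediction error (MAE) of model *m* on dataset *d* is
the mean of |observed − expected| falls with each participant's level
and exposure; the diagonal of the model × dataset matrix is the apparent
error. Calibration-in-the-large recalibrates an existing model to a new
cohort on the link scale: compute the model's linear predictor p0
(offset included), fit a fresh intercept-only NB2 model to the new
outcomes with p0 as offset, and report its intercept α_new; updated
predictions are `p1 = α_new + p0`. The dispersion is re-estimated in
that fit by default (`carry_theta=True` keeps the original). For cohorts
that differ only in baseline rate, α_new estimates the log baseline-rate
ratio; self-recalibration returns α_new ≈ 0.

The cross-validation matrix supports both raw and recalibrated scoring.
The package's qualitative model-independence check uses the
**recalibrated** matrix. Rationale: with the published generating
values, the *expected* raw MAE of the second cohort's model (baseline
0.83) on first-cohort data (baseline 0.43) exceeds the apparent error by
roughly 20% — most participants have zero incident falls, so doubling
the predicted rate adds the difference directly to the error. The
published external errors instead equal the apparent ones to the second
decimal, which is only consistent with errors computed after
intercept recalibration; the adjacent remark that recalibration "can
catch the baseline rate of the cohorts" supports this reading. Raw MAE
remains the default elsewhere and both matrices are written by the
pipeline.

Rootograms assess marginal calibration: expected frequency of count k is
the sum over participants of the NB2 pmf at k given (μ_i, θ) — the
standard marginal-calibration construction — with counts above K
(default 20) pooled into an open tail bin on both sides so observed and
expected frequencies each sum to n. Bars are drawn hanging from the
square-root expected curve: a bar crossing below the axis means the
model underestimates that frequency, a floating bar overestimation.

## Numerical choices and degenerate inputs

- NB fit: statsmodels joint ML (`loglike_method="nb2"`), 200 iterations,
  gradient tolerance 1e-8; on non-convergence one retry from a Poisson
  warm start with BFGS, then a `ConvergenceError` carrying the optimiser
  trace. All-zero outcomes raise immediately (θ unidentifiable, boundary
  intercept), as does a non-positive dispersion estimate (data with no
  overdispersion have no interior NB2 maximum).
- Factor levels with no participants are dropped with a warning and
  recorded on the model; stage 2 pools a coefficient only where ≥ 2
  models carry it and flags it otherwise, rather than imputing.
- CI back-transform from a printed CI refuses degenerate (zero-width)
  intervals, since a zero SE would give that study infinite weight.
- I² is clamped to [0, 100]; τ² is floored at 0.

## Problem sizes

Simulation-based checks run at the study sizes (630/370/855) for
pipeline-level properties, n = 10,000 for parameter-recovery and
calibration identities (100 replications for coverage, 10 for the
MAE-spread property, which is reported as a mean over replications
because a single replication at the study sizes carries several points
of Monte-Carlo noise). The published-table reproduction is exact
arithmetic on 3 studies and runs in milliseconds.

## Known limitations

- The overall model's diagonal covariance ignores within-study
  correlation between coefficients; predictions combining α and β are
  fine, but joint Wald tests across coefficients are not supported.
- The synthetic level probabilities are assumptions (see above); any
  statistic sensitive to the prior-fall distribution (e.g. absolute MAE
  levels) is not comparable to the published real-data values.
- No one-stage IPD meta-analysis, no zero-inflated/hurdle variants, no
  calibration slopes — the scope is intercept recalibration only.
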