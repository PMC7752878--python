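# Methods

## Model and estimands

The quantity modelled is the instantaneous probability of dying at time
*t*, `g(t) = 1 − exp[−h(t)]`, where `h` is the hazard. Unlike a hazard
(a rate, unbounded above), `g` is a proper probability, so odds ratios of
`g` are interpretable risk comparisons. The regression is

    logit g(t | x) = η(t, x) = γ₀ + B(t)·γ + x·β + interactions

with `B(t)` a baseline basis in time since surgery (constant, linear, or a
restricted cubic spline) and `x` the age term(s) plus dummy-coded
covariates (sex, education, Charlson comorbidity index, neoadjuvant
therapy, histology, pathological stage, resection margin; reference level =
first listed category). Consequences of the logit link:

* `exp(β)` is an odds ratio of the instantaneous death probability,
  constant over follow-up time — one number per covariate;
* the hazard is `h = softplus(η) = log(1 + e^η)`, strictly positive with no
  constraint needed;
* `log h` is concave in η and `h` convex, so the censored/truncated
  log-likelihood is globally concave and Newton-type optimisation is
  reliable.

A proportional-hazards variant uses `log h(t|x) = η` instead; `exp(β)` is
then a hazard ratio. Both links share one likelihood engine; under
proportional hazards the two scales are connected by the power identity
`1 − g₁(t) = (1 − g₀(t))^HR`, exact at every *t*.

**Time unit.** `g` is a per-unit-interval probability, so its value and the
odds ratios depend on the time unit. The package fixes **years**
(days/365.25) throughout: with yearly hazards in the range seen here, `g`
is visibly different from `h` and the OR from the HR. (Had days been used,
`g ≈ h` everywhere and fitted ORs would collapse to HRs — the estimand
would lose its distinct meaning.) Hazard-scale effects, by contrast, are
unit-invariant up to an intercept shift, and the test suite checks this
exactly on the PH model.

## Likelihood, censoring, delayed entry

With per-subject entry time `a`, exit time `t`, and event indicator `d`:

    ℓ = Σᵢ [ dᵢ log h(tᵢ | xᵢ) − H(aᵢ, tᵢ | xᵢ) ],   H(a,t) = ∫ₐᵗ h(u) du.

Right censoring contributes only `−H`; left truncation (the 90-day landmark
of the disease-specific endpoint) starts the integral at the entry time.
`H` is computed by Gauss–Legendre quadrature with 20 nodes per subinterval,
intervals split at the spline knots so the integrand is smooth on each
piece; on such pieces the quadrature is accurate to ~1e−13 relative
(verified against 10⁶-step midpoint Riemann sums in the tests). Because the
design columns at event times and quadrature nodes do not depend on the
coefficients, they are precomputed once per fit and the likelihood,
gradient and Hessian reduce to dense matrix products.

## Fitting and inference

* Optimiser: scipy trust-region Newton (`trust-exact`) with analytic
  gradient and Hessian; convergence requires gradient norm < 1e−5 (the
  `converged_` flag reports this honestly); on failure, 5 restarts from
  perturbed initial values (seeded).
* Initial values: `γ₀` set so the baseline hazard equals the crude event
  rate D/T (`softplus⁻¹(D/T)` for the logit link, `log(D/T)` for PH), all
  other coefficients 0. With the time coefficientless (`constant`) baseline
  the fit reproduces the exponential MLE `λ̂ = D/T` to machine precision.
* Covariance: inverse observed information at the optimum; 95% intervals
  are Wald on the coefficient scale, exponentiated (z = 1.96).
* Rank deficiency: pivoted QR on the quadrature design with tolerance
  1e−8; offending columns are reported by name rather than silently
  dropped.
* Knots: data-driven placement follows the Royston–Parmar convention —
  boundary knots at the min/max observed event times, interior knots at
  event-time quantiles (median for 3 knots, 33rd/67th centiles for 4).
* Model selection: AIC = 2k − 2ℓ across candidate baselines; ties go to the
  fewer-parameter, earlier-listed candidate; non-convergent candidates are
  recorded and excluded with a warning. Interactions (age×time,
  age×covariate) are judged by likelihood-ratio tests at α = 0.05.
* Degenerate inputs: deaths recorded on day 0 are moved to day 0.5
  (registry day resolution; the hazard must be integrable from 0); fits
  with zero events are refused with an explicit error.

## Endpoints

* `d90_all_cause`: exit = min(follow-up, 90 d); death on day 90 counts as
  an event (inclusive cut-off).
* `y5_all_cause`: exit = min(follow-up, 1826 d), where 1826 d = 5 × 365.25
  rounded.
* `y5_disease_specific`: subjects with follow-up ≤ 90 d are excluded;
  entry = day 90; events are cancer-cause deaths in (90, 1826]; non-cancer
  deaths are censoring at the death date (cause-specific framing, no
  competing-risks model).

Every excluded row is logged with a reason so counts reconcile. The
disease-specific denominator for descriptive rates is the count of 90-day
survivors (total minus 90-day deaths). Percentages round half-up to one
decimal.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, so
the full pipeline is testable without access to registry data:

* **Covariate marginals** equal the published cohort composition
  (probabilities = published counts / 1737).
* **Age** is a truncated skew-normal on [18, 89] with parameters
  (a = −3.19, loc = 76.3, scale = 15.65) chosen once so the median is
  ≈ 65.6 years and the four published age-band frequencies are matched to
  within about one percentage point.
* **Confounding**: comorbidity is drawn conditional on age band — an
  exponential tilt toward higher comorbidity at older ages, corrected by
  iterative proportional fitting so the marginal comorbidity distribution
  still matches its target exactly. This is the minimal structure that
  makes crude and adjusted odds ratios differ; all other covariates are
  independent (configurable).
* **Death times** are drawn from the logit-g model family by
  inverse-transform sampling: `t` solves `H(0, t) = E`, `E ~ Exp(1)`, by
  bracketing and bisection to 1e−8 years. The default truth has a linear
  time trend, a per-year age OR of 1.05 at surgery attenuating with
  follow-up (negative age×time interaction, so short-term age effects
  exceed long-term ones), and directionally sensible covariate effects;
  the baseline intercept and time slope are calibrated so the
  population-average 90-day and 5-year death probabilities are 0.112 and
  0.748. The non-age effect sizes are order-of-magnitude choices, not
  estimates — the source cohort does not report them.
* **Causes**: given death, cancer cause is Bernoulli with stage-dependent
  probability (0.85 early-stage, 0.95 advanced), giving roughly 90% of
  post-90-day deaths cancer-caused.
* **Censoring**: a single administrative horizon (default 6 years,
  constrained ≥ 5) guarantees five years of potential follow-up for every
  subject; calendar accrual and period effects are deliberately collapsed
  into this one parameter.
* **Randomness**: one master seed spawns named substreams (covariates,
  event times, causes), so adding draws in one stage does not perturb the
  others; identical configs give byte-identical cohort CSVs.

What the generator does **not** emulate: registry linkage errors, loss to
follow-up, period/calendar effects, competing-risks cause structure, or
within-covariate dependence beyond age→comorbidity. Passing tests
demonstrate that the estimator recovers the truth under the model's own
assumptions and the published cohort composition — not that the model is
correctly specified for any particular real cohort.

## Verification

The suite combines exact oracles with calibration simulations; the
acceptance script recomputes the same quantities from scratch.

* Spline basis vs a term-by-term symbolic evaluation of the restricted
  truncated-power formula; curvature zero beyond the boundary knots.
* Quadrature vs 10⁶-step midpoint Riemann sums over random spline
  configurations (relative error < 1e−6; observed ~1e−12).
* Full fitting path vs the closed-form exponential MLE (λ̂ = D/T).
* Wald coverage: cohorts of n = 2000 simulated from the model (per-year
  age OR 1.05, administrative censoring at 5 years), analysed end-to-end;
  500 replicates; per-coefficient 95%-interval coverage required in
  [0.92, 0.98] (observed ≈ 0.94–0.95).
* Interaction LRT size: 500 null replicates at n = 1000; rejection rate at
  α = 0.05 required in [0.03, 0.07] (pooled over 3500 replicates ≈ 0.049).
* Power identity `1 − g₁ = (1 − g₀)^HR` to 1e−8 on PH fits; for small
  effects with g ≤ 0.15 the median |OR − HR| is below 0.01, quantifying
  when the two estimands coincide; lifelines' Cox partial likelihood serves
  as an independent cross-check of the PH coefficients.
* Pipeline determinism: identical cohort/seed/plan give byte-identical
  report bundles (no timestamps in the manifest).

Replicate counts and cohort sizes above are the package's chosen simulation
conditions; they keep each calibration suite to a couple of minutes on a
single CPU while leaving binomial noise well inside the asserted bands.

## Open design choices, as made

* The exact linear-predictor scale used by the original analysis software
  is not recoverable from public sources; the logit-of-g parametrisation is
  this package's decision, chosen because it is the only scale on which the
  reported "odds ratios of the probability" are single time-constant
  numbers per covariate.
* The hazard-ratio comparison model is a spline-baseline *parametric* PH
  fit sharing the likelihood engine (not Cox partial likelihood), so the
  OR/HR contrast isolates the link choice; Cox is a test-only cross-check.
* Stratified analyses drop the stratifying variable from its own
  adjustment set (configurable via `AnalysisPlan.drop_stratifier`).
* The OR-vs-HR similarity flag uses a 5% relative threshold — arbitrary,
  documented, configurable.
* No multiple-testing adjustment is applied anywhere; stratified tables
  are labelled descriptive.

## Limitations

Time-varying covariates, penalised or Bayesian estimation, and
competing-risks models are out of scope. The odds-of-probability estimand
is tied to the chosen time unit (years). Categorical age uses fixed breaks
(70, 75). The synthetic generator's non-age effect sizes are assumptions;
analyses of real cohorts should treat the bundled truth values as
placeholders, not priors.
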