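# Methods

This note documents the models, conventions and numerical choices behind
`phenosync`, in the order the pipeline runs.

## Curve construction

**Availability.** Caterpillar biomass (g/m², already converted from frass
mass) is sampled every 3–4 days; a daily curve is needed.  We fit an exact
interpolating cubic spline — one knot per sampling date, so the smoother has
the maximum possible degrees of freedom and passes through every sample.
Outside the sampled range the curve continues linearly with the spline's
boundary slope.  If that slope points *upward* away from the data (a
non-decreasing outward prediction), the whole tail on that side is set to
zero instead: a rising extrapolation of a seasonal food pulse is an artefact
of the sampling window, not biology.  The rule is applied per side
independently, and all negative values are clipped to zero.  Seasons whose
first or last sample exceeds 25% (configurable) of the seasonal maximum are
flagged as possibly truncated — the sampling campaign may have missed a tail
— but never dropped silently.

**Requirement.** Per-nestling daily demand is the age-specific series
2.57, 2.92, 3.34, 3.62, 3.90, 3.97, 4.21, 4.37, 4.49, 4.51, 4.51 g wet
biomass for ages 5–15 (energy intake ÷ 21.4 kJ/g dry × 5 for 80% wet mass;
all four constants are `PipelineConfig` fields, never hard-coded).  Each
non-failed brood contributes `brood_size_d15 ×` that series on the 11
calendar days its nestlings are in the critical window (hatch day = age 0);
contributions are summed across broods.  Failed broods (no day-15 count)
contribute nothing — their earlier-stage demand is unknown, and the
resulting downward bias is accepted and documented rather than imputed.

**Scaling.** Availability (g/m²) and requirement (g) are on different
scales; each kind is divided by its own single maximum across all seasons.
This preserves within-year shapes and between-year height ratios exactly.
Whether across-season scaling should use the global maximum or another
normaliser was genuinely open; the global maximum is the only choice that
preserves both properties and is recorded here as the package's decision
(configurable in principle by scaling curves manually).

**Peak statistics.** Peak date is the earliest day attaining the maximum
(deterministic tie-break); HCP is that maximum.  Skewness and excess
kurtosis treat the normalised curve as a probability mass over days (third
and fourth standardised central moments).  Degenerate curves (zero mass, or
all mass on one day) raise errors rather than returning NaNs.

## Synchrony metrics

* `MD_b = (hatch + 10) − peak date`; `MD_p = mean lay date + 33 − peak
  date`, the mean taken over **all** first broods including failed ones
  (laying decisions precede failure).  Positive = consumer late.
* `MO_p` = trapezoidal integral of `min(f_F, f_R)` over the union day grid
  (each curve zero outside its support) divided by the trapezoidal integral
  of `f_F`.  The denominator is the availability integral exactly — not the
  union, not the requirement.  `MO_p` is signed by the direction of `MD_p`
  where direction matters; the `MD_p = 0` tie takes the positive sign
  (undefined otherwise; flagged in the API docs).
* `MO_b` sums the **raw** availability over a brood's 11 critical days and
  standardises within year to mean 0, SD 1 using the population SD
  (divisor n — deterministic for two broods).  Summing vs averaging over
  the 11 days is equivalent after standardisation; summing is used.  A
  single brood or zero spread maps to 0 by convention.
* The MD–MO association across years is a beta-regression mean model
  (logit link) of `MO_p` on `MD_p + MD_p²`; boundary values of exactly
  0 or 1 are nudged inward by machine epsilon and logged.

Note a structural property of the overlap: when the requirement curve nests
strictly inside the availability curve, `MO_p` is *flat* over small shifts
(the minimum is the requirement everywhere), so the overlap-maximal-at-zero-
mismatch property holds only when peak heights are comparable.

## Candidate-model suites

Recruitment (binomial, nestling level, non-failed first broods only):
base `dens + BCI`, then `+MD_b`, `+MD_b + MD_b²`, `+MO_b`; random
intercepts year, mother, brood-within-mother (brood ids are globally
unique, so the nesting reduces to independent mother and brood intercepts).
Selection (Poisson recruit count, all first broods of known females):
base `dens + CS + ELD + BCI` with ELD mean-centred within years, plus the
eight focal variants combining `MD_p`, `MD_p:ELD`, signed `MO_p`, `MO_p²`,
`MO_p:ELD` and `HCP`; random intercepts year and female.  Shape variants
replace HCP with across-year-standardised skewness or kurtosis in the two
HCP candidates.  BCI enters as a single numeric ordinal covariate; it is
identical across candidates within a suite, so rankings are unaffected by
the coding.

**Fitting.** Random-intercept GLMMs are fitted by maximum likelihood with a
Laplace approximation: an inner penalised-IRLS loop finds the joint mode of
fixed and random effects at given variance components (sparse Cholesky via
LU on the random-effects block), and a bounded L-BFGS-B outer loop
optimises the random-effect standard deviations on [0, 5].  At zero
variance the approximation is exact and the fit coincides with the plain
GLM (tested at machine precision); at positive variance it matches
`lme4::glmer`'s Laplace fit closely (cross-checked in the test suite; small
intercept differences arise because `glmer` includes the log-determinant's
dependence on the fixed effects in its profiled objective).  Note that on
data generated *without* group effects the ML variance estimate can
legitimately remain positive in finite samples; the fixed effects then
differ from the GLM by a correspondingly small amount.

**Ranking.** `AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)` with `k` = fixed effects
(incl. intercept) + one per variance component, and `n` = response rows
(nestlings or broods).  ΔAICc ≤ 2 flags a candidate competitive.  Models
that fail to fit (separation, singular systems) are excluded from the
ranking with a logged warning.

**Uncertainty.** Bootstrap CIs are parametric: simulate responses from the
fitted model with fresh random-effect draws, refit, take 2.5/97.5
percentiles (the alternative — cluster resampling by year — is a
straightforward swap but parametric is the default).  VIF is the standard
`1/(1−R²)` per fixed-effect column.

## Synthetic-data generator

The generator emulates the structure of a long-term nest-box study: 24
seasons of ~85 pairs (defaults), among-year variance of the population
mismatch ≈ 52 days² and within-year laying spread ≈ 22.5 days², a Gaussian
availability bump in expectation (unimodal, as the metrics presume) with
mean peak height 7 g/m² and width SD 7 days, sampled every 3 days with
mean-one multiplicative log-normal noise (CV 0.2).  Clutch = 5 +
Binomial(8, 0.5) (mean 9); day-15 brood size subtracts binomial losses
(p = 0.08); 12% of broods fail; mothers return between years at rate 0.5.
Hatch = lay + 23, so the 33-day lay-to-peak-need convention holds exactly
and `MD_p` and `MD_b` are mutually consistent by construction.

Recruitment truth: per-nestling Bernoulli with
`logit p = α + β_md·MD_b + β_md2·MD_b² + β_mo·MO_b + year + mother + brood`
random intercepts, the metrics computed from the *true* noiseless curve.
A second, brood-level path draws Poisson recruit counts from
`log λ = α + β·ELD·MD_p` (plus optional main effects) for validating the
selection suite.

What the generator does **not** emulate: spatial heterogeneity in
availability (one area-wide curve), density dependence, trends or
autocorrelation across years, observation error in breeding records, and
any realistic joint distribution of density and beech crop beyond plausible
ranges.  Passing recovery tests therefore show that the *pipeline* measures
and ranks correctly under its own assumptions — not that MD or MO wins in
any real system.

## Measurement-error simulation

Per iteration: 1,500 observations over 23 years; `MD_p ~ N(0, 52)`;
`ELD ~ N(MD_p, 22.5)` (the 33-day lag is deliberately ignored — ELD is
already on the mismatch scale).  Availability: the N(0, 140) density on
1,000 points spanning ±3.5 SD (span configurable), averaged within 30
consecutive bins (rounded bin edges keep the binned curve exactly
symmetric), rescaled to a mean of 4 g·m⁻²·d⁻¹, then × 0.2 × 21.4 = 4.28 to
kJ/m² and × 3×10⁵ to total kJ.  Requirement: broods binned by laying day
contribute 4 g × 8 nestlings × 4.28 kJ/g = 136.96 kJ each, smoothed with a
natural cubic smoothing spline at 30/3 = 10 effective df; the requirement
curve is built from within-year-centred laying dates and then translated by
`round(MD_p)` (building from raw dates *and* shifting would double-count
the year offset).

The two correlation layers (density → total, total → provisioned) use
`y = r·sd(res)·x + res·sd(x)·√(1−r²)`, with `res` the OLS residuals of a
standard-normal draw regressed on `x`: residual orthogonality makes the
in-sample correlation *exactly* `r` (the formula as printed in the source
material is typographically garbled; this is the unique reading with that
property, and the exactness is pinned by tests at 1e−8).  Each layer is
applied to the concatenated across-year daily series, not per year:
per-year application would rescale years by different factors even at
r = 1, changing the overlap after across-year scaling.  The provisioned
series is smoothed (10 df) and clipped at zero.

Fitness is Poisson with `λ = exp(0.5·MO_true²)` — driven by the **true**
(undegraded) overlap, since the question is how estimation error in MO
affects inference against a fixed truth.  Unsigned MO enters the fitness
exponent (the square makes the sign moot).  The two fitted fixed-effects
GLMs are `W ~ MO + MO²` (MO from the degraded signal, entering signed by
the year's MD_p direction, which also keeps MO and MO² well separated) and
`W ~ ELD × MD_p`; covariates are scaled to unit SD before fitting so the
reported coefficients are standardised; models are compared by
`ΔAICc = AICc(MO) − AICc(MD)`, negative favouring the overlap model.  The
grid is {1, 0.75, 0.5, 0.25}² with independent sub-seeds per scenario and
iteration; non-converged iterations are dropped and counted, erroring above
5%.

## Problem sizes and tolerances

The test suite and acceptance script keep Monte-Carlo work desk-sized as
the package's own choice: model-recovery checks use 12-year × 40-pair
noiseless studies (noiseless sampling isolates ranking correctness from
curve-estimation error, which otherwise dominates: with sampling noise
CV 0.2 the estimated peak date errs by several days and the overlap proxy —
robust to that error — can out-rank the true quadratic-MD model); the
correlation grid runs 200 iterations per scenario (the trends stabilise
well below that); bootstrap examples use B = 100–200.  Spline
interpolation is tested to 1e−9 at the knots; the smoothing spline's hat
trace to 1e−4 of the requested df; correlation induction to 1e−8; GLM fits
match statsmodels to 1e−6.

## Known limitations

* The Laplace approximation is first-order; with few groups and strong
  nonlinearity its variance estimates can be biased (the usual caveat for
  `glmer`-style fits).  Rankings in the tested regimes are unaffected.
* The overlap numerator uses the pointwise minimum on an integer-day grid;
  sub-day peak timing is not resolved.
* One area-wide availability curve is assumed; territory-level variation in
  food is outside scope.
* The beta-regression association check is validated on synthetic data
  only.
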