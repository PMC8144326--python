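# Methods

## Scoring and grading

Four ICF dimension scores (activity 0–50, body 0–60, participation
0–30, health 0–100) are summed to a total in [0, 240] and banded into
five ordered grades. Band intervals are lower-open/upper-closed except
the first: [0,50] → 1, (50,100] → 2, (100,150] → 3, (150,200] → 4,
(200,240] → 5. The closed lower band follows the convention that "50
points or less" belongs to the severe grade; all other boundary points
belong to the band below them being the worse grade's upper edge. Both
the per-dimension caps and the band edges are configuration
(`GradingScheme`), because the dimension weighting is an assessment
design choice, not something the pipeline can estimate; the defaults
embody the 50/60/30/100 weighting. Item-level scoring (which
questionnaire items feed each dimension) is out of scope — the pipeline
consumes dimension-level scores.

Descriptive percentages are rounded half-up to one decimal;
disabled-duration shares half-up to two decimals. Within one variable
the rounded percents may sum to 100.0 ± 0.2.

A record may carry both a grade (its wave assessment) and a
death-by-follow-up indicator; the `state` column used by the transition
stage collapses the two, with death (code 0) overriding the grade.

## Synthetic cohort generator

The generator emulates a CLHLS-style two-wave panel (waves 2011/2014,
3-year interval): baseline grade drawn from a per-age-group prevalence
vector, wave-2 state drawn from the age group's 5×6 transition matrix
with death absorbing, and realized dimension scores drawn for every
surviving grade. Defaults are the study conditions:

- **Sample sizes** 2,890 / 4,377 / 4,079 / 2,909 subjects for age groups
  65–74 / 75–84 / 85–94 / 95+ (the per-age-group estimation samples).
- **Baseline prevalence** (0.047, 0.053, 0.090, 0.139, 0.671) over
  grades 1–5, the pooled descriptive distribution, applied to every age
  group because no per-age breakdown is published.
- **Transition matrices**: every cell the source text states for an age
  group × initial state (death probabilities, stay probabilities,
  health-transfer probabilities) is anchored exactly; the residual row
  mass is spread over the unreported cells following the overall-matrix
  pattern (more mass to nearby states), and rows are normalized. These
  are generator configuration, not estimates. One stated anomaly is kept
  as stated: the 85–94 healthy-row death probability (11.5%) is lower
  than its neighbours.
- **Covariate effects on death**: log-odds male +1.0, widowed +0.65,
  urban 0 (urban effects are reported non-significant), applied to the
  death probability with the transient row renormalized. Optional
  proportional-odds effects on the surviving grade are available and
  default to zero, so the baseline mechanism is exactly the matrix.
- **Covariate prevalences** male 0.45, urban 0.40, widowed 0.50 —
  plausible for an oldest-old oversampled cohort; they only set
  predictor variance, not any estimand.
- **Scores within a band** are uniform on the band (no within-band
  distribution is published), split across the four dimensions by a flat
  Dirichlet composition with cap-respecting redistribution: allocations
  above a dimension cap are clipped and the excess is spread over the
  remaining capacity, which preserves the total exactly.

All randomness flows from one `numpy` generator seeded by
`CohortSpec.seed` (default 20110000); regeneration is bit-identical.

Deliberately **not** emulated: sampling weights, attrition /
loss-to-follow-up, proxy respondents, death timing within the interval
(a binary 3-year outcome matches the absorbing-state treatment), and
aging across the interval — the age group is frozen at its baseline
value, matching stratification by baseline age. Passing tests therefore
show estimator correctness under clean multinomial sampling, not
robustness to informative dropout or measurement error.

## Transition estimation

Matched subject pairs are counted into 5×6 tables (baseline grade ×
3-year outcome) and converted to probabilities by the row-wise
multinomial MLE. Conventions:

- Complete-case: subjects without a wave-2 outcome are excluded and
  reported in a `lost` tally; subjects dead at baseline are excluded
  with a warning tally.
- No smoothing by default (the estimates are the raw observed
  frequencies); add-k smoothing sits behind `smoothing_k`.
- Zero-count rows yield NaN with a warning rather than an imputed value;
  the life-table stage refuses NaN rows.
- Age strata are half-open decade bins [65,75), [75,85), [85,95),
  [95,∞), labelled 65-74 / 75-84 / 85-94 / 95+.
- Estimated rows sum to 1 within 1e-12; the text report prints one
  decimal and notes the pre-rounding row sums.

Uncertainty is by subject-level bootstrap (percentile intervals,
B ≥ 100).

## Life table

With Q the transient block, N = (I − Q)⁻¹ exists iff the spectral
radius of Q is below 1; otherwise the chain is reported as not absorbing
from the offending state. Durations are `interval × πᵀN` years.

- **Discrete-time convention**: the starting interval is counted once,
  so the minimum remaining life is one interval (3 years). No mid-period
  death correction is applied by default; `half_interval=True` subtracts
  half an interval (charged proportionally to occupancy) for sensitivity
  analysis.
- **Stationarity**: an age group's matrix is applied repeatedly without
  moving the survivor into older age groups. This matches per-age-group
  reporting but overstates remaining life where mortality rises steeply
  with age — most visibly for healthy 65–74-year-olds, whose implied
  remaining life under a frozen 65–74 matrix exceeds what an
  age-progressing model would give. Cross-age-group chaining is a
  non-goal here.
- **Aggregated rows** use the stratum's observed baseline grade
  distribution as the initial mixture (the weighting of published
  aggregate rows is not stated; the mixture is configurable).
- The Monte-Carlo simulator draws whole paths until absorption
  (vectorised over paths, max-step cutoff with a warning for
  non-absorbing inputs) and agrees with the closed form within
  Monte-Carlo error; it is the independent oracle for N.

## Validity models

Two models probe whether the grading carries signal: a logit for the
3-year death indicator and a proportional-odds model for the grade, each
optionally with a Gaussian random intercept on a cluster column.

- The marginal likelihood integrates the intercept by **adaptive
  Gauss–Hermite quadrature** (15 nodes): per cluster the integrand is
  re-centred at its posterior mode (Newton iterations with a
  finite-difference curvature) and rescaled before applying the rule.
  No installed package offers this fit for logit/ordered-logit by ML,
  hence the in-house implementation; with the variance pinned to ~0 it
  reproduces the plain fits to optimizer tolerance, and the plain fits
  match statsmodels `Logit` / `OrderedModel` in the test suite.
- Ordered parameterization: latent `xβ + u + logistic noise` against
  strictly increasing thresholds estimated as (first threshold,
  log-differences); threshold standard errors by delta method. Positive
  coefficients mean better function. A predictor-free fit returns
  exactly the logits of the cumulative outcome frequencies.
- The LR test against the fixed-effects model uses the boundary null
  0.5·χ²₀ + 0.5·χ²₁.
- The default cluster column is the subject identifier — the only
  replication structure in a two-wave panel; with one outcome row per
  subject this means singleton clusters, which are accepted with a
  warning (the variance is then weakly identified). Discrete covariates
  such as multi-level function scores enter as linear scores.
- Wald coverage of the slope CIs is checked empirically at 95% ± 6 pp
  over 50 replicates.

## Projection

The moving-average forecast is the iterated simple mean of the trailing
`window` values, with forecasts re-entering the window — the only way a
10-year horizon can be produced from a 4-point series, hence the default
window of 4 (all available history). Forecasts of a monotone series
never exceed its running maximum. The disabled scale multiplies each
projected group population by a per-group grade prevalence (default: the
observed baseline distribution), so grade counts sum to the group total
exactly; `evolve_prevalence` optionally pushes the prevalence through
the transition matrix per 3-year step, renormalizing over survivors.
The bundled population series is geometric growth from a configurable
base (defaults: 360/200/70/10 ×10⁴ persons at 2016, 4%/year).

## Problem sizes

The test suite exercises estimator recovery at 10³–10⁵ pairs (20 seeds
per size for the consistency check), the fundamental-matrix oracle with
10⁵ paths on 20 random absorbing chains, and mixed-model recovery at
10⁴ observations (500 clusters × 20); the acceptance script uses 10⁵
pairs for matrix recovery, 10 × 10⁵ paths for the Monte-Carlo check and
10⁴ subjects for effect recovery. These sizes give standard errors
comfortably inside the asserted tolerances while keeping a full run in
well under a minute of compute.

## Known limitations

- Real-survey coefficient values (the published regression tables) are
  not reproducible without the restricted microdata; the models
  reproduce the *structure* and are validated by parameter recovery on
  synthetic data instead.
- The default generating matrices are a documented completion of
  partially reported cells, not published estimates.
- Percent rounding follows the half-up convention of the source tables;
  re-rounded sums can differ from printed totals by one unit in the last
  decimal.
- The projection inherits whatever population concept (resident vs
  registered) the supplied series measures.
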