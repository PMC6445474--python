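# Methods

`stagedist` implements a life-stage-resolved species distribution workflow
for demersal trawl-survey data, together with a synthetic survey generator
that supplies ground truth for every stage of the pipeline. This note
records the models, the defaults and why they were chosen, the numerical
decisions, and what the synthetic experiments do and do not demonstrate.

## Life-stage decomposition

Survey catches arrive as haul-level 1-cm length frequencies; life stage
(age-0, age-1, mature) is only observed for the individually sampled fish
in the sex-maturity-age-length keys (SMALKs). The probability that a fish
of length *L* belongs to a stage is modelled per survey as a binomial GLM
with logit link,

    logit p = alpha + b1*sex + b2*region + b3*L + b4*year + interactions,

fitted by maximum likelihood (statsmodels). Backward elimination removes,
at each step, the removable term with the largest likelihood-ratio p-value
above 0.05; main effects stay while any retained interaction contains them.
The 0.05 level is the conventional choice; it is exposed as an argument.
The age-0 schedule is fitted on autumn-survey SMALKs, the age-1 and
maturity schedules on spring-survey SMALKs, the maturity model on fish of
age >= 1 only.

L50 — the length at which the fitted probability crosses 0.5 — is obtained
by solving the linear predictor for zero at a fixed covariate profile,
computed as `-eta(0) / (eta(1) - eta(0))`; this is exact for any retained
interaction structure because the predictor is linear in length. A zero
effective length slope leaves L50 undefined (reported as missing).

Stage CPUE per haul is the sum over length classes of the standardized
count times the fitted stage probability at the class midpoint (lower
bound + 0.5 cm). Counts are standardized to a 30-minute tow and floored to
whole fish. Counts of unknown sex use a sex-averaged probability weighted
by the SMALK sex ratio in that 1-cm bin, falling back to 0.5/0.5 — HL-style
length frequencies are usually not sex-disaggregated, and this choice is
recorded in the output metadata.

## Environmental layers

* Terrain: Horn's 3x3 finite differences on the (negated) bathymetry give
  slope (radians) and downslope aspect (degrees clockwise from North,
  flat cells 0 by convention). Horn's operator is the de-facto raster
  standard and reproduces analytic planes to machine precision, which the
  tests exploit.
* Shore distance: distance from each sea-cell centre to the nearest
  land-cell centre minus half the east-west cell width, floored at zero
  (so a cell adjacent to land is half a cell away). Planar (distance
  transform with anisotropic cell sizes) by default; a brute-force
  haversine mode exists for geographic fidelity.
* Sediment: a mapping table merges the 17 raw substrate codes into five
  classes (mud/sandy mud, sand/muddy sand, coarse, mixed, rock); rock
  cells are excluded from the modelling domain because that ground is not
  towable by the survey gear.
* CTD handling: per station x year x season the record with maximum
  pressure (closest to the bottom) is retained, ties to the last record.
* Temperature/salinity surfaces: Nadaraya-Watson smoothing with a Gaussian
  kernel `exp(-d^2 / (2 theta^2))`, distances in km. The bandwidth theta is
  selected on a log-spaced grid (default 20 points, 5-500 km) by exact
  leave-one-out least squares; ties go to the smaller theta. The kernel
  form is recorded in output metadata so alternates can be swapped. The
  grid search (rather than continuous optimisation) keeps the selection
  reproducible and lets the LOOCV curve be verified point by point.

## Hurdle models

Stage CPUE is zero-inflated: a zero-altered Poisson (hurdle) pair is
fitted per stage — a binomial GAM for presence on all hauls and a
zero-truncated Poisson GAM (log link) for abundance on positive hauls.
The combined expectation is `p * lambda / (1 - exp(-lambda))`, the
presence probability times the truncated-Poisson conditional mean; the
untruncated alternative `p * lambda` is available behind a flag but the
truncated mean is the correct ZAP expectation.

The additive components are penalized regression splines authored in
`stagedist.gam`:

* 1-d smooths: cubic B-spline bases (default k = 10, here k = 8 at desk
  scale) with second-order difference penalties (P-splines);
* aspect: a wrapped cyclic P-spline (period 360 deg, k = 8), exactly
  periodic at 0/360;
* two-covariate interactions: tensor products of marginal bases
  (default 5x5) with the additive row/column penalty;
* categorical terms (sediment, year): unpenalized dummies;
* the survey/gear random intercept: a ridge-penalized two-level
  categorical effect. With two levels a variance component is not
  identifiable, so the reported quantity is the estimated contrast with an
  approximate SE, and mapping predictions set the intercept to the
  population level (zero).

Each smooth carries an absorbed sum-to-zero constraint for intercept
identifiability. Fitting is penalized IRLS; for the zero-truncated Poisson
the score with respect to the log-rate is `y - mu` with working weights
equal to the ZTP variance `mu (1 + lambda - mu)`, so Fisher scoring has
the standard GLM form. A single global smoothing parameter multiplies each
term's Frobenius-normalized penalty and is chosen on a 15-point log grid
by a GCV criterion `n * dev / (n - edf)^2`; the criterion name is recorded
in the model object. Per-term effective degrees of freedom are the traces
of the corresponding blocks of the influence matrix.

Model selection follows screen-then-select: a VIF screen (drop the largest
VIF above 3, iterate) on the continuous covariates, then bidirectional
stepwise AIC (`AIC = -2 loglik + 2 edf`) over the candidate terms, drops
tried before re-adds, ties resolved toward fewer terms. Variable
importance is reported as single-term-deletion delta deviance at the
selected smoothing parameter, with an approximate chi-square p-value on
the term's edf.

## Validation

Randomized 7:3 train/test splits at the haul level, stratified by presence
class with largest-remainder rounding, repeated (default 100, 20 in the
desk-scale pipeline). AUC uses the mid-rank formula (equal to the
pairwise P(score+ > score-) + half ties); Spearman is the Pearson
correlation of mid-ranks. The count-component correlation uses positive
test hauls only; the combined-model correlation includes zeros. Refits
re-select smoothing by default; a freeze option reuses the full-data
smoothing parameter.

## Aggregation, classification, persistence

Occupied units (cells with positive predicted CPUE, or hauls in the
empirical mode) are ranked by density descending (stable under ties) and
accumulated: x = cumulative area share, y = cumulative abundance share.
For equal-area units the slope of the k-th segment equals the k-th density
over the mean occupied density, so the slope-1 tangent corresponds
exactly to the mean occupied density — the module's primary oracle, and
the definition used by the `empirical` threshold mode.

The `cubic` mode follows the curve-fitting construction: a least-squares
cubic on the transition phase, operationalised as the run of points whose
local slope lies in [1/2, 2], widened symmetrically when fewer than four
points qualify. A wider bracket ([1/3, 3]) was evaluated against the
mean-density oracle and underfits on strongly aggregated fields (threshold
errors up to ~19% vs <= 8% for the tighter bracket), so [1/2, 2] is the
default; the bracket is an argument. The tangent solves
`3a x^2 + 2b x + c = 1` on the concave branch within [0, 1]; the threshold
density z* interpolates the ranked density profile at x*, using each
unit's upper area edge so tied densities never split between classes.
Uniform densities are degenerate (the curve is the diagonal): everything
is classified dispersed and the result is flagged.

Cells above z* form the aggregated class (1), others dispersed (0),
unoccupied cells nodata; persistence is the cellwise sum across years.
The precision statistic reports the percentage of occupied cells whose
quantile under the ranked density distribution lies outside +-0.025 of
the threshold position — cells outside that band would not flip under a
small threshold shift. (At the tangent the curve has slope 1, so an
abundance-share band of the same width coincides to first order.)

## Synthetic survey: what it emulates, and what not

The generator reproduces the structural features the pipeline must cope
with: two surveys with different tow durations (30 vs 60 minutes) and
gear intercepts; nine rectangular regions tiling the extent with
region/sex/year-varying logistic stage schedules; a coastline strip with
westward-deepening bathymetry and derived terrain; autocorrelated sediment
with a small rock fraction; yearly temperature/salinity fields; and
zero-inflated catches from Bernoulli presence x zero-truncated Poisson
counts with smooth covariate effects.

Key defaults (all config-exposed): stage length distributions N(15,3),
N(22,4), N(30,6) cm truncated at zero, overlapping enough that stage
decomposition is non-trivial; base L50 of 18/24/26 cm with slopes
-0.8/-0.5/+0.5 per cm; region offsets +-2 cm, sex +-0.4 cm, year +-0.8 cm;
gear intercepts (0, -0.5) for presence and (0, -0.4) for counts. The
"strong" presence surfaces use Gaussian-bump responses to depth,
temperature and shore distance with amplitudes set so that the
truth-score (Bayes) AUC is about 0.90 — computed from the generator alone,
so "strong signal" genuinely is strong. The "null" truth has constant
predictors and zero gear intercepts (a gear contrast is real signal that a
random intercept legitimately recovers, and would push a "null" AUC above
chance).

Raw catch counts are the standardized ZTP totals scaled back up by tow
duration, so 30-minute standardisation recovers them exactly; length
classes are multinomial draws from the stage length distribution. Label
draws use the true logistic at the drawn length, making every stage's
conditional membership curve exactly logistic — which is what lets L50
recovery be tested to +-0.5 cm.

Not emulated: realistic coastline geometry, oceanographic structure in
temperature/salinity beyond smooth trends and noise, spatial correlation
in catches beyond what the covariates induce, sex-structured catches
(length frequencies are unsexed), and observation-level overdispersion.
Passing tests therefore demonstrate correctness of the estimators under
the stated generating process, not robustness to the full messiness of
real survey data.

## Problem sizes

Desk-scale defaults keep the full pipeline to a few seconds and the whole
test suite to about a minute: a 20x30 grid (about 500 sea cells), 3 years
per season, ~200 hauls, 60 SMALKs per region-year, k = 8 spline bases and
20 CV iterations. Recovery experiments use larger, targeted sizes: 2000
SMALKs per region for L50, 5000 records per selection replicate, ~950
hauls for hurdle recovery, 10^4 draws for the ZTP moments, 2400-cell
density fields for the aggregation oracle (with fewer ranked units the
transition phase spans too few ranks and the tangent threshold inherits
rank-discretisation error — a known limitation of the cubic mode on very
small or extremely aggregated grids), and 100-120 casts for bandwidth
selection.

## Known limitations

* The global smoothing parameter trades per-term adaptivity for speed and
  determinism; mgcv-style per-term selection would be more flexible.
* The two-level random intercept is a fixed-ridge contrast, not a
  variance-component estimate.
* The ZTP count component requires integer counts; decomposed stage CPUE
  is rounded to the nearest fish before hurdle fitting.
* The cubic tangent threshold is reliable on smooth density fields with
  enough occupied cells (relative error <= ~8-10% against the mean-density
  identity); the empirical mode is exact and is preferred when the curve
  has few points.
* Haul positions are treated as points on the grid (nearest cell); no
  tow-path integration.
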