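# Methods

## Estimands

Let X be a Bernoulli indicator of service use (crude coverage) and Y a
facility readiness measure, estimated from two independent samples with
(effective) sizes n_x and n_y.  Within a stratum — one (region r, facility
type f) cell — effective coverage is the product of the two means,
p_rf = p_x,rf · p_y,rf.  Regionally p_r = Σ_f p_rf; since the facility-type
coverage proportions partition (at most) the population in need, the
package validates Σ_f p_x,rf ≤ 1 (tolerance 1e−9) and rejects tables that
violate it.  Nationally P = Σ_r w_r p_r with weights normalized on input —
callers may pass anything proportional to the regional denominators.

All proportions are derived from integer counts, never accepted as
pre-rounded decimals: the delta method needs the raw success/failure counts
for its logit intercepts, and count-based boundary detection (a cell with 0
or n successes) is exact where floating-point comparison is not.

Across strata and regions the three variance methods assume independence
(zero covariance).  This holds when both samples are stratified the same
way; where it fails the within-region covariance of stratum estimates is
typically negative, so ignoring it is conservative.  Covariance-aware
aggregation is out of scope.

## Exact (Goodman) variance

For independent Z and M,
Var(ZM) = (Var Z + (EZ)²)(Var M + (EM)²) − (EZ EM)² is an identity.  The
estimator plugs in the binomial variance p(1−p)/n and the observed
proportions:

    s²(p_rf) = [p_x(1−p_x)/n_x + p_x²][p_y(1−p_y)/n_y + p_y²] − p_rf².

Each bracket is at least the corresponding squared mean, so the result is
never negative (tiny negative round-off is clamped to zero).  With a
continuous readiness score the second bracket becomes s²_y/n_y + ȳ², where
s²_y is the sample variance of the score.  Aggregation under independence:
s²_r = Σ_f s²_rf and s² = Σ_r w_r² s²_r.  The interval is the symmetric
Wald interval p ± z·s with z = 1.96 fixed by default (other confidence
levels are accepted but 0.95 maps to the literal 1.96 for bit
compatibility).

Bounds are never clipped.  An interval is classified `degenerate` when the
point estimate is exactly 0 or 1 (classification is by the point estimate,
not by zero variance), `invalid_bounds` when a bound leaves [0, 1], and
`valid` otherwise.  Clipping is available for display only, so invalid
intervals remain countable.

The test suite checks the Goodman identity against exhaustive enumeration
of all (k_x, k_y) binomial outcomes for n up to 12 at 10 significant
digits.

## Delta method on the logit scale

With b = log(n₁/n₀) the intercept of an empty logit regression and
s_b = √(1/n₀ + 1/n₁) its standard error, the level target F = logit(p) is
expanded to first order in the per-stratum intercepts:

    Var(F) = Σ_strata ( g_x² s_bx² + g_y² s_by² ).

The chain rule through p_x = antilogit(b_x) gives, at the stratum level,
g_x = p_x(1−p_x)p_y / (p(1−p)) = (1−p_x)/(1−p) and symmetrically for g_y.
At region level the same numerators are divided by p_r(1−p_r); nationally
the numerators carry w_r and the denominator is P(1−P).  These expressions
are derived symbolically and gated on a central finite-difference oracle
(step 1e−6, relative tolerance 1e−5) over random interior points at every
level, rather than trusted as transcriptions.

The 95% interval is antilogit(F ∓ 1.96·√Var F): asymmetric about the point
estimate and always strictly inside (0, 1), so it can never be invalid.  It
is *undefined* exactly when a required logit is infinite — the product is 0,
or either observed proportion is 1 — detected from the count cells.
Per-stratum design-based logit-scale standard errors (from complex-survey
software) may be supplied as overrides in place of the simple-random-sample
closed form; the package itself implements no survey machinery.

For a continuous readiness score the logit machinery applies only to the
coverage factor; the score mean enters the expansion on the natural scale:

    Var(F) = ((1−p_x)/(1−p))² s_bx² + (p_x/(p(1−p)))² · s²_y/n_y,

with p = p_x·ȳ.  This natural-scale expansion is a design choice validated
against the internal finite-difference oracle (the alternative — a logit
transform of the score mean — has no count-based standard error).

## Parametric bootstrap

Per stratum: draw B pairs Binomial(n_x, p_x)/n_x and Binomial(n_y, p_y)/n_y,
multiply elementwise, and take the 2.5th/97.5th percentiles of the products
(B = 10 000 by default).  Quantiles use linear interpolation between order
statistics (Hyndman–Fan type 7), recorded in the config; at B = 10 000 the
convention shifts endpoints by under 1e−3.  Continuous readiness replicates
are means of n_y Beta(α, β) draws with α, β matched to the observed score
mean and variance (support on [0, 1] makes Beta the natural choice; the
moments must satisfy s²_y < ȳ(1−ȳ)).  Percentile bounds cannot leave
[0, 1]; the interval is degenerate iff the observed product is 0 or 1.  The
non-parametric bootstrap is deliberately not implemented (it shows
consistent undercoverage for this target and, for a binary simple random
sample, resampling the data coincides with the parametric binomial scheme
anyway), and the bootstrap is defined per stratum only.

## Simulation study

`run_setting` simulates, for one (P_x, P_y, n_x, n_y) cell, `reps` simple
random samples, builds all requested intervals and tallies the estimated
coverage probability — the fraction of intervals containing the true
product P_x·P_y.  Removal rules are method-specific, so one iteration can
count for one method and be removed for another:

- exact and bootstrap remove *degenerate* iterations (product estimate
  exactly 0 or 1);
- delta removes *undefined* iterations (product 0, or either observed
  proportion 1 — i.e. any empty/full count cell);
- exact intervals with a bound outside [0, 1] are counted as *invalid*
  among the non-degenerate iterations but still count as covering when they
  contain the truth (the only accounting consistent with total conditional
  coverage co-occurring with total invalidity at the most extreme setting).

The standard grid crosses 25 true proportions (0.02–0.98) for each factor
with 11 sample-size pairs (equal sizes 50–500 and unequal pairs n_y = 50).
Default replicates per setting: 10 000, giving a Monte-Carlo standard error
of at most 0.005 on a coverage probability (±2 percentage points is a
comfortable check for a single cell; grid extrema, being maxima/minima over
625 cells, get ±3).

Reproducibility: each setting derives an RNG substream from
SeedSequence(master seed, setting parameters), so any subset of the grid
reproduces the matching cells of a full run and rerunning with the same
master seed reproduces the table bit-for-bit.  The inner bootstrap draws
from a second per-setting substream; since the percentile CI is a pure
function of the observed counts, iterations with the same (k_x, k_y) are
deduplicated and resampled once, which cuts the only expensive loop without
changing what is estimated.  The inner-bootstrap size is independently
configurable; the bundled acceptance script runs the bootstrap grid at
1 000 replicates × 1 000 resamples, with the correspondingly widened
tolerance, and the other grids at full 10 000 replicates.

Continuous-readiness simulation draws facility scores from a Beta law with
mean P_y and variance 0.5·P_y(1−P_y) (half the Bernoulli variance) — a
moderately dispersed bounded score; the dispersion fraction is a recorded
config field.

### What the synthetic data do and do not show

The generator (both the simulation sampler and the fixture tables) draws
*simple random samples* with exact binomial/Beta laws and independent
strata.  Passing tests therefore demonstrate the correctness of the
estimators and the coverage behaviour of the intervals under the stated
model; they do not speak to complex-survey effects (clustering, weighting,
non-response), to correlation between facility types within a region, or to
misclassification in either measure.  Effective sample sizes and
design-based logit SEs can be supplied to approximate complex designs, but
the precise coverage levels under such designs may differ somewhat.

## Numerical choices and degenerate inputs

- antilogit is computed in the numerically stable branch form; logit-scale
  half-widths arising from real tables keep bounds strictly inside (0, 1)
  in double precision.
- Goodman variance clamps negative round-off to 0.
- Boundary detection for degenerate/undefined classification uses integer
  counts, never float equality.
- Region weights of zero are allowed (the region drops out); all-zero
  weight vectors are rejected.
- A continuous score's sample variance is validated against the maximum
  possible for a [0, 1]-supported variable with the given mean.

## Known limitations

- No covariance between strata: variances at region/national level are
  conservative when the true within-region covariance is negative and
  anti-conservative if it were positive.
- The bootstrap is stratum-level only; no bootstrap for aggregated levels
  or complex designs.
- The delta method cannot produce an interval when a count cell is empty or
  full; such strata yield `undefined` results rather than an arbitrary
  continuity correction.
- Finite-population corrections are not applied.
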