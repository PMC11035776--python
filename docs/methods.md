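# Methods

## Setting and notation

A two-arm randomized trial with a non-negative continuous outcome
(duration in days, half-day resolution supported).  In potential-outcome
notation a unit has an untreated duration X and a treated duration X*;
only one is revealed.  Randomization makes the control arm's empirical
distribution a consistent estimate of the marginal law of X and the
treatment arm's of X*.  Everything below is a functional of these two
marginals except the individual-level effect distribution X − X*, which
depends on the unidentified joint law and is only *bounded* here.

Sign convention: effects are reported as reductions, `Q₀(p) − Q₁(p)` and
`X − X*`, so a treatment that shortens illness has positive effects.  The
treated-minus-untreated convention is always recoverable since both arms'
quantiles are stored.

## Estimators

**Empirical quantiles.**  Default is the left-continuous inverse ECDF,
the order statistic `x₍k₎` with `k = ⌈p·n⌉`.  Rationale: the estimation
procedure is naturally stated on ordered observations, and on the
midpoint grid with equal arms it makes mean(QTE) = ATE an exact identity.
A `linear` (interpolated) estimator is available as an option.  Ties and
flat segments from (half-)day rounding are kept as-is — no jittering;
flat segments are the truth of the ECDF.

**Grid.**  Midpoint levels `pᵢ = (i − ½)/m`, with `m = n₀` (control arm
size) by default.  Control anchoring keeps one level per control order
statistic, which the back-transformation needs.  Unequal arm sizes are
handled by evaluating both quantile functions on this common grid; no
truncation or resampling.

**QTE curve.**  `reduction(p) = Q₀(p) − Q₁(p)` at each grid level.  For
equal arms on the midpoint grid this equals sorting both arms and
differencing element-wise (property-tested exhaustively).

**BQTE curve.**  Re-indexes the QTE by untreated duration.  With
day-resolution data many grid levels map to one observed control duration
d; the BQTE at d is the *mean* of the QTE over that whole block of levels
(any single-level choice inside the block would be arbitrary; the block
mean is the ECDF-consistent summary, and the support count per duration
is reported).  Between observed durations: linear interpolation.  No
extrapolation outside the observed control range — a request outside it
raises a range error.

**UTBQTE.**  For threshold t, let `k₀` be the number of control outcomes
≥ t (closed tail, "t days and longer") and `k₁ = round(k₀·n₁/n₀)`
(half-up, clamped to ≥ 1; floor/ceil configurable).  The effect is
mean(top-k₀ control) − mean(top-k₁ treatment).  This matched-tail
contrast compares the two *marginal* tails and therefore makes no
assumption about rank preservation.  It is this package's reading of an
"upper-tail average effect"; note the two possible directional readings —
as an upper bound on how much an effect concentrated in the tail can be
diluted, or (when effects grow with duration, as in the worked example) a
lower bound on the tail units' own benefit — depend on the shape of the
effect map and are deliberately not resolved by the code: the estimate is
reported with its bootstrap interval and both readings documented here.
At the minimum control value the tail is the whole sample and the UTBQTE
equals the ATE whenever the proportional rounding is exact (always, for
equal arms).

**Extreme couplings.**  Both arms' quantile functions are evaluated on
the midpoint grid and paired (Q₀(pᵢ), Q₁(pᵢ)) (order preserved /
comonotonic) or (Q₀(pᵢ), Q₁(1 − pᵢ)) (order reversed /
countermonotonic).  Computing r on grid pseudo-observations rather than
raw values handles unequal arms; for equal arms with m = n it reduces to
pairing sorted raw values.  By the rearrangement inequality the preserved
coupling attains the maximum Pearson r and the minimum variance of the
paired differences over *all* possible joints with these margins, the
reversed coupling the opposite extremes (verified against exhaustive
enumeration of all n! pairings in the tests).  Both couplings leave the
margins untouched, so the mean effect is coupling-free; the variance obeys

    var(X − X*) = v + v* − 2 r √(v·v*)

with exact closed forms (√v − √v*)² at r = +1 and (√v + √v*)² at r = −1.
The API reports both the *empirical* extreme correlations (preserved /
reversed r for the data at hand) and the *mathematical* variance limits
at r = ±1; they answer different questions and are named distinctly.  If
an arm has zero variance, r is undefined and a `degenerate_variance`
status is returned instead of a number.

**Bounds at a duration.**  The preserved-coupling BQTE and the analogous
reversed-coupling back-transformed curve (block-averaged and interpolated
identically) give the two attainable extremes of the expected
individual-level reduction at each untreated duration.  Above the median
of a beneficial treatment the reversed value is the larger one; below it
the roles swap — the pair is therefore returned both by name and sorted
as (min, max).

## Inference

Percentile bootstrap, stratified by arm (arms are independent samples in
an RCT): each replicate resamples each arm with replacement, re-evaluates
the estimator at the *original* grid levels / durations / threshold, and
pointwise `(1 ± level)/2` empirical percentiles form the band.
Percentile rather than BCa: the simplest defensible default for a
quantile-based, tie-heavy estimator.  Replicate j draws from an RNG
seeded by `(seed, j)`, so results are bit-reproducible and increasing
`n_boot` extends the replicate sequence without reshuffling earlier ones.
A replicate whose resampled control range misses an evaluation point (or
whose tail is empty) contributes a missing value there; bands use the
non-missing replicates and any point missing in more than half of them is
flagged.  Bands are pointwise, not simultaneous.

## Synthetic-trial generator

The generator draws *paired* potential outcomes so the hidden joint is
available to tests:

1. latent standard-normal pairs with correlation `rank_rho` (Gaussian
   copula — one parameter spans fully reversed ranks at −1, independence
   at 0, exact rank invariance at +1; the Cholesky factor is written out
   explicitly so ±1 are exact);
2. both coordinates pushed through the untreated marginal's inverse CDF —
   gamma (default shape 4, rate 0.5 d⁻¹: mean 8 days, right-skewed,
   cold-like) or negative binomial (integer days);
3. the treatment coordinate transformed by a monotone effect map on the
   duration scale: `shift(c)` (constant reduction, clamped at 0),
   `scale(s)` (proportional), or `piecewise` (reductions interpolated
   linearly between knots, flat outside; validated to keep
   d − reduction(d) non-decreasing).  Applying the map to the quantile of
   the *control* marginal gives the population QTE in closed form
   (`true_qte`), independent of `rank_rho` — the identification property
   the QTE rests on;
4. optional rounding to a whole- or half-day lattice (default half-day);
5. complete randomization: a random permutation splits units into the two
   configured arm sizes and each unit reveals one potential outcome.

Defaults: 100 units per arm, `Shift(2.0)` days, `rank_rho = 1`, half-day
rounding.  What the generator does *not* emulate: censoring or dropout,
covariates, noncompliance, measurement error beyond rounding, or
non-Gaussian-copula dependence (the extremes ±1 are exact, intermediate
dependence is one particular interpolation).  Tests passing on this
generator therefore demonstrate the estimators' internal coherence and
sampling behavior under a clean RCT, not robustness to those real-data
complications.

## Numerical choices and degenerate inputs

- Quantile levels restricted to the open interval (0, 1); empty arms,
  negative or non-finite outcomes rejected at construction with named
  errors; arms need ≥ 2 observations for estimation.
- The variance identity is exact in exact arithmetic; tests assert it to
  1e-9.  ATE/QTE consistency is exact at the level of sums for
  integer-valued data (a single float division separates the means).
- Population-level `true_qte` is computed before rounding; lattice
  effects are a finite-sample feature.
- Problem sizes in the test suite and acceptance script (10⁴ per arm for
  identification checks, 500 × n = 200 trials with 400 bootstrap
  replicates for coverage, exhaustive n! enumeration up to n = 6) were
  chosen to make Monte-Carlo error small relative to the tolerances while
  keeping a full run around half a minute.

## Known limitations

- No covariate adjustment, quantile regression, censoring support, or
  more-than-two-arm designs.
- The BQTE curve is not smoothed or monotonized; with heavy ties it is a
  step-and-interpolate curve.
- Bootstrap bands are pointwise percentile bands; simultaneous bands and
  hypothesis tests are out of scope.
- Intermediate (non-extreme) couplings appear only in the simulator, not
  as estimators.
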