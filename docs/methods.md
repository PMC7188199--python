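# Methods

This note documents the statistical content of `nldrkit`: the model, the
estimators, the numerical conventions, what the synthetic generator does
and does not emulate, and the design choices made where more than one
convention was defensible.

## The discriminant rule

The workload predictor is a two-class Gaussian classifier with a shared
covariance matrix.  Donors are split into an easy group G₀ and a
difficult group G₁ by operative time at a threshold τ (inclusive: time ≥
τ is difficult).  With group means μ₀, μ₁, shared covariance Σ and
empirical priors πᵢ = nᵢ/(n₀+n₁), the discrimination index of a feature
vector **x** on the chosen predictor subset is

Ω(x) = log(π₁/π₀) − ½[Δ(x; μ₁, Σ) − Δ(x; μ₀, Σ)],  Δ(x; μ, Σ) = (x−μ)ᵀΣ⁻¹(x−μ).

Ω > 0 predicts difficult.  Ω = 0 is a measure-zero tie and resolves to
easy, fixed for determinism.  Because the two quadratic forms share Σ,
Ω is affine in x — Ω(x) = log(π₁/π₀) + wᵀx − ½wᵀ(μ₀+μ₁) with
w = Σ⁻¹(μ₁−μ₀) — which the implementation exploits (one Cholesky solve
per fit) and the test suite verifies against the quadratic form directly.
Ω is invariant under any invertible affine map of the features, so the
variables are used in their native clinical units and never standardized.

**Covariance estimator.**  Two conventions are implemented because the
phrase "covariance of all the feature vectors from both groups" is
ambiguous between them:

- `pooled` (default): Σ = [(n₀−1)S₀ + (n₁−1)S₁]/(n₀+n₁−2), the classic
  within-group pooled estimate and the standard choice for this rule;
- `total`: the sample covariance of all vectors from both groups
  combined, which additionally contains the between-group mean shift.

Every fitting entry point accepts `covariance_mode`; results tables can
be produced under both (`scripts/reproduce_published.py` prints both).

**Singularity.**  A subset whose covariance slice is not positive
definite (constant column, duplicated variable, degenerate resample) is
an explicit error — no silent pseudo-inverse.  An optional ridge term
ε·I (default ε = 0) exists for deliberately degenerate synthetic tests.

## The workload threshold

The default threshold is 210 min.  On the reference cohort this is the
84.1th percentile of operative time — the mass below mean + 1 SD under a
normal model, since Φ(1) ≈ 0.8413.  Percentile thresholds elsewhere in
the package (the sweep module) use linear interpolation between closest
order statistics, the common "linear" convention; the convention only
matters for the sweep because the primary dichotomization is a fixed
minute value, not a recomputed percentile.  The sweep covers the 2nd–98th
percentile in steps of 1 by default, refits the rule at each cut, and
records thresholds whose groups drop below two members per class as
`skipped` rather than interpolating them.

## Hit rates

Predictions vs labels form the 2×2 table (A = predicted difficult &
difficult, B = predicted difficult & easy, C = predicted easy &
difficult, D = both easy).  Five rates, reported in percent:

| rate | formula | reading |
|---|---|---|
| HRDC | A/(A+B) | how often a "difficult" call is right |
| HREC | D/(C+D) | how often an "easy" call is right |
| sensitivity | A/(A+C) | difficult cases caught |
| specificity | D/(B+D) | easy cases passed |
| total | (A+D)/n | overall accuracy |

A rate with a zero denominator is undefined and reported as `None`,
never as 0 or 100.  The HRDC/HREC naming follows the published rate
columns (which back-calculate uniquely to these formulas from the group
sizes), not the prose that pairs them with PPV/NPV the other way around.

## Subset search and the selection funnel

All 2¹⁶ − 1 = 65,535 non-empty predictor subsets are evaluated on the
training data.  The sufficient statistics (group means and the full
16×16 shared covariance) are computed once; any subset's statistics are
slices of them, so each subset costs one small linear solve plus a
mat-vec, batched across same-size subsets.  Results are emitted in
ascending bit-mask order (bit 0 = sex, … bit 15 = subcutaneous-fat area)
regardless of execution batching, so identical inputs give byte-identical
tables.  Singular subsets are recorded with status `singular`, not
dropped.

The best-apparent *tier* is the set of subsets whose predictions produce
the identical 2×2 table as the best subset (the strict tie); the looser
same-total-rate tier is reported alongside.  When several distinct
tables share the maximum total rate, the table of the lowest-mask subset
is the representative — a deterministic convention that matters only in
contrived ties.

The final model is selected by a three-stage funnel:

1. exhaustive search → best-apparent tier;
2. leave-one-out cross-validation of the tier; survivors are subsets
   whose CV total is within `cv_band_pp` (default 1.6 percentage points)
   of the best;
3. the .632 estimator on the survivors; the highest estimated total wins,
   ties broken by fewer variables, then lower mask.

The 1.6-pp default for the stage-2 band corresponds to the published
funnel's survivor band (best CV total 96.1% vs survivors down to 94.5%
on the original cohort) and is exposed in the run config.

## True-hit-rate estimators

**Leave-one-out cross-validation.**  Each donor is predicted by the rule
fitted to the other n−1; the n held-out predictions are pooled into one
2×2 table.  Fully deterministic.  "Cross-validation" is interpreted as
leave-one-out — the standard in the discriminant-analysis literature —
and fold-based CV is deliberately not offered, to avoid an untestable
free parameter.

**.632 bootstrap.**  B resamples of size n with replacement (default
B = 200, classic practice; the seed is mandatory).  Resamples with fewer
than `min_group` = 2 members of either class, or whose subset covariance
is singular, are redrawn with a counted budget.  The rule fitted to each
resample predicts only its out-of-bag donors; out-of-bag predictions are
pooled across replicates into one table before computing rates (pooling
is stabler than averaging per-replicate rates when the difficult class is
rare), then combined rate-wise:

    r(.632) = 0.368 · r(apparent) + 0.632 · r(out-of-bag).

Inside the funnel all survivors share the same resamples, so their
estimates differ only through the subsets, not through Monte-Carlo luck.

On no-signal data the apparent total exceeds the majority-class share
while LOOCV does not — the optimism these estimators exist to correct;
the test suite checks this calibration over 20 seeded null cohorts.

## Association statistics

- OLS of operative time on each predictor alone and on all 16 jointly
  (with intercept, no stepwise selection), two-sided t-tests on slopes;
  fitted through statsmodels.
- Pearson and Spearman screens per predictor against operative time or
  the complication rank; Spearman uses average ranks for ties.
- Extremes comparison (≥ 240 min vs ≤ 100 min): two-sided Mann-Whitney U
  for continuous/ordinal variables, Fisher's exact test for binary ones;
  externally computed columns (e.g. the discrimination index) can join
  the comparison.
- Complication grades use the modified Clavien scale for donor
  nephrectomy encoded as ordered ranks (0 < 1 < 2a < 2b < 3a …); grade 0
  (no complication) is included in rank correlations.
- Complications across quartiles of perinephric-fat area are tested with
  the Freeman–Halton extension of Fisher's exact test (complete
  enumeration over tables with the observed margins; the two-sided p sums
  the multivariate-hypergeometric probability of tables no more probable
  than the observed one).  The implementation is hand-written — SciPy
  only provides the 2×2 case — and is cross-checked in the tests against
  a seeded Monte-Carlo version and, during development, against R's
  `fisher.test`.

## Synthetic cohort generator

The generator emulates the *statistical shape* of the reference cohort
so every module is testable without patient data:

- marginal means/SDs/ranges of the 14 continuous predictors as published
  (e.g. operative time 159.1 ± 47.4 min; perinephric-fat area
  14.39 ± 10.98 cm²; fat CT value −83.98 ± 12.17 on its native negative
  scale);
- sex from a latent normal thresholded at the 58/128 male fraction,
  letting it correlate with perinephric-fat area (latent r = 0.3);
- renal-artery count categorical on {1,2,3,4} with probabilities
  (86, 32, 7, 3)/128;
- plausible latent correlations: weight–height 0.6, weight–subcutaneous
  fat area 0.5, 0.6 pairwise among the perinephric thickness/area
  variables, fat area–fat CT value −0.4.  These are declared assumptions
  (the source tables print no correlation matrix) and are config-exposed;
  a non-positive-definite user map is repaired to the nearest valid one
  with a warning;
- operative time = 83 + 3.2·areaPNF + 21·numberRA + N(0, 28²) minutes,
  clipped below at 90.  The slopes are the published univariate
  magnitudes; the intercept and noise SD were derived analytically from
  the published time mean/SD so that the 210-min difficult fraction is
  ~16% (the 21/128 study split).  The measured population fraction is
  16.5%; single 128-donor cohorts scatter binomially around it
  (SE ≈ 3.3 pp);
- complication grades with overall probability 12/128 and a weak logistic
  dependence on the subcutaneous-fat variables (surgical-site events
  track abdominal-wall fat), independent of the workload index by
  construction.

Truncation is by rejection within the published ranges.  Because some
ranges cut one tail more than the other (the fat-area lower bound sits at
z ≈ −1.2), rejection shifts the realized means slightly above the
configured ones (realized mean time ≈ 172 min vs the 159 configured);
this bias is inherent to bounded marginals and is documented rather than
compensated.  What passing tests on synthetic cohorts do *not* show:
real donors are not multivariate normal, operative time is not exactly
linear in its drivers, and the true inter-variable correlations are
unknown — the generator validates the machinery and its statistical
calibration, not clinical transportability.

## Numerical and interface conventions

- All randomness flows through `numpy.random.default_rng(seed)`; seeds
  are explicit everywhere (bootstrap config, generator config, CLI).
- Covariance factorizations use Cholesky; a failed factorization is the
  singularity signal.
- Rates are kept at full precision internally and rounded to one decimal
  only for display.
- Model files are JSON (subset, means, covariance, priors, mode,
  training metadata) and round-trip exactly; cohort CSVs are written at
  full precision (`%.17g`) and round-trip bit-identically.
- Records with any missing predictor are excluded from fitting with a
  warning; there is no imputation.
- Column headers resolve through a canonical snake_case registry plus
  the short clinical aliases (`Bw`, `Ht`, `TP`, `numberRA`, `areaPNF`,
  …); a YAML run config can add source-specific aliases, change the
  threshold, and set the validation parameters.

## Known limitations

- The funnel's stage-2 band is a rule here; whether the original
  analysis used a fixed band or a post-hoc description is not decidable
  from the published text.  The band is a config knob.
- Published fat areas are printed in cm² in the summary table but mm² in
  parts of the discussion; the canonical unit here is cm² and values are
  consumed unchanged.
- With ~21 difficult cases, per-class rates (HRDC, sensitivity) have
  wide sampling error; the .632 estimator inherits Monte-Carlo noise on
  top (±0.5 pp on the total at B ≈ 1000 is typical).
- The quartile complication test enumerates exactly for realistic
  complication counts; very large counts fall back to seeded
  Monte-Carlo, reported as such.
- No quadratic discriminant, logistic regression, alternative
  classifiers, .632+ estimator, or k-fold CV: the scope is the NLDR
  pipeline and its validation as specified.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run entirely on synthetic
cohorts of n = 60–128 (plus one 50,000-donor draw to measure the
generator's population fraction), B = 100–1000 bootstrap replicates, and
the full 65,535-subset search; the whole suite completes in well under
two minutes on one core.
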