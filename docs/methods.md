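# Methods

## Indicator definitions and person-level classification

Vision is handled on the 5-level ordinal scale used by rapid eye-health
surveys (can see 6/12; <6/12–6/18; <6/18–6/60; <6/60–3/60; <3/60), because
the indicator thresholds are exactly these category cut points; no finer
acuity scale is modelled.  Every comparison is one-sided against a named
Snellen cut — "strictly worse than" for surgical need (BCVA) and "at or
better" for a good outcome (presenting VA) — and a missing value satisfies
neither, so missingness can only remove a person from a count, never add
one.

A person is *operated* if at least one eye is pseudophakic or aphakic.  An
eye is *operable* if it is phakic with cataract, its BCVA is worse than the
surgical threshold and (by default) cataract is recorded as the principal
cause of impairment; the cause requirement is a configuration flag because
field data sometimes attribute the impairment of a cataractous eye to
comorbidity, and analysts differ on whether such eyes represent unmet
surgical need.  The denominator is operated people plus unoperated people
with at least one operable eye.  The eCSC numerator takes the **presenting**
VA of the **better operated eye** against the outcome threshold.

Two readings of the unilateral rule are implemented and always labelled in
output: `ALL_OPERATED` (default) counts every person with an operated eye
in the CSC numerator; `FELLOW_IMPAIRED_ONLY` counts unilaterally operated
people only when the unoperated fellow eye has BCVA worse than the surgical
threshold.  Under the second rule a fellow eye whose impairment cannot be
observed (missing BCVA) leads to conservative exclusion, and the exclusion
is counted.  The rules only differ for unilateral cases whose fellow eye is
healthy or unobservable, so `FELLOW_IMPAIRED_ONLY` numerators are a subset
of `ALL_OPERATED` numerators.

Missing data policy (a package decision; field practice varies and is
rarely reported): a participant with missing lens status in both eyes is
excluded from every count; an operated participant with no observable
postoperative presenting VA stays in the denominator and the CSC numerator
but is excluded from the eCSC numerator.  Both exclusion counts are
reported with every tally so the analyst can audit their impact.

## Estimation

Counts are tallied per (cluster × sex × age band) cell.  Post-stratification
multiplies each stratum's counts by `w_s = N_s / n_s` (census population
over number examined), which standardises the estimate to the age-sex
structure of the survey area; sex-restricted estimates use only that sex's
strata (age adjustment within sex).  A stratum with census population but
no examined participants has no factor; its population is folded into the
adjacent age band of the same sex (toward younger, else older), conserving
the census total — or the run can be configured to fail hard instead.

The standard error is the classical ratio-estimator variance over cluster
totals, `se(r) = 100·sqrt(c/(c−1)·Σ(y_i − r·x_i)²)/Σx_i`, algebraically
identical to `(1/x̄)·sqrt(Σresid²/(c(c−1)))`.  Weights are applied at the
participant level before summing within cluster, so the SE reflects both
weighting and clustering; clusters with no denominator members contribute
(0, 0) pairs and stay in `c`, since the cluster count is a design property.
CIs are `value ± 1.96·se`, clipped to [0, 100]; no transformation is
applied.  Internal arithmetic is double precision; published-style tables
round to one decimal.

The multiplier direction deserves a note: descriptions of this adjustment
sometimes phrase the factor as "examined over population", but that
multiplier would weight strata by their sampling fraction, the inverse of
standardisation.  This package uses population-over-examined and stamps
`weight_direction="population/examined"` on every estimate so the
convention is explicit in output.

## Country selection, pooling, meta-analysis

The country decision tree is a pure function of survey metadata: any
national estimate (single national survey, or a declared series of
subnational surveys pooled first — series membership is metadata, never
inferred) wins, most recent first, ties broken by larger sample then
lexicographic survey id; otherwise the most recent subnational survey is
pooled with every subnational survey completed within 3 years before it,
boundary inclusive (2019 pools with 2016).  Subnational pooling is
fixed-effect inverse variance (`u_k = 1/se_k²`), which keeps the pooled SE
no larger than any contributing SE; zero-variance estimates are rejected
with a diagnostic.  Grouped summaries report median and IQR using linear
interpolation between order statistics (the numpy/R type-7 default, stated
here because quantile conventions differ), plus range, group size and year
span.

Sex disparities are risk differences (percent scale; the CI widths this
yields match how such gaps are conventionally reported) and risk ratios
(pooled on the log scale with delta-method SEs) between male and female
estimates that are age-adjusted within sex.  Across surveys the effects are
combined by DerSimonian–Laird random effects:
`tau² = max(0, (Q − (k−1))/(Σu − Σu²/Σu))`, random-effects weights
`1/(se² + tau²)`, normal-approximation CI.  DL is the historical default of
the standard meta-analysis packages; other tau² estimators are out of
scope.  Surveys with a zero sex-specific numerator are excluded from RR
pooling with a diagnostic rather than continuity-corrected.

## Synthetic data generator

The generator emulates the frame such surveys sample from: adults 50+
partitioned into clusters (default 400), with per-age-band probability of
bilateral operable cataract (5%, 12%, 25%, 40% from the youngest to the
oldest band), a configurable fraction of unilateral need (30%), and
surgical access given need driven by a logistic model with a base log-odds,
a male offset, an age-band gradient, and a Normal cluster random effect
whose variance is set from the target intra-cluster correlation via the
latent-logistic identity `sigma² = rho/(1−rho)·π²/3`.  Operated people
achieve a good (6/18) better-eye presenting outcome with probability
`p_good_outcome` (default 0.75, so the census relative quality gap is close
to 25%); eye-level VA categories are then drawn from fixed conditional
distributions spanning all categories, which is what spreads eCSC across
the four surgical thresholds.  A small aphakia probability, residual
operable fellow eyes after unilateral surgery, and non-cataract bilateral
impairment keep every classification branch populated.

Defaults describe the study conditions the test-bed targets: ~270k people
in the frame, samples of 50 clusters × 60 participants (≈3000, the typical
size of these surveys), access calibrated so census eCSC is close to 40%
and the male–female eCSC gap close to 3 percentage points (the realised
roster values carry Monte-Carlo noise of a few tenths of a point), rho =
0.05.  Real cluster sizes and ICCs are not published for these surveys;
these defaults are plausible placeholders and are labelled as such.

Ground truth is never taken from the configuration: it is enumerated by
classifying every roster member (a census), so estimator checks compare
against exact finite-population truth.  Sampling is two-stage — simple
random sampling of clusters, then of persons within cluster, both without
replacement.  All randomness flows from one root seed through named
`SeedSequence` spawn keys (`[seed, 0]` for the population, `[seed, 1, k]`
for survey replicate k), so population and each survey are independently
reproducible.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: probability-proportional-to-size cluster
selection, within-household sampling and non-response, VA measurement
error, secular trends in surgical quality, and correlation between access
and outcome quality.  Estimator calibration results transfer to field data
only to the extent the design assumptions (many clusters, small sampling
fractions) hold there.

## Numerical and calibration notes

* Ordinal comparisons are strict and total; no ties are possible.
* A zero weighted denominator yields an undefined-estimate error, never 0%
  or 100%; `quality_gap` is undefined at CSC = 0 and rejects eCSC > CSC.
* The quality gap is computed as `100·((CSC − eCSC)/CSC)` so a zero eCSC
  gives exactly 100.
* Fewer than two clusters is a design error at survey construction.
* In simulation at the default conditions the ratio-estimator SE tracks a
  2000-replicate cluster bootstrap within a few percent, and 95% CI
  coverage of the census truth sits near 94%: sampling many clusters from a
  finite roster of 400 and estimating stratum weights leaves the intervals
  very slightly anti-conservative there, within the 93–97% band the test
  suite asserts.  These are properties the acceptance script recomputes,
  not assumed constants.
* Simulation problem sizes used by the tests (27k-person rosters for unit
  checks, the 270k default for calibration, 500 coverage replicates, 50
  meta-analysis surveys, 2000 bootstrap replicates) were chosen to make
  Monte-Carlo error small relative to the tolerances asserted.

## Known limitations

Eye-level coverage indicators, spectacle/refractive coverage, small-area
estimation, finite-population corrections, design-effect diagnostics beyond
the SE, meta-regression and publication-bias diagnostics are out of scope.
Native survey-software export dialects are not parsed; a column-mapping
hook translates external headers to the canonical schema.  WHO-region and
income-group assignment is a metadata input, not a lookup.
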