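# ecsc — cataract surgical coverage from population survey data

`ecsc` estimates **cataract surgical coverage (CSC)** and **effective
cataract surgical coverage (eCSC)** from individual-participant records of
RAAB-style population eye surveys (two-stage cluster samples of adults aged
50 and older), for epidemiologists and eye-health programme analysts who
need quality-adjusted service-coverage indicators.

## The indicators

A person with at least one **operated eye** (pseudophakia or aphakia) has
accessed cataract surgery.  A person with an unoperated **operable
cataract** — cataract with best-corrected visual acuity (BCVA) worse than a
surgical threshold *s* — still needs it.  With a good-outcome threshold *o*
on the presenting visual acuity (PVA) of the better operated eye:

```
CSC  = operated / (operated + operable at s)
eCSC = operated with better-eye PVA >= o / (operated + operable at s)
relative quality gap = 100 x (CSC - eCSC) / CSC
```

The default configuration uses 6/18 for both thresholds; 3/60, 6/60, 6/18
and 6/12 surgical cuts and 6/18 or 6/12 outcome cuts are supported, as is
an alternative rule restricting unilaterally operated people to those with
an impaired fellow eye.

Estimates are **post-stratified** to the census age-sex structure of the
survey area (eight strata: male/female × 50–59, 60–69, 70–79, ≥80; stratum
factor `w_s = N_s / n_s`) and carry cluster-design standard errors from the
ratio-estimator variance over weighted cluster totals `(y_i, x_i)`:

```
se(r) = 100 · sqrt( c/(c−1) · Σ_i (y_i − r·x_i)² ) / Σ_i x_i ,   r = Σy/Σx
```

with normal-approximation 95% CIs clipped to [0, 100].  The package also
implements the country-level workflow: a metadata-driven decision tree
(most recent national estimate, else subnational surveys pooled over an
inclusive 3-year window by fixed-effect inverse-variance weighting), grouped
median/IQR summaries, and DerSimonian–Laird random-effects meta-analysis of
male–female risk differences and risk ratios.

A synthetic-data module generates full populations with known, enumerable
truth and samples RAAB-scale two-stage cluster surveys from them, so every
pipeline stage is testable without access-controlled survey data.

## Worked example

Simulate a down-scaled survey (1200 participants, 30 clusters) and estimate
coverage:

```bash
ecsc simulate --small --seed 7 --out demo
ecsc estimate --survey demo/survey.csv --population demo/population.csv \
              --meta demo/meta.yaml --out demo/estimates.csv
```

`demo/truth.json` records the census truth enumerated from the full
synthetic roster: CSC 53.3%, eCSC 40.0%, quality gap 25.0%.  The estimates
file contains the design-based estimates from the 1200-person sample:

```
indicator sex  value  se  ci_low  ci_high  n_examined  n_clusters
      CSC ALL   48.8 4.3    40.4     57.1        1200          30
     eCSC ALL   35.9 4.6    26.9     44.9        1200          30
     eCSC   F   37.7 4.9    28.1     47.3         610          30
     eCSC   M   33.7 6.5    21.0     46.4         590          30
```

Read: the sample's age-sex-adjusted eCSC is 35.9% (95% CI 26.9–44.9),
covering the true 40.0%; about one in four people who accessed surgery did
not reach the 6/18 presenting-acuity outcome (gap 25%); men and women are
estimated separately (age-adjusted within sex) for disparity analysis.
`ecsc run --config run.yaml` drives the full multi-survey pipeline
(estimates, country selection/pooling, grouped summaries, threshold matrix,
sex-gap meta-analysis) and writes provenance-stamped tables.

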