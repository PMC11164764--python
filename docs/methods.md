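# Methods

## The stage-given-age model

Ossification of the medial clavicular epiphyseal cartilage is staged on the
nine-category ordinal scale 1 < 2a < 2b < 2c < 3a < 3b < 3c < 4 < 5, from no
ossification center to complete epiphyseal fusion.  Reference studies report,
per sex and stage, the mean age M(s) and SD of age among staged individuals.
`clavage` treats each (sex, stage) case group as a normal age distribution
and inverts it pointwise: for a true age x, the probability of presenting
stage s is the normal density evaluated at x, normalized over the stages
present,

    p_s(x) = N(x; M_s, SD_s) / sum_t N(x; M_t, SD_t).

The normalization uses the density at the exact (real-valued) age, not an
integral over an age interval.  Ages derived from dates use 365.25
days/year and are never rounded internally.

Three assumptions make this a *best-case* model of reference-study
assessment: the reference statistics are representative of the evaluated
population; age within each stage is normal; staging is error-free.  Under
them, a reader who predicts M(s) for an individual of age x incurs expected
absolute error

    AE(x) = sum_s p_s(x) * |x - M_s|,

a convex combination of the distances to the stage means, hence bounded by
the nearest and farthest mean.  The cohort-level bound is the plain mean of
AE over members (plus the SD of the per-member values).  No age prior enters:
AE conditions on the true age, so it is a per-age lower bound, not a
Bayesian posterior summary.

### Numerical choices

- Densities are computed in log space and normalized after subtracting the
  maximum, so stages whose densities underflow a float64 do not poison the
  normalization.  If the age is more than 10 SD from *every* stage mean the
  model raises instead of returning a spurious near-uniform distribution.
- Tables with non-monotone stage means load with a warning, not an error —
  pathological user tables should remain inspectable.
- The model is strictly sex-stratified; there is no pooled mode, because the
  reference statistics are published per sex.
- Partial (toy) tables can be constructed programmatically for testing; the
  CSV loader always requires all nine stages per sex and positive SDs.

### Bundled data

Only the nine male stage means are bundled (13.28 … 31.77 years); the
per-stage SDs and the female statistics belong to the original reference
studies and are deliberately not reproduced.  Every automated test that
needs SDs uses synthetic values, and all numbers downstream of an SD choice
(stage probabilities, AE values) depend on that choice.

## Evaluation metrics

Absolute errors e_i = |predicted - true| are summarized as MAE, SD of
absolute errors, maximum, and 90th percentile; per-age-bin summaries bin by
true age into left-closed right-open intervals (an individual aged exactly
16.0 falls in [16, 17)).  Empty bins are omitted; ages outside the declared
range are an error, since balanced evaluation designs guarantee coverage.
Predictions join cohort records by id with a hard error on any mismatch —
silent intersection hides data bugs.

Two conventions are configurable and echoed into all output metadata:

- **p90 quantile rule** — default linear interpolation between closest ranks
  (Hyndman–Fan type 7, numpy's default); any numpy method name is accepted.
- **SD denominator** — default sample SD (n − 1) for both error summaries
  and ensemble-member spread, the conservative choice; population SD (n) is
  available.

## Ensemble aggregation and abstention

A K-member ensemble's point prediction is the member mean; its predictive
uncertainty is the member SD (K ≥ 2 required).  The
abstention-performance trade-off ranks samples by uncertainty and, at
abstention rate r over N samples, drops the most uncertain fraction:

- the default rate grid is per-sample, k/N for k = 0 … N−1;
- on-grid rates retain exactly N − k samples; off-grid rates retain
  ceil((1 − r)·N) — abstention is conservative, a fractional sample is kept;
- uncertainty ties break by id, so results are platform-reproducible;
- retained sets are nested across rates.

Threshold crossing reports the smallest grid rate r* such that the chosen
metric is strictly below the threshold at *every* grid rate beyond r*.
Because real predictors need not yield monotone curves, the whole grid is
scanned rather than bisected; if the final grid point is still at or above
the threshold the result is "never" (Python `None`).

## Synthetic data

The generators replace private CT-cohort data with simulations whose
defaults mirror the standard balanced evaluation design:

- **Balanced cohort** — 10 individuals per sex per 1-year bin over
  [15.0, 30.0), 300 total; counts are exact, not in expectation.  Within-bin
  ages default to uniform (real ages are continuous and no within-bin
  distribution is published); a bin-midpoint mode exists for deterministic
  tests (its mean age is exactly 22.5 under the default design).
- **Stage assignment** — each individual's stage is drawn independently from
  p_s(age, sex), making staged cohorts exactly consistent with the AE model;
  the central consistency check is that stage simulation + stage-mean
  prediction reproduces the analytic cohort bound over replicates.
- **Ensemble simulator** — per individual a latent error ε ~ N(bias,
  noise_sd²) shared by all members, plus member-specific N(0, s²) noise with
  s = (1 − c)·member_spread_sd + c·|ε|.  The coupling c interpolates between
  uninformative (c = 0) and near-oracle (c = 1) uncertainty.  Defaults: 20
  members, noise_sd = 2.0 years — via the folded-normal relation
  E|ε| = σ·√(2/π) this puts the cohort MAE near 1.6 years, the error scale
  reported for CT-based clavicle age regressors — member_spread_sd = 1.0,
  c = 0.5.  An optional outlier knob adds a ± shift to a small fraction of
  individuals, emulating rare pathology-driven gross failures without
  claiming to model their anatomy.  The error model is intentionally simple
  (Gaussian, exchangeable members); it does not emulate age-dependent bias,
  scanner effects, or repeat scans per patient.
- **Reference refitting** — per-(sex, stage) sample mean/SD of age from a
  staged cohort, as reference studies derive their statistics.  Cells with
  fewer than 2 members or zero variance are reported as unusable rather than
  raising; missingness is data.

All generators are driven by a single seed with per-operation substreams
(numpy `SeedSequence` spawn keys), so adding one generator call never
perturbs another, and identical configs give bit-identical output.

### What parameter recovery can and cannot show

Refitting recovers generating stage means only when the design makes them
identifiable: stages well separated relative to their SDs, and the uniform
age range ending half a stage-spacing beyond the extreme means so each
stage's assignment window is symmetric about its mean.  With overlapping
stages — as in real clavicle tables, where adjacent substage means differ by
a few months — or an age range extending far past the first/last means, the
age distribution conditional on an assigned stage is *not* the generating
normal (every age below the first stage mean maps to stage 1 almost surely),
and its mean is systematically shifted.  The recovery test therefore uses a
separated synthetic table by design; passing it validates the estimator, not
the identifiability of real reference tables.

Likewise, passing tests on synthetic cohorts shows internal consistency of
the model chain, not that the normal within-stage assumption or the
published statistics describe any real population.

## Problem sizes

Test-suite simulations use cohorts of 300–4,000 individuals, 20–100
replicates, and 10⁵ Monte-Carlo draws per check, with stochastic assertions
at 3–4.5 standard errors of their own estimators; the whole suite runs in a
few seconds on one CPU.

## Known limitations

- Binary sex only, as published by the reference studies.
- No Bayesian age posterior, age priors, or interval estimation; AE is a
  pointwise bound.
- No modelling of reader mis-staging (the bound assumes perfect staging) or
  left/right clavicle discordance.
- No uncertainty calibration (temperature scaling, conformal prediction);
  the abstention analysis takes the uncertainty ranking as given.
- Quantities that depend on private clinical cohorts or unpublished
  reference SDs cannot be reproduced by this package; they require the
  user's own reference table and prediction files.
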