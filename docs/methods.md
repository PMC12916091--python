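# Methods

`tapcog` implements a complete smartphone finger-tapping → cognition
analysis pipeline: extraction of 15 inter-tap-interval (ITI) features from
raw tap-event logs, construction of neuropsychological domain scores,
a covariate-adjusted association battery with multiplicity control and
sensitivity variants, and a nested cross-validated LASSO composite score
validated by partial correlation. Because individual-level cohort data of
this kind are not publicly deposited, the package ships a synthetic-data
generator that emulates the statistical structure the analysis assumes and
records its ground truth, so every stage can be exercised and calibrated
end to end.

## The tapping task and its features

The task is an alternating two-button tapping test: 10 seconds with two
fingers of the left hand, then 10 seconds with the right hand. One 10-s
single-hand segment is a *trial*, keyed by (participant, session, hand).
A trial is included when the app recorded a valid 10-second segment with
at least one tap event and all timestamps inside the [0, 10000] ms
window; no performance-based exclusions (minimum tap counts, adherence
thresholds) are applied at ingest, because slow or instruction-nonadherent
tapping is itself potentially informative. Out-of-window timestamps
invalidate a trial rather than being clamped — they indicate a logging
fault.

All features derive from the ITI series, the successive differences of
the time-sorted tap timestamps. Fifteen features are computed per trial:

| group | features |
|---|---|
| basic temporal | number of taps, mean ITI, SD of ITI, CV of ITI |
| asymmetry / shape | skewness, kurtosis, alternating tap ratio, per-button mean and SD of ITI (left, right) |
| consistency | ITI range |
| fatigue / drift | ITI slope, last-to-first ITI ratio |
| microfluctuation | Microfluctuation Index (SD of successive ITI differences) |

Conventions that the formulas leave open are fixed as follows and
oracle-tested against an independently coded brute-force implementation:

- SD-type features use the n−1 denominator; skewness and excess kurtosis
  use population moments (`g1 = m3/m2^1.5`, `g2 = m4/m2² − 3`) with no
  small-sample correction. A zero-variance series leaves them missing
  (0/0), not zero.
- Per-button "ITI" means intervals between successive taps **on the same
  button** — the within-finger tapping period. Under perfect alternation
  at constant interval c both per-button means are 2c.
- The ITI slope regresses ITI on the 0-based interval index, not
  wall-clock time, so pauses do not stretch the regressor; a
  wall-clock-based variant is available (`slope_on_time`).
- The last-to-first ratio is missing when the first interval is 0 ms
  (duplicate opening timestamps), not infinite.
- Insufficient data makes the individual feature missing, never the
  record: a valid one-tap trial contributes `n_taps = 1` and 14 missing
  fields.

Participant-level values are the arithmetic mean of each feature over the
participant's valid in-stratum trials, pairwise over non-missing values.
Strata are: all trials, left hand, right hand, dominant and nondominant
hand (dominant = right hand for right-handers, left for left-handers;
ambidextrous or unknown handedness has no defined dominant hand and is
excluded from dominance strata). Columns are then z-standardized (n−1
SD) so association coefficients are per 1 SD of the feature.

## Neuropsychological scoring

The battery holds 21 tests mapped to four domains (memory, executive,
language, visuospatial). Processing order: (1) natural-log transform of
the three skew-normalized tests (Hooper Visual Organization Test, Trail
Making A, Trail Making B) and sign flip of lower-is-better tests, so
higher always means better; (2) multiple imputation by chained equations;
(3) column z-scoring; (4) domain score = mean of member-test z-scores,
global score = mean of the four domains, both averaged over the `m`
completed tables.

The chained-equations scheme initializes missing cells at column means
and then, for `n_iter = 10` sweeps, refits a linear regression of each
column on all others over the originally observed rows and overwrites
missing cells with prediction plus a normal residual draw
(predictive-mean matching with k = 5 donors is available as an option).
`m = 5` chains run from derived sub-seeds; observed cells are never
altered. Scores are averaged across completed datasets rather than pooled
with Rubin's rules because the downstream use is score construction, not
within-imputation inference. Whether the Hooper needs a direction flip
after the log transform is a configuration entry (default: higher is
better, no flip); the shipped 21-test list is a synthetic stand-in
battery and site batteries can swap in their own mapping via a YAML spec.

## Association battery

Each model is an ordinary least-squares regression of one cognitive
outcome (a domain score or the global score) on one standardized tapping
feature, adjusted for age at tapping, sex, education (two dummies,
reference college-and-higher), cohort, handedness (three dummies,
reference right; "unknown" is a dummy level by default with a switch to
drop those rows), and the neuropsych-to-tapping time interval in years.
Fits are on complete cases per model (the test battery is imputed;
covariates and features are not). Dummy levels absent from the analyzed
subsample are dropped, as a factor fit would drop unused levels; any
remaining rank deficiency is an error naming the collinear columns.

The main battery is 15 features × 5 outcomes = 75 models. Both
multiplicity controls are reported side by side: a Bonferroni flag at
α/15 = .003 within each outcome, and Benjamini–Hochberg step-up q-values
across all 75 tests with an FDR flag at q < .05. Sensitivity variants
compose per-trial filters applied before aggregation: dropping trials
with alternating tap ratio strictly below 0.80 (trials whose ratio is
undefined are kept — the inclusion rule imposes no performance
thresholds), restricting to each participant's first k sessions, and
hand or dominance restriction. An exploratory interaction model adds a
feature × cohort product term and reports its coefficient and p-value.

## Composite score

For one outcome, the composite tapping score is a weighted linear
combination of the 15 standardized features with LASSO-selected weights,
kept strictly out-of-sample by nested cross-validation: a 5-fold outer
loop standardizes features with training-fold statistics only, selects
the penalty by an inner 5-fold cross-validation, refits on the training
fold and scores the held-out fold. Every participant receives exactly one
composite from a model that never saw them. The composite is validated by
partial correlation with the outcome adjusting for age, sex and
education, pooling out-of-fold scores across folds into a single partial
correlation; the p-value uses the t distribution with n − k − 2 degrees
of freedom.

The L1 solver is cyclic coordinate descent on the Gram matrix for
`(1/2n)‖y − b0 − Xβ‖² + λ‖β‖₁` with an unpenalized intercept, using the
glmnet-style active-set strategy (full sweep, then iterate the nonzero
set to convergence, confirm with a full sweep). Every coordinate update
is an exact one-dimensional minimization, so the objective is
non-increasing sweep over sweep, and the returned solution satisfies the
KKT stationarity conditions to tolerance; both properties are tested, and
scikit-learn's Lasso serves as an independent cross-check in the test
suite. Some toolkits call this penalty "alpha"; it is `lam` here to avoid
clashing with the significance level α.

Numerical choices: the penalty grid has 100 log-spaced values from
λ_max (the smallest penalty with an all-zero solution) down to
λ_max·10⁻⁴; selection is by minimum mean out-of-fold squared error with
ties going to the larger (sparser) penalty — the grid is descending so
the first minimum wins. Path fits along the cross-validation grid use a
loose tolerance (10⁻⁵ coefficient change, 300 sweeps) because they only
rank penalties by an error estimate whose Monte-Carlo noise is far
larger; the refit at the selected penalty uses the tight defaults
(10⁻⁹/10⁻¹⁰). Folds are seeded stratification-free random partitions
with sizes differing by at most one. A feature that is constant within a
training fold gets SD 1 in the standardization and a zero coefficient.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions the rest of the package is calibrated under. Each participant
carries a latent global cognition g ~ N(0,1).

- **Demographics** mirror the target population: n = 302, age
  N(74.7, 6.3²) years, 56% female, 13.2% minority-cohort membership,
  education split 9.9/26.5/63.6% (high school / some college / college+),
  handedness 81.8/11.9/5/1.3% (right/left/ambidextrous/unknown), a
  neuropsych-to-tapping gap |N(1.7, 1.2²)| years, and a session count
  1 + Poisson(sessions_mean − 1) capped at 7, matching a seven-send
  bimonthly schedule.
- **Tapping**: within-segment ITIs are gamma distributed —
  positive support with tunable CV; the true ITI law is unknown, so gamma
  is a modelling stand-in, not a claim about real data — with
  log-link couplings `mean = 300·exp(0.25·(−g))` ms and
  `CV = 0.25·exp(0.20·(−g))`, plus a linear drift of `2·(−g)` ms per
  interval index. Lower cognition therefore taps slower, more variably,
  and slows down more within a trial; all couplings at zero give the null
  configuration in which tapping is independent of cognition. Intervals
  are rounded to integer milliseconds and floored at a 50 ms
  physiological minimum tapping period (which also breaks ties and keeps
  the drift term from collapsing intervals). Buttons alternate with an
  independent 5% flip probability.
- **Cognition**: domain latents d_k = 0.7·g + √(1−0.7²)·ε_k; each test
  scores d_k plus N(0, 0.6²) noise mapped to a plausible raw scale, the
  timed tests in positive seconds with lower = better. Missingness is
  MCAR at 5% by default, with a MAR option whose missingness probability
  increases with age rank.
- **Determinism**: one master seed; every stream draws from a
  `SeedSequence` keyed by a stated counter scheme (cohort, per
  participant-session tapping, battery, missingness), so any sub-stream
  is reproducible in isolation.

What the generator does *not* emulate: touchscreen sensor noise and
device latency, practice or learning effects across sessions, and —
deliberately — any person-level tapping variance beyond the latent
cognition pathway. That last omission means the standardized
tapping-cognition associations recovered on synthetic data are much
stronger than published real-data estimates of this design (where
tapping explains only a modest share of cognitive variance); passing
recovery tests here demonstrate that the pipeline estimates what the
generator encodes, not that real effects are this large.

## Calibration experiments

Three repeated-simulation checks calibrate the statistics
(`tapcog.experiments`, mirrored in the test suite and
`scripts/acceptance.py`):

- **Type-I error**: 500 cohorts of n = 300 under the null generator run
  the full pipeline (tap streams → features → aggregation → imputation →
  scores → 75-model battery); the fraction of p-values below .05 must lie
  in [0.03, 0.07].
- **CI coverage**: the standardized truth is not available in closed form
  through the nonlinear tap chain (the couplings act on the log scale),
  so coverage is checked at the association-model level, building the
  outcome directly on the standardized feature pathway with β = −0.25
  plus covariate effects and noise, and refitting the full
  covariate-adjusted model 200 times; 95% CI coverage must lie in
  [0.90, 0.98].
- **Composite null**: repetitions with 15 correlated Gaussian features
  and an independent outcome; the mean out-of-fold composite–outcome
  correlation must be within ±0.02 of zero. Under the null the selected
  model is frequently all-zero, making the composite constant; a
  composite with (numerically) zero variance counts as correlation 0. A
  separate bit-identity check verifies that changing the held-out fold's
  outcomes leaves that fold's composite scores byte-identical — the
  no-leakage guarantee. Two properties of this statistic are worth
  knowing. First, the composite deliberately excludes the training-fold
  intercept: out-of-fold *predictions* (intercept included) are offset by
  their training fold's outcome mean, which under the null is
  anti-correlated with the held-out outcomes and drags the pooled
  correlation to ≈ −0.075. Second, even without intercepts the pooled
  cross-validated Pearson correlation carries a small negative
  normalization bias (≈ −0.015 here) although the corresponding
  covariance is unbiased at zero — a known property of cross-validated
  correlations, driven by the normalization, not by leakage. The check
  therefore runs 500 repetitions so the Monte-Carlo standard error
  (≈ 0.0025) resolves the mean clearly inside the band.

Problem sizes in the shipped acceptance script (300 null cohorts by
default, 200-rep coverage and composite checks, a 10,000-participant
cohort for demographic summaries) are chosen so the whole script
recomputes everything from scratch in a few minutes on one core; the
test suite runs the 500-cohort version.

## Known limitations

- The gamma/log-link generative law, the synthetic test battery, and the
  raw-scale mappings of the tests are plausible stand-ins, not fitted to
  real data; conclusions about real cohorts require the real logs.
- Repeated sessions are averaged, not modelled longitudinally; there is
  no mixed-effects option.
- The chained-equations imputer assumes linear conditional means; with
  strongly non-Gaussian test scales predictive-mean matching is the safer
  option.
- With near-duplicate features (e.g. SD of ITI and the Microfluctuation
  Index are highly correlated) the LASSO solution at very small penalties
  is nearly non-unique; the solver caps path sweeps rather than polishing
  a direction the cross-validation will not select anyway.
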