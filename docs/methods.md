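# Methods

This note records the modelling assumptions, parameter choices and numerical
conventions behind `walkcast`, and what the synthetic-data experiments do and
do not demonstrate.

## The prediction problem

The unit of analysis is the participant-hour.  At each anchor hour the model
predicts whether the person will take at least one qualifying walk — a
maximal run of ≥5 consecutive minutes, each at ≥60 steps/min — during the
3-hour window starting at the anchor.  Predictors are purely temporal and
idiographic: the anchor's calendar position (hour of day, day of week, month,
day of month, each one-hot) and the person's own previous 840 hourly states
(5 weeks), each encoded as a 3-state one-hot over INACTIVE/ACTIVE/MISSING.
Missingness is deliberately a predictor state, not something to impute:
device non-wear is itself informative behavior.

Conventions the problem statement leaves open, fixed here and stamped into
instance provenance:

- **Outcome window** is `[anchor, anchor+3)`; the history ends at
  `anchor − 1`.  The label is 1 if any window hour is ACTIVE, 0 if none is
  and at least one is observed ("walked" is observable; "did not walk"
  requires some observation), and no instance is emitted when the whole
  window is MISSING or runs past the participant's span.
- **Lag history** is the 840 hours immediately preceding the anchor, not
  day-of-week-aligned blocks; hours before the participant's span are
  encoded MISSING so early anchors still produce instances.
- **Hour states**: a bout spanning an hour boundary marks *both* hours
  ACTIVE (any-overlap rule).  Missingness is day-granular: all 24 hours of
  an unrecorded calendar day are MISSING, and no hour on a recorded day is.
- **Run consecutiveness**: bout minutes must be exactly one minute apart;
  a recording gap breaks a run just as a slow minute does.
- **Exclusion**: "data on fewer than 10 days" counts distinct calendar days
  with ≥1 record, not elapsed span.

## Evaluation protocol

Non-walking anchors heavily outnumber walking anchors, so the majority class
is undersampled (uniformly, without replacement) down to the minority count
*once, globally, before splitting* — oversampling is avoided because
duplicated minority instances can leak between folds and inflate accuracy.
A single seeded shuffle then forms K=10 parts; fold *i* tests on part *i*,
tunes on part *i*+1 (cyclically, so every fold is structurally identical),
and trains on the other eight.  Splits are instance-level to match the
shuffle-based protocol; a participant-level grouping would be the
leakage-conservative alternative and is straightforward to build from the
`FoldSplit` primitives, but is not the default.  All classifier families are
evaluated on the *same* precomputed folds so their per-fold metric
distributions are directly comparable.

Metrics: accuracy, sensitivity, specificity and MCC.  Two aggregations are
reported side by side — the mean (and sample SD, ddof = 1) of per-fold
metrics, and the metrics of the fold-averaged confusion matrix — because the
two differ in the third decimal whenever folds vary.  Conventions: MCC with
a zero marginal returns 0 with a warning; a zero-denominator ratio metric is
NaN and flagged.  Per-fit wall-clock time is recorded with a monotonic clock
around the fit call only and reported descriptively (min/max/mean/SD and a
mean ± 1.96·SD interval); absolute timings are hardware-bound and never
asserted on.

The six families are deliberately *not* reimplemented: adapters wrap
scikit-learn (logistic regression, RBF SVM, decision tree, random forest,
MLP) and XGBoost (gradient-boosted trees).  Hyperparameters that the
protocol does not fix default to the backing library's defaults and are
snapshotted into each fit report.  The scikit-learn MLP is driven epoch by
epoch via `partial_fit` so that early stopping uses the protocol's explicit
tune part: training stops once tune-set log-loss has failed to improve for
`patience` consecutive epochs (default 10, epoch budget 100) and the best
weights seen are restored.  Activation (relu), optimizer (adam) and epoch
budget are this package's choices; nothing in the protocol fixes them.

## Random architecture search

MLP hidden-layer architectures are sampled with layer count uniform on
1..`max_layers` (default 5) and each width uniform over
{4, 8, 16, 32, 64, 128, 256}; these ranges span clearly under- to clearly
over-parameterized networks at desk scale and are fully configurable, since
the protocol specifies only the random-search idea, not its bounds.  Every
trial is evaluated with full K-fold cross-validation on the shared folds.
Trials are ranked by mean accuracy (the optimization metric — on balanced
data accuracy is unambiguous; MCC is recorded but never optimized), with
ties broken by higher mean MCC and then lower trial index for determinism.
The top 3 architectures are retained, and the running-maximum accuracy trace
is logged per trial.

## The synthetic generator

The generator emulates the *structure* of consumer wrist-band step data, not
any particular person: per non-missing day, walk-bout starts are Poisson
draws per (hour-of-day, day-of-week) cell of a 24×7 rate matrix, placed at
uniform minutes, with lognormal durations floored at 5 min; overlapping or
contiguous bouts merge into one run.  Bout minutes draw a walking cadence
(normal, mean 100, SD 15, floored at 60 steps/min); a per-day count of
background minutes (normal, mean 119, SD 30) is sprinkled over the rest of
the day with sub-threshold cadences (discretized lognormal on 0–59).  Whole
calendar days go missing independently with probability 0.369.  Each
participant's stream derives from a child seed keyed by (cohort seed,
participant index), so streams are stable when the cohort grows.

Default-preset calibration targets, checked by Monte-Carlo over ≥30 seeds:
2.6 detected bouts/day (the configured 2.72 expected starts/day shrink
slightly through merging), mean bout length 10.3 min (lognormal µ = 2.09,
σ = 0.62 after the 5-min floor), ≈146 recorded min/day, missing-day fraction
0.369.  Two contrast presets flank it: **null** (rate constant over hours
and days — no temporal predictability, so classifiers must sit at chance on
balanced instances) and **structured** (bouts concentrated in weekday
commute/lunch/evening windows — strong predictability the pipeline must
recover).

Known departures from real cohort data, hence limits on what passing tests
show: brisk minutes occurring in runs shorter than 5 minutes are not
modelled (background cadence is capped at 59 steps/min so that a zero bout
rate provably yields zero bouts), which understates total ≥60-steps/min
minutes per day relative to real streams; bouts are clipped at midnight;
missingness is day-granular and independent across days (no wear-time decay
or within-day dropout); and all participants share one rate matrix, whereas
real cohorts mix heterogeneous routines.  Consequently the synthetic
experiments validate the *protocol* — that the pipeline recovers
predictability when present, sits at chance when absent, and keeps its
bookkeeping exactly — not any real-data accuracy level.  Note also that
published cohort summaries of this kind are not always jointly satisfiable
(e.g. bouts/day × mean bout length can exceed what a reported walking-hours/
day figure allows); the generator calibrates to the bout-process and
missingness statistics and reports the rest as computed.

## Problem sizes

Test and acceptance runs use cohorts the generator's defaults define
(41 participants × 43 days) where the check concerns calibration or signal
recovery, and smaller cohorts (6–8 participants, 25–30 days) for the
chance-level and architecture-search experiments, with the MLP epoch budget
reduced (12–15 epochs, patience 3) — these sizes keep the experiments
desk-scale while leaving the measured effects far from their thresholds
(e.g. structured-preset accuracy ≈ 0.83 against a 0.65 bar; chance-level
means within 0.01 of 0.5 against a ±0.05 band).

## Known limitations

- Instance-level splitting means a person's adjacent hours can appear in
  both train and test folds; reported accuracies characterize the protocol
  on pooled data, not deployment generalization to unseen people.
- Overlapping 3-hour outcome windows make neighboring instances correlated;
  fold SDs understate true sampling variability.
- The feature matrix is dense uint8 (≈2.6 kB/instance); cohorts beyond a few
  hundred thousand instances would want a sparse or chunked representation.
- Predicted probabilities are used only through the 0.5 threshold (decision
  function at 0 for the SVM); no calibration is attempted.
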