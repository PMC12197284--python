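# Methods

This note documents the models, conventions and design decisions behind
`flightmwl`, in the spirit of a statistical software methods appendix.

## 1. The estimation problem

Mental workload (MWL) is treated as a latent continuum in [0, 100] that is
binarized into low/high states for supervised learning.  The observable
data are one pair of flight sessions per pilot — a *baseline* recon
scenario followed by a *demanding* rescue scenario — each carrying
uniformly sampled channels (cardiac, respiratory, gaze, helicopter state,
manipulanda) and event logs (oral self-reports on a 0–100 scale, NASA-TLX
task intervals, radio communication, autopilot sub-modes, gaze
area-of-interest stream).  The estimator must produce a continuous
workload score from signals *external* to any single modality and remain
interpretable: every decision is a named feature compared with a learned
threshold.

## 2. Feature extraction

**Windows.**  Self-report windows cover `[t − 40 s, t + 10 s)` around the
report time (50 s unclipped; windows clipped at session bounds carry a
truncation flag).  NASA-TLX windows span the full evaluated task.  All
times are seconds from session start; all intervals are half-open.

**Registry.**  76 features in three categories — 23 physiology, 28
machine, 25 interface.  The interface count is structural (4 manipulanda x
{mean, sd, crossings} x {displacement, force} + the communication share);
the physiology and machine counts depend on the configured category sets,
which default to 13 gaze areas of interest and 10 horizontal + 8 vertical
autopilot sub-modes.

**Conventions** (fixed once, used everywhere):

* standard deviation uses the n−1 denominator;
* *mean-crossings* counts strict sign changes of `x − mean(window)`, with
  exact-zero deviations inheriting the previous nonzero sign;
  *zero-crossings* is the same rule around 0.  Crossing features are
  stored per second so that fixed 50 s windows and variable-length TLX
  windows live on one scale (this also realizes "movement frequency" of a
  control as its displacement mean-crossing rate);
* dwell features (AoI, autopilot sub-modes, communication) are fractions
  of window time; exhaustive category sets sum to 1;
* the 95% prediction ellipse area is `pi * q * sqrt(l1*l2)` with `q` the
  0.95 chi-square quantile (2 df) and `l1, l2` the eigenvalues of the
  sample covariance of gaze points; rank-deficient covariances yield area
  0 with a degeneracy flag;
* fixations/saccades come from I-VT velocity-threshold segmentation
  (default 30 deg/s, minimum fixation 100 ms, pixels-per-degree
  calibration constant default 35); with no saccade detected the window is
  one fixation and saccade statistics are missing;
* a window must contain at least 80% of its expected samples per channel,
  otherwise the feature is missing; rows with missing values are dropped
  at training time with a logged count.

**Normalization.**  Physiological features are baseline-normalized per
pilot: subtract the pilot's mean over baseline-scenario windows.  This
removes idiosyncratic resting levels (e.g. resting heart rate) so one
model can serve all pilots.  Machine and interface features are left
untouched.  The same normalizer (fitted on baseline self-report windows)
is applied for every ground-truth kind and for continuous traces.

## 3. Ground-truth binarization

* Self-reports: per-pilot threshold = 75th percentile (linear
  interpolation between closest ranks) of that pilot's baseline-scenario
  reports.  Personal thresholds absorb individual rating styles.
* RTLX (unweighted mean of the six NASA-TLX sub-scores) and individual
  sub-scales: fixed threshold 47.78, the median answer for
  aircraft-piloting tasks in a published meta-analysis; configurable.
* Comparison is strictly-greater: a score equal to its threshold is low.
  The convention is arbitrary but fixed and documented.
* Baseline-scenario windows enter training with labels from the same
  personal threshold (configurable via `include_scenario1`).
* The "physical demand" and "performance" sub-scales are structurally
  single-class in this setting and are flagged as such.

## 4. The HBagging ensemble

One weak classifier per feature: an orientation sign and a decision
threshold.  In one dimension a linear maximum-margin classifier is a
threshold, and the threshold is recalibrated on the ROC anyway, so the
weak learner is implemented directly as an oriented cut at the ROC
top-left optimum (candidates: midpoints between consecutive distinct
values plus both infinities; ties broken toward higher TPR, then the lower
threshold).  Orientation follows an expert heuristic when one is given,
otherwise the sign that makes the training AUC at least 0.5.  A classifier
is *retained* only if its oriented training ROC AUC reaches `min_auc`
(default 0.6); constant features are rejected as degenerate.  Rejection is
a quality gate, not an error; single-class labels are an error.

The ensemble score is the unweighted mean of binary votes — the bagging
reference leaves the aggregation rule open, and the unweighted vote mean
is the simplest choice that yields a continuous, interpretable [0, 1]
score suitable for ROC/PR evaluation.  An empty ensemble abstains at 0.5
with a logged warning.  Models serialize to JSON (features, orientations,
thresholds, training AUCs) and `describe()` renders the full audit table.

## 5. Evaluation protocol

Per pilot, windows are ordered by (scenario, time); the earliest 80% form
the training pool, the latest 20% the test set, so no test window can be
predicted from later assessments.  Published distributions over many
repetitions do not specify what varies between repetitions; here each
repetition bootstrap-resamples the per-pilot training pool while the test
rows stay fixed — this respects the no-future rule while inducing model
variability.  Metrics per repetition: ROC AUC, maximum F1 over thresholds,
and PR AUC (average precision), computed on pooled test rows; per-pilot
ROC AUC is additionally computed on each pilot's test rows.  Repetitions
whose test set is single-class record missing metrics and are excluded
from aggregates with a logged count.  Feature usage = percentage of
repetitions in which a feature was retained.

**Ablation.**  To score one feature category, every column outside it is
independently permuted across rows — a fresh permutation per repetition —
which destroys its relation to the labels while preserving marginal
distributions; the repetition protocol then runs unchanged.

**Continuous trace.**  Sliding 50 s windows at a configurable stride (the
first full window ends at 50 s), features per window, normalizer applied,
ensemble score per window; under-covered windows yield missing scores.

The desk-scale default is 100 repetitions (the study-scale figure is
1000); all reported simulations here use 50–100 repetitions, which keeps
the full suite and the acceptance script within a few minutes on one CPU
while leaving Monte-Carlo error on mean AUC below ~0.01.

## 6. The synthetic-data generator

The generator emulates the *structure* of the study — 7 pilots (numbered
3–9), two ordered sessions of 3600 s, 15 oral self-reports per session,
ten NASA-TLX tasks in the demanding scenario — with a known latent
workload trajectory as the single hidden cause of every modality:

* **Latent profile**: scenario-scripted boxcar events (takeoff, ship
  landing, emergency landing, engine failure, ...) smoothed with a 10 s
  Gaussian kernel, plus a slow random wander (sd 6, 60 s scale), clipped
  to [0, 100].  The demanding scenario's scripted amplitudes dominate the
  baseline's, so its mean and upper quartile are higher.
* **Effect sizes** are per *feature family* (cardiac, respiratory, gaze
  dispersion, out-of-cockpit gaze share, helicopter stability, autopilot
  engagement, control displacement/force variability, communication): a
  family with effect `e` shifts its channel statistic by `e` noise-sd per
  25 latent points from mid-scale.  Mean-coupled families (cardiac,
  respiratory) shift the local channel mean; variability-coupled families
  (helicopter, controls) scale the AR(1) fluctuation amplitude;
  proportion-coupled families shift category probabilities.  The study
  does not quantify real effect magnitudes, so the defaults are declared
  calibration knobs: 1.0 per family, with `null()` (all zero) and
  `planted()` (five families spanning all three categories) presets.
* **Channels**: Gaussian AR(1) around the latent-modulated mean with
  realistic time constants and per-pilot trait offsets (resting HR/IBI/BR
  drawn from a pilot-level substream, stable across the pilot's two
  sessions — exactly what baseline normalization should remove).  Gaze is
  a fixation/saccade process (gamma fixation durations, instantaneous
  jumps) so the I-VT detector sees genuine events; trajectory drifts
  (altitude, heading) live on scales well beyond the 50 s window so that
  windowed variability stays dominated by the latent-modulated term.
* **Self-reports**: latent value at the key moment plus N(0, 8), clipped —
  the label noise that keeps per-pilot AUC realistically below 1.
* **NASA-TLX**: affine maps of the interval-mean latent plus noise;
  physical demand is capped at 45 (never "high" vs the 47.78 threshold)
  and performance floored at 48 (never "low"), mirroring the single-class
  sub-scales seen in cockpit settings.  Theoretical (expert) answers are
  generated once per cohort from the scripted event expectations and
  shared across pilots.
* **Reproducibility**: all randomness flows from `SeedSequence(master
  seed, spawn_key)` substreams per pilot/scenario/stage — cohorts are
  bit-reproducible and pilots mutually independent.

What the generator does **not** emulate: flight dynamics, ECG waveforms,
sensor dropouts and artefacts, audio content, or cross-modal couplings
beyond the shared latent (e.g. communication does not perturb breathing).
Passing tests therefore demonstrate that the pipeline recovers a latent
state expressed through channel statistics under realistic noise — not
that real pilot workload is recoverable at these effect sizes.

## 7. Statistical behaviour worth knowing

With 76 candidate features, a 0.6 training-AUC gate and ~170 training
windows, the null distribution of the Mann–Whitney AUC has sd ≈ 0.05, so
a handful of pure-noise features pass the gate in any one repetition and
the maximum chance usage among dozens of noise features can reach tens of
percent for a given cohort realization.  This is inherent
multiple-comparison behaviour at this sample size, visible in the
effect-free calibration runs (ensembles are rarely completely empty even
though mean test AUC stays at chance).  Usage percentages should therefore
be read as a ranking, not as a significance test; raising the gate or the
number of windows per pilot sharpens the separation.

## 8. Known limitations

* The weak learners are axis-aligned thresholds: monotone effects only,
  no interactions.
* The 60 Hz gaze rate limits saccade metrics; saccade durations quantize
  to multiples of one sample.
* The bootstrap repetition scheme is one defensible reading of
  "distribution over repetitions"; alternatives (subsampling, moving
  splits) would change the spread but not the ranking behaviour.
* Per-pilot evaluation uses a pooled model; per-pilot training is left to
  configuration rather than implemented as a separate protocol.
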