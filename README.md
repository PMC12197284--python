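# flightmwl

Continuous estimation of the **mental workload (MWL)** of human–machine
interface operators — modelled on helicopter pilots flying realistic
scenarios in a full-flight simulator — from multimodal recordings: cardiac
and respiratory series, gaze tracking, helicopter state, and the pilot's
actions on the flight controls.

The package is aimed at human-factors and physiological-computing
researchers who need a *fully interpretable* workload classifier and a
leakage-free evaluation protocol for time-stamped cognitive-state data.
Because real pilot recordings of this kind are confidential, the package
ships a synthetic-session generator with a known latent workload, so the
whole pipeline is testable and reproducible end to end.

## The model

Seventy-six features are computed on evaluation windows (50 s around each
oral self-report, or the span of each NASA-TLX task), partitioned into
**23 physiology** (HR/IBI/BR statistics, fixations, saccades, 95% gaze
prediction ellipse, time per gaze area of interest), **28 machine**
(attitude/altitude variability and mean-crossings, autopilot sub-mode
occupancy) and **25 interface** features (displacement and force statistics
of the collective, pedals and cyclic, radio-communication share).
Physiological features are normalized per pilot by subtracting their mean
over the first (baseline) scenario.

Ground truth is binarized: a self-report *s* of pilot *p* is "high" iff
*s* > Q₇₅(baseline reports of *p*); RTLX scores (unweighted mean of the six
NASA-TLX sub-scores) are thresholded at the fixed meta-analytic value
**47.78**.

The classifier is **HBagging**: one weak classifier per feature — an
oriented decision threshold θⱼ placed where the ROC operating point is
closest to the top-left corner, i.e. minimizing √((1−TPR)² + FPR²).  A weak
classifier is retained only if its training ROC AUC ≥ 0.6; expert
heuristics can constrain the orientation.  The ensemble score of a window
x is the mean vote

&nbsp;&nbsp;&nbsp;&nbsp;ŷ(x) = (1/|R|) Σ_{j∈R} 1[σⱼ xⱼ > σⱼ θⱼ] ∈ [0, 1],

which doubles as a continuous workload estimate over sliding windows.

Evaluation uses temporal cross-validation without future leakage: per
pilot, the chronologically earliest 80% of windows form the training pool
and the latest 20% the test set; performance distributions (ROC AUC,
maximum F1, PR AUC) come from repetitions that bootstrap-resample the
training pool.  Feature importance is the percentage of repetitions in
which a feature is retained, and a shuffling ablation (permute every
column outside one category) ranks the three feature categories.

## Worked example

```python
from flightmwl import synthetic, features, ground_truth, evaluation

config = synthetic.GeneratorConfig.planted(seed=1)   # effects in 5 families
cohort = synthetic.generate_cohort(config)           # 7 pilots x 2 sessions
matrix = features.extract_feature_matrix(cohort)     # 210 windows x 76
labels = ground_truth.build_labels(matrix.meta, "selfreport")

report = evaluation.run_repetitions(
    matrix, labels, evaluation.SplitConfig(n_repetitions=100, seed=1)
)
print(report.summary.round(3))
print(report.usage.sort_values(ascending=False).head(8).round(1))
```

prints

```
          mean     sd  median     q1     q3      n
roc_auc  0.894  0.022   0.899  0.879  0.909  100.0
max_f1   0.922  0.009   0.925  0.921  0.925  100.0
pr_auc   0.967  0.012   0.970  0.962  0.976  100.0

heart_rate_mean               100.0
ibi_mean                      100.0
aoi_outside                   100.0
pedals_force_sd               100.0
collective_force_sd           100.0
pedals_displacement_sd        100.0
collective_displacement_sd    100.0
cyclic_roll_force_sd          100.0
```

The ensemble recovers the planted workload channels: mean test ROC AUC
0.894 over 100 repetitions, and every feature family carrying a planted
effect (cardiac means, out-of-cockpit gaze share, control displacement and
force variability) is retained in 100% of repetitions.

The same pipeline is scriptable from the shell:

```bash
flightmwl simulate --seed 1 --out cohort/
flightmwl extract  --cohort cohort/cohort.json --out run/fm
flightmwl evaluate --features run/fm --repetitions 100 --seed 1 --out run/report
flightmwl ablate   --features run/fm --repetitions 50  --seed 1 --out run/ablation.csv
```

## Layout

| module | contents |
| --- | --- |
| `flightmwl.synthetic` | latent-workload cohort generator (study conditions) |
| `flightmwl.session_io` | session data model, CSV/JSON storage |
| `flightmwl.features` | 76-feature registry, window statistics, normalization |
| `flightmwl.ground_truth` | self-report / RTLX binarization |
| `flightmwl.hbagging` | the weak-classifier ensemble |
| `flightmwl.evaluation` | temporal CV, metrics, usage, ablation, trace |
| `flightmwl.cli` | `flightmwl` command-line entry points |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
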