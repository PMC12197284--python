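"""Leakage-free temporal evaluation of the workload ensemble.

The protocol mirrors field practice for time-stamped cognitive-state data:
for each pilot, the chronologically earliest 80% of evaluation windows form
the training pool and the latest 20% the test set, so no test window is
ever predicted from assessments that occur later in time.  Performance
distributions are obtained over many repetitions; each repetition
bootstrap-resamples the per-pilot training pool (the test rows stay fixed),
refits the ensemble and scores the pooled test rows with three metrics:
ROC AUC, maximum F1 and PR AUC (average precision).

Feature importance is summarized as the percentage of repetitions in which
each feature's weak classifier survived the AUC gate.  Feature-subset
ablation keeps one category of features intact and independently permutes
every other column across rows (a fresh permutation per repetition),
turning the complement into distribution-preserving noise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
)

from . import hbagging
from .features import (
    FeatureConfig,
    FeatureMatrix,
    FeatureRegistry,
    PhysiologyNormalizer,
    WindowSpec,
    _session_window_features,
)
from .ground_truth import MWLLabelSet
from .hbagging import HBaggingConfig, HBaggingModel, SingleClassError
from .session_io import SessionRecording

logger = logging.getLogger(__name__)

METRICS = ("roc_auc", "max_f1", "pr_auc")


@dataclass(frozen=True)
class SplitConfig:
    train_fraction: float = 0.8
    n_repetitions: int = 100
    seed: int = 0
    bootstrap: bool = True  # resample the train pool on each repetition

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def max_f1(scores, y) -> float:
    """Maximum F1 over all decision thresholds (positive class = high)."""
    y = np.asarray(y, dtype=bool)
    if y.all() or not y.any():
        raise SingleClassError("labels contain a single class")
    precision, recall, _ = precision_recall_curve(y, np.asarray(scores,
                                                               dtype=float))
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = 2.0 * precision * recall / (precision + recall)
    return float(np.nanmax(f1))


def pr_auc(scores, y) -> float:
    """Average precision: step-wise sum of precision x recall increments."""
    y = np.asarray(y, dtype=bool)
    if y.all() or not y.any():
        raise SingleClassError("labels contain a single class")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def _roc_auc(scores, y) -> float:
    y = np.asarray(y, dtype=bool)
    if y.all() or not y.any():
        raise SingleClassError("labels contain a single class")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# temporal split
# ---------------------------------------------------------------------------


def temporal_split(
    meta: pd.DataFrame,
    train_fraction: float = 0.8,
) -> tuple[dict[int, np.ndarray], dict[int, np.ndarray]]:
    """Per-pilot chronological split into train pool and test rows.

    Rows are ordered by the ``order`` column (scenario order, then time);
    the earliest ``train_fraction`` enter the train pool and the remainder
    the test set, so every train row strictly precedes every test row for
    that pilot.  Pilots with fewer than 2 rows are excluded with a warning.
    Returns positional indices into ``meta``.
    """
    train: dict[int, np.ndarray] = {}
    test: dict[int, np.ndarray] = {}
    pos = np.arange(len(meta))
    for pilot, group_idx in meta.groupby("pilot_id").groups.items():
        rows = pos[meta.index.get_indexer(group_idx)]
        if len(rows) < 2:
            logger.warning("pilot %s has <2 rows; excluded from evaluation",
                           pilot)
            continue
        order = meta["order"].to_numpy()[rows]
        rows = rows[np.argsort(order, kind="stable")]
        n_train = int(round(train_fraction * len(rows)))
        n_train = min(max(n_train, 1), len(rows) - 1)
        train[pilot] = rows[:n_train]
        test[pilot] = rows[n_train:]
    return train, test


def check_no_leakage(meta: pd.DataFrame, train: dict[int, np.ndarray],
                     test: dict[int, np.ndarray]) -> bool:
    """True iff, for every pilot, max(train order) < min(test order)."""
    order = meta["order"].to_numpy()
    return all(
        order[train[p]].max() < order[test[p]].min() for p in test
    )


# ---------------------------------------------------------------------------
# repetition protocol
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    per_repetition: pd.DataFrame      # n_retained + roc_auc, max_f1, pr_auc
    per_pilot: pd.DataFrame           # per-pilot AUC summaries
    usage: pd.Series                  # feature -> % of repetitions retained
    n_repetitions: int
    n_degenerate: dict[str, int]      # metric -> repetitions excluded
    split: SplitConfig
    subset: str = "all"

    @property
    def empty_fraction(self) -> float:
        """Fraction of repetitions in which no weak classifier survived."""
        return float((self.per_repetition["n_retained"] == 0).mean())

    @property
    def summary(self) -> pd.DataFrame:
        rows = {}
        for m in METRICS:
            v = self.per_repetition[m].dropna()
            rows[m] = {
                "mean": v.mean(),
                "sd": v.std(ddof=1) if len(v) > 1 else 0.0,
                "median": v.median(),
                "q1": v.quantile(0.25),
                "q3": v.quantile(0.75),
                "n": len(v),
            }
        return pd.DataFrame(rows).T

    def write(self, path_prefix: str) -> None:
        self.per_repetition.to_csv(f"{path_prefix}_repetitions.csv",
                                   index=False)
        self.per_pilot.to_csv(f"{path_prefix}_per_pilot.csv")
        self.usage.rename("usage_percent").to_csv(f"{path_prefix}_usage.csv")
        self.summary.to_csv(f"{path_prefix}_summary.csv")
        with open(f"{path_prefix}_summary.json", "w") as fh:
            json.dump(
                {
                    "subset": self.subset,
                    "n_repetitions": self.n_repetitions,
                    "n_degenerate": self.n_degenerate,
                    "metrics": {
                        m: {
                            "mean": float(self.summary.loc[m, "mean"]),
                            "sd": float(self.summary.loc[m, "sd"]),
                        }
                        for m in METRICS
                    },
                },
                fh,
                indent=1,
            )


def _align_labels(matrix: FeatureMatrix, labels: MWLLabelSet) -> np.ndarray:
    if len(labels.frame) != len(matrix.values):
        raise ValueError(
            "labels and feature matrix have different row counts; build "
            "labels from this matrix's meta table"
        )
    return labels.y


def run_repetitions(
    matrix: FeatureMatrix,
    labels: MWLLabelSet,
    split: SplitConfig = SplitConfig(),
    model_config: HBaggingConfig = HBaggingConfig(),
    shuffle_columns: list[str] | None = None,
) -> EvaluationReport:
    """Full repetition protocol: split, (re)fit, score, aggregate.

    ``shuffle_columns`` (used by the ablation) lists feature columns to
    permute independently across all rows with a fresh permutation on every
    repetition.  Repetitions whose test set is single-class record missing
    metrics and are excluded from the aggregates.
    """
    y = _align_labels(matrix, labels)
    X = matrix.values
    rng = np.random.default_rng(split.seed)
    train_pool, test_idx = temporal_split(matrix.meta, split.train_fraction)
    if not test_idx:
        raise ValueError("no pilot has enough rows to evaluate")
    assert check_no_leakage(matrix.meta, train_pool, test_idx)
    test_all = np.concatenate([test_idx[p] for p in sorted(test_idx)])

    rep_rows = []
    pilot_aucs: dict[int, list[float]] = {p: [] for p in test_idx}
    retained_counts = pd.Series(0.0, index=X.columns)
    n_degenerate = {m: 0 for m in METRICS}

    for _ in range(split.n_repetitions):
        if shuffle_columns:
            X_rep = X.copy()
            for col in shuffle_columns:
                X_rep[col] = rng.permutation(X_rep[col].to_numpy())
        else:
            X_rep = X
        if split.bootstrap:
            train_rows = np.concatenate(
                [
                    rng.choice(pool, size=len(pool), replace=True)
                    for _, pool in sorted(train_pool.items())
                ]
            )
        else:
            train_rows = np.concatenate(
                [pool for _, pool in sorted(train_pool.items())]
            )
        model = hbagging.fit(X_rep.iloc[train_rows], y[train_rows],
                             model_config)
        for w in model.retained:
            retained_counts[w.feature] += 1
        scores = hbagging.predict_score(model, X_rep.iloc[test_all])
        y_test = y[test_all]

        row = {"n_retained": len(model.retained)}
        for name, fn in (("roc_auc", _roc_auc), ("max_f1", max_f1),
                         ("pr_auc", pr_auc)):
            try:
                row[name] = fn(scores, y_test)
            except SingleClassError:
                row[name] = np.nan
                n_degenerate[name] += 1
        rep_rows.append(row)

        offset = 0
        for p in sorted(test_idx):
            k = len(test_idx[p])
            s_p = scores[offset:offset + k]
            y_p = y_test[offset:offset + k]
            offset += k
            try:
                pilot_aucs[p].append(_roc_auc(s_p, y_p))
            except SingleClassError:
                pass

    per_repetition = pd.DataFrame(rep_rows,
                                  columns=["n_retained", *METRICS])
    per_pilot = pd.DataFrame(
        {
            p: {
                "median": np.median(v) if v else np.nan,
                "q1": np.percentile(v, 25) if v else np.nan,
                "q3": np.percentile(v, 75) if v else np.nan,
                "mean": np.mean(v) if v else np.nan,
                "sd": np.std(v, ddof=1) if len(v) > 1 else np.nan,
                "n": len(v),
            }
            for p, v in pilot_aucs.items()
        }
    ).T
    per_pilot.index.name = "pilot_id"
    usage = retained_counts / split.n_repetitions * 100.0
    return EvaluationReport(
        per_repetition=per_repetition,
        per_pilot=per_pilot,
        usage=usage,
        n_repetitions=split.n_repetitions,
        n_degenerate=n_degenerate,
        split=split,
    )


# ---------------------------------------------------------------------------
# ablation
# ---------------------------------------------------------------------------


def ablate_subsets(
    matrix: FeatureMatrix,
    labels: MWLLabelSet,
    split: SplitConfig = SplitConfig(),
    model_config: HBaggingConfig = HBaggingConfig(),
    subsets: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Evaluate each feature category with every other column shuffled.

    ``subsets`` defaults to the registry's physiology/machine/interface
    partition; it must partition the columns exactly.  Returns one row per
    subset plus an "all" row, with mean and sd of the three metrics.
    """
    registry = matrix.registry
    if subsets is None:
        subsets = {
            cat: registry.names_in(cat)
            for cat in ("physiology", "machine", "interface")
        }
    claimed = [c for cols in subsets.values() for c in cols]
    if sorted(claimed) != sorted(registry.names):
        raise ValueError("subsets must partition the feature columns exactly")

    rows = []
    report_all = run_repetitions(matrix, labels, split, model_config)
    rows.append(_ablation_row("all", report_all))
    for name, cols in subsets.items():
        complement = [c for c in registry.names if c not in cols]
        report = run_repetitions(matrix, labels, split, model_config,
                                 shuffle_columns=complement)
        rows.append(_ablation_row(name, report))
    return pd.DataFrame(rows).set_index("subset")


def _ablation_row(name: str, report: EvaluationReport) -> dict:
    row: dict = {"subset": name}
    for m in METRICS:
        row[f"{m}_mean"] = float(report.summary.loc[m, "mean"])
        row[f"{m}_sd"] = float(report.summary.loc[m, "sd"])
    return row


# ---------------------------------------------------------------------------
# continuous workload trace
# ---------------------------------------------------------------------------


def continuous_trace(
    model: HBaggingModel,
    session: SessionRecording,
    registry: FeatureRegistry,
    normalizer: PhysiologyNormalizer | None = None,
    stride: float = 10.0,
    window_length: float = 50.0,
    feature_config: FeatureConfig = FeatureConfig(),
) -> pd.DataFrame:
    """Sliding-window ensemble score over a whole session.

    Windows of ``window_length`` seconds advance by ``stride``; the first
    full window ends at ``window_length``.  Returns columns ``time`` (window
    end) and ``score`` in [0, 1]; windows with insufficient coverage yield
    missing scores.
    """
    if stride <= 0:
        raise ValueError("stride must be > 0")
    ends = np.arange(window_length, session.duration + 1e-9, stride)
    rows = []
    for end in ends:
        rows.append(
            _session_window_features(session, (end - window_length, end),
                                     registry, feature_config)
        )
    X = pd.DataFrame(rows, columns=registry.names)
    if normalizer is not None:
        offsets = normalizer.baseline_means.loc[session.pilot_id]
        X[normalizer.physiology_columns] = (
            X[normalizer.physiology_columns] - offsets
        )
    scores = np.full(len(X), np.nan)
    usable = X[model.feature_names].notna().all(axis=1).to_numpy() \
        if not model.empty else np.ones(len(X), dtype=bool)
    if usable.any():
        scores[usable] = hbagging.predict_score(model, X.loc[usable])
    return pd.DataFrame({"time": ends, "score": scores})
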