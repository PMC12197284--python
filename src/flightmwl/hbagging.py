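"""HBagging: an interpretable ensemble of single-feature threshold rules.

Each candidate feature gets one weak classifier: an oriented decision
threshold ("feature above this value means high workload", or below, for a
negatively oriented feature).  In one dimension a linear maximum-margin
classifier reduces to exactly such a threshold, and here the cut is placed
directly where the ROC operating point is closest to the top-left corner
(FPR = 0, TPR = 1), balancing true positives against true negatives.

A weak classifier is retained only when its training ROC AUC reaches a
minimum (default 0.6): features that cannot beat chance on their own are
discarded, which gives the ensemble a built-in feature selection.  Expert
knowledge enters through optional heuristics constraining the orientation
(e.g. "heart rate increases with workload"); an ill-constrained feature
then fails the AUC gate instead of flipping its sign.

The ensemble score of a window is the unweighted mean of the retained
classifiers' binary votes, a value in [0, 1] usable both as a continuous
workload estimate and, thresholded at 0.5, as a hard label.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

INCREASES = "increases-with-MWL"
DECREASES = "decreases-with-MWL"
UNCONSTRAINED = "unconstrained"


class SingleClassError(ValueError):
    """Training labels contain a single class."""


@dataclass(frozen=True)
class Heuristic:
    """Expert prior on the direction a feature moves with workload."""

    feature: str
    direction: str = UNCONSTRAINED

    def __post_init__(self) -> None:
        if self.direction not in (INCREASES, DECREASES, UNCONSTRAINED):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class HBaggingConfig:
    min_auc: float = 0.6
    heuristics: tuple[Heuristic, ...] = ()

    def __post_init__(self) -> None:
        if not 0.5 <= self.min_auc < 1.0:
            raise ValueError("min_auc must lie in [0.5, 1)")
        names = [h.feature for h in self.heuristics]
        if len(names) != len(set(names)):
            raise ValueError("at most one heuristic per feature")

    def direction_for(self, feature: str) -> str:
        for h in self.heuristics:
            if h.feature == feature:
                return h.direction
        return UNCONSTRAINED


@dataclass(frozen=True)
class WeakClassifier:
    """Oriented threshold rule: vote high iff ``orientation * x >
    orientation * threshold``."""

    feature: str
    orientation: int  # +1: larger values mean high workload
    threshold: float
    train_auc: float

    def votes(self, x: np.ndarray) -> np.ndarray:
        return (self.orientation * np.asarray(x, dtype=float)
                > self.orientation * self.threshold)


@dataclass(frozen=True)
class Rejection:
    feature: str
    reason: str  # "low-auc" or "degenerate"
    train_auc: float | None = None


@dataclass
class HBaggingModel:
    retained: list[WeakClassifier]
    rejected: list[Rejection]
    config: HBaggingConfig
    n_train: int = 0

    @property
    def empty(self) -> bool:
        return not self.retained

    @property
    def feature_names(self) -> list[str]:
        return [w.feature for w in self.retained]

    def to_json_dict(self) -> dict:
        return {
            "config": {
                "min_auc": self.config.min_auc,
                "heuristics": [
                    {"feature": h.feature, "direction": h.direction}
                    for h in self.config.heuristics
                ],
            },
            "n_train": self.n_train,
            "retained": [
                {
                    "feature": w.feature,
                    "orientation": w.orientation,
                    "threshold": w.threshold,
                    "train_auc": w.train_auc,
                }
                for w in self.retained
            ],
            "rejected": [
                {"feature": r.feature, "reason": r.reason,
                 "train_auc": r.train_auc}
                for r in self.rejected
            ],
        }

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @classmethod
    def from_json_dict(cls, d: dict) -> "HBaggingModel":
        config = HBaggingConfig(
            min_auc=d["config"]["min_auc"],
            heuristics=tuple(
                Heuristic(h["feature"], h["direction"])
                for h in d["config"]["heuristics"]
            ),
        )
        return cls(
            retained=[WeakClassifier(**w) for w in d["retained"]],
            rejected=[Rejection(**r) for r in d["rejected"]],
            config=config,
            n_train=d.get("n_train", 0),
        )

    @classmethod
    def load(cls, path: str) -> "HBaggingModel":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def _check_two_classes(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=bool)
    if y.all() or not y.any():
        raise SingleClassError("labels contain a single class")
    return y


def roc_auc(values, y) -> float:
    """P(random high value > random low value), ties counted one half."""
    y = _check_two_classes(y)
    return float(roc_auc_score(y, np.asarray(values, dtype=float)))


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    distance: float
    tpr: float
    fpr: float
    boundary: bool  # no interior threshold beat a degenerate corner


def topleft_threshold(values, y, orientation: int = 1) -> ThresholdResult:
    """Decision threshold minimizing the distance to the ROC top-left corner.

    Candidates are the midpoints between consecutive distinct sorted values
    plus the two infinities; prediction is high iff
    ``orientation * x > orientation * t``.  Ties are broken toward higher
    TPR, then toward the lower threshold.
    """
    y = _check_two_classes(y)
    x = np.asarray(values, dtype=float)
    distinct = np.unique(x)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    candidates = np.concatenate([[-np.inf], mids, [np.inf]])
    n = len(x)
    n_pos = int(y.sum())
    n_neg = n - n_pos

    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    cum_pos = np.concatenate([[0], np.cumsum(ys)])
    if orientation >= 0:
        idx = np.searchsorted(xs, candidates, side="right")
        tp = n_pos - cum_pos[idx]
        fp = (n - idx) - tp
    else:
        idx = np.searchsorted(xs, candidates, side="left")
        tp = cum_pos[idx]
        fp = idx - tp
    tpr = tp / n_pos
    fpr = fp / n_neg
    dist = np.hypot(1.0 - tpr, fpr)
    # tie-break: minimal distance, then higher TPR, then lower threshold
    best = np.lexsort((candidates, -tpr, dist))[0]
    t = float(candidates[best])
    return ThresholdResult(threshold=t, distance=float(dist[best]),
                           tpr=float(tpr[best]), fpr=float(fpr[best]),
                           boundary=not np.isfinite(t))


def fit_weak_classifier(
    feature: str,
    values,
    y,
    config: HBaggingConfig = HBaggingConfig(),
) -> WeakClassifier | Rejection:
    """Fit one oriented threshold rule; returns a :class:`Rejection` (not an
    error) when the oriented training AUC falls below the gate or the
    feature is degenerate."""
    y = _check_two_classes(y)
    x = np.asarray(values, dtype=float)
    if len(np.unique(x[np.isfinite(x)])) < 2 or not np.all(np.isfinite(x)):
        return Rejection(feature=feature, reason="degenerate")

    auc_plus = roc_auc(x, y)
    direction = config.direction_for(feature)
    if direction == INCREASES:
        orientation, oriented_auc = 1, auc_plus
    elif direction == DECREASES:
        orientation, oriented_auc = -1, 1.0 - auc_plus
    else:
        orientation = 1 if auc_plus >= 0.5 else -1
        oriented_auc = max(auc_plus, 1.0 - auc_plus)

    if oriented_auc < config.min_auc:
        return Rejection(feature=feature, reason="low-auc",
                         train_auc=oriented_auc)
    result = topleft_threshold(x, y, orientation)
    return WeakClassifier(feature=feature, orientation=orientation,
                          threshold=result.threshold,
                          train_auc=oriented_auc)


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------


def fit(
    X: pd.DataFrame,
    y,
    config: HBaggingConfig = HBaggingConfig(),
) -> HBaggingModel:
    """Independently fit one weak classifier per feature column.

    Rows containing any missing value are dropped (with a logged count)
    before fitting, so every weak classifier sees the same windows.
    """
    if X.shape[1] < 1:
        raise ValueError("need at least one feature column")
    y = np.asarray(y, dtype=bool)
    if len(y) != len(X):
        raise ValueError("X and y length mismatch")
    complete = X.notna().all(axis=1).to_numpy()
    dropped = int((~complete).sum())
    if dropped:
        logger.info("dropping %d/%d rows with missing features", dropped,
                    len(X))
    Xc, yc = X.loc[complete], y[complete]
    try:
        _check_two_classes(yc)
    except SingleClassError as exc:
        raise SingleClassError(
            f"training labels are single-class ({exc})"
        ) from exc

    retained: list[WeakClassifier] = []
    rejected: list[Rejection] = []
    for name in Xc.columns:
        result = fit_weak_classifier(name, Xc[name].to_numpy(), yc, config)
        if isinstance(result, WeakClassifier):
            retained.append(result)
        else:
            rejected.append(result)
    model = HBaggingModel(retained=retained, rejected=rejected, config=config,
                          n_train=int(complete.sum()))
    if model.empty:
        logger.warning("empty ensemble: every weak classifier was rejected")
    return model


def predict_score(model: HBaggingModel, X: pd.DataFrame) -> np.ndarray:
    """Mean of the retained classifiers' binary votes, one score per row.

    An empty ensemble abstains with 0.5 everywhere.  A missing retained
    feature (absent column or NaN in a row) is a contract violation.
    """
    if model.empty:
        logger.warning("empty ensemble: predicting 0.5 for every row")
        return np.full(len(X), 0.5)
    missing = [w.feature for w in model.retained if w.feature not in X]
    if missing:
        raise KeyError(f"rows lack retained features: {missing}")
    votes = np.zeros(len(X))
    for w in model.retained:
        col = X[w.feature].to_numpy(dtype=float)
        if np.any(~np.isfinite(col)):
            raise ValueError(
                f"missing values in retained feature {w.feature!r}"
            )
        votes += w.votes(col)
    return votes / len(model.retained)


def predict_label(model: HBaggingModel, X: pd.DataFrame) -> np.ndarray:
    return predict_score(model, X) > 0.5


def describe(model: HBaggingModel) -> pd.DataFrame:
    """Human-readable audit table of every retained classifier."""
    return pd.DataFrame(
        [
            {
                "feature": w.feature,
                "orientation": "high-when-large" if w.orientation > 0
                else "high-when-small",
                "threshold": w.threshold,
                "train_auc": w.train_auc,
            }
            for w in model.retained
        ],
        columns=["feature", "orientation", "threshold", "train_auc"],
    )
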