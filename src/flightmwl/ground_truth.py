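"""Binarization of raw mental-workload assessments into low/high labels.

Three assessment sources are supported:

* oral self-reports (0-100), binarized against a personal threshold - the
  75th percentile of the pilot's own baseline-scenario reports, so that
  "high" means "high for this pilot";
* the experimental Raw-TLX (RTLX, unweighted mean of the six NASA-TLX
  sub-scores) and its individual sub-scales, binarized against the fixed
  meta-analytic aircraft-piloting median of 47.78;
* the theoretical (expert-consensus) RTLX and sub-scales, same threshold.

The comparison convention is strictly-greater: a score exactly equal to its
threshold is "low".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .session_io import TLX_SUBSCALES

#: meta-analytic median RTLX answer for aircraft-piloting tasks
DEFAULT_RTLX_THRESHOLD = 47.78

#: supported ground-truth kinds; sub-scale kinds are "rtlx/<name>" and
#: "theoretical-rtlx/<name>"
BASE_KINDS = ("selfreport", "rtlx", "theoretical-rtlx")

#: sub-scales that are structurally single-class in cockpit settings:
#: physical demand never reaches "high", performance rarely reaches "low"
SINGLE_CLASS_SUBSCALES = ("physical", "performance")


class GroundTruthError(ValueError):
    """Invalid or insufficient assessment data for label construction."""


@dataclass(frozen=True)
class BinarizationConfig:
    selfreport_percentile: float = 75.0
    rtlx_threshold: float = DEFAULT_RTLX_THRESHOLD
    include_scenario1: bool = True  # baseline windows enter training too

    def __post_init__(self) -> None:
        if not 0.0 < self.selfreport_percentile < 100.0:
            raise ValueError("selfreport_percentile must be in (0, 100)")
        if not 0.0 <= self.rtlx_threshold <= 100.0:
            raise ValueError("rtlx_threshold must be in [0, 100]")


@dataclass
class MWLLabelSet:
    """Per-window binary labels with full provenance.

    ``frame`` columns: raw (the score that was thresholded), threshold,
    label ("low"/"high").  Rows align positionally with the feature matrix
    the labels were built from.
    """

    frame: pd.DataFrame
    kind: str
    flags: dict = field(default_factory=dict)

    @property
    def y(self) -> np.ndarray:
        """Boolean array, True = high workload."""
        return (self.frame["label"] == "high").to_numpy()

    @property
    def single_class(self) -> bool:
        return len(set(self.frame["label"])) < 2

    def to_csv(self, path: str) -> None:
        out = self.frame.copy()
        out["kind"] = self.kind
        out.to_csv(path, index=False)


def personal_threshold(
    scenario1_scores, percentile: float = 75.0
) -> float:
    """Percentile of a pilot's baseline-scenario self-reports, with linear
    interpolation between closest ranks."""
    scores = np.asarray(list(scenario1_scores), dtype=float)
    if len(scores) == 0:
        raise GroundTruthError("no scenario-1 self-reports to threshold on")
    return float(np.percentile(scores, percentile, method="linear"))


def rtlx_score(subscores) -> float:
    """Unweighted mean of the six NASA-TLX sub-scores."""
    values = np.asarray(list(subscores), dtype=float)
    if values.shape != (6,):
        raise GroundTruthError(
            f"RTLX needs exactly six sub-scores, got {values.shape}"
        )
    return float(values.mean())


def binarize(score: float, threshold: float) -> str:
    """"high" iff the score strictly exceeds the threshold."""
    return "high" if score > threshold else "low"


def _parse_kind(kind: str) -> tuple[str, str | None]:
    base, _, sub = kind.partition("/")
    if base not in BASE_KINDS:
        raise GroundTruthError(
            f"unknown ground-truth kind {kind!r}; base must be one of "
            f"{BASE_KINDS}"
        )
    if sub and sub not in TLX_SUBSCALES:
        raise GroundTruthError(
            f"unknown TLX sub-scale {sub!r}; expected one of {TLX_SUBSCALES}"
        )
    if base == "selfreport" and sub:
        raise GroundTruthError("selfreport kind has no sub-scales")
    return base, (sub or None)


def build_labels(
    meta: pd.DataFrame,
    kind: str = "selfreport",
    config: BinarizationConfig = BinarizationConfig(),
) -> MWLLabelSet:
    """Labels for the windows described by a feature-matrix ``meta`` table.

    For ``selfreport``, each pilot's threshold is the configured percentile
    of their own baseline-scenario reports (error if a pilot has none).
    For TLX kinds the fixed RTLX threshold applies to the unweighted mean of
    the six sub-scores, or to a single sub-scale for ``rtlx/<name>`` /
    ``theoretical-rtlx/<name>``.
    """
    base, sub = _parse_kind(kind)
    flags: dict = {}

    if base == "selfreport":
        if "raw_score" not in meta:
            raise GroundTruthError(
                "meta lacks raw_score: not a self-report window table"
            )
        thresholds = {}
        for pilot, group in meta.groupby("pilot_id"):
            s1 = group.loc[group["scenario"] == "baseline", "raw_score"]
            if not len(s1):
                raise GroundTruthError(
                    f"pilot {pilot} has no scenario-1 self-reports"
                )
            thresholds[pilot] = personal_threshold(
                s1, config.selfreport_percentile
            )
        raw = meta["raw_score"].to_numpy(dtype=float)
        thr = meta["pilot_id"].map(thresholds).to_numpy(dtype=float)
    else:
        prefix = "theo_" if base == "theoretical-rtlx" else ""
        cols = [f"{prefix}{s}" for s in TLX_SUBSCALES]
        missing = [c for c in cols if c not in meta]
        if missing:
            raise GroundTruthError(
                f"meta lacks TLX columns {missing}: not a task window table"
            )
        if sub is None:
            raw = meta[cols].to_numpy(dtype=float).mean(axis=1)
        else:
            raw = meta[f"{prefix}{sub}"].to_numpy(dtype=float)
            if sub in SINGLE_CLASS_SUBSCALES:
                flags["structurally_single_class"] = sub
        thr = np.full(len(meta), config.rtlx_threshold)

    labels = np.where(raw > thr, "high", "low")
    frame = pd.DataFrame({"raw": raw, "threshold": thr, "label": labels},
                         index=meta.index)
    if not config.include_scenario1 and base == "selfreport":
        keep = (meta["scenario"] != "baseline").to_numpy()
        frame = frame[keep]
        flags["scenario1_excluded"] = True
    return MWLLabelSet(frame=frame, kind=kind, flags=flags)
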