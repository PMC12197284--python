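"""Windowed multimodal feature extraction.

Seventy-six features are computed on evaluation windows, split into three
categories: 23 from the physiology of the operator (cardiac, respiratory
and gaze statistics, time in each gaze area of interest), 28 from the state
of the machine (helicopter attitude statistics, time in each autopilot
sub-mode) and 25 from the operator's actions on the interface (displacement
and force statistics of the four manipulanda, plus the proportion of time
in radio communication).

Two window kinds exist.  Oral self-reports get a fixed 50 s window running
from 40 s before the report to 10 s after it.  NASA-TLX assessments get
variable windows spanning the full evaluated task.

Physiological features are baseline-normalized per pilot by subtracting the
pilot's mean over the first (baseline) scenario, so that the model sees the
deviation from a personal resting level rather than idiosyncratic absolute
values.

Conventions used throughout: the standard deviation uses the n-1
denominator; crossing counts are reported per second so windows of unequal
length stay comparable; dwell features are fractions of window time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .session_io import (
    DEFAULT_AOI_CATEGORIES,
    DEFAULT_HORIZONTAL_MODES,
    DEFAULT_VERTICAL_MODES,
    MANIPULANDA,
    Channel,
    Cohort,
    SessionRecording,
)

logger = logging.getLogger(__name__)

#: 0.95 quantile of the chi-square distribution with 2 degrees of freedom
CHI2_95_2DF = float(chi2.ppf(0.95, df=2))

PHYSIOLOGY = "physiology"
MACHINE = "machine"
INTERFACE = "interface"


class WindowError(ValueError):
    """A requested evaluation window is invalid."""


@dataclass(frozen=True)
class WindowSpec:
    """Evaluation-window geometry.

    ``selfreport`` windows cover ``[t - pre_seconds, t + post_seconds)``
    around the report time; ``task-interval`` windows span the evaluated
    task.
    """

    kind: str = "selfreport"
    pre_seconds: float = 40.0
    post_seconds: float = 10.0


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable constants of the extraction stage."""

    min_coverage: float = 0.8          # fraction of expected samples required
    velocity_threshold_deg_s: float = 30.0
    min_fixation_s: float = 0.1
    pixels_per_degree: float = 35.0    # gaze calibration constant
    sd_ddof: int = 1


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    category: str
    source: str
    statistic: str


@dataclass
class FeatureRegistry:
    """The named feature set, each entry tagged with its category."""

    entries: list[FeatureSpec]

    @classmethod
    def default(
        cls,
        aoi_categories: tuple[str, ...] = DEFAULT_AOI_CATEGORIES,
        horizontal_modes: tuple[str, ...] = DEFAULT_HORIZONTAL_MODES,
        vertical_modes: tuple[str, ...] = DEFAULT_VERTICAL_MODES,
    ) -> "FeatureRegistry":
        e: list[FeatureSpec] = []

        def add(name, category, source, statistic):
            e.append(FeatureSpec(name, category, source, statistic))

        for ch in ("heart_rate", "ibi", "breathing_rate"):
            add(f"{ch}_mean", PHYSIOLOGY, ch, "mean")
            add(f"{ch}_sd", PHYSIOLOGY, ch, "sd")
        add("fixation_duration_mean", PHYSIOLOGY, "gaze", "fixation_duration")
        add("saccade_duration_mean", PHYSIOLOGY, "gaze", "saccade_duration")
        add("saccade_amplitude_mean", PHYSIOLOGY, "gaze", "saccade_amplitude")
        add("gaze_ellipse_area", PHYSIOLOGY, "gaze", "prediction_ellipse")
        for cat in aoi_categories:
            add(f"aoi_{cat}", PHYSIOLOGY, "aoi", "dwell")

        add("altitude_sd", MACHINE, "altitude", "sd")
        add("altitude_mean_crossings", MACHINE, "altitude", "mean_crossings")
        add("yaw_sd", MACHINE, "yaw", "sd")
        add("yaw_mean_crossings", MACHINE, "yaw", "mean_crossings")
        for ch in ("pitch", "roll"):
            add(f"{ch}_mean", MACHINE, ch, "mean")
            add(f"{ch}_sd", MACHINE, ch, "sd")
            add(f"{ch}_mean_crossings", MACHINE, ch, "mean_crossings")
        for mode in horizontal_modes:
            add(f"ap_horizontal_{mode}", MACHINE, "autopilot", "dwell")
        for mode in vertical_modes:
            add(f"ap_vertical_{mode}", MACHINE, "autopilot", "dwell")

        for m in MANIPULANDA:
            add(f"{m}_displacement_mean", INTERFACE, m, "mean")
            add(f"{m}_displacement_sd", INTERFACE, m, "sd")
            add(f"{m}_displacement_mean_crossings", INTERFACE, m,
                "mean_crossings")
            add(f"{m}_force_mean", INTERFACE, m, "mean")
            add(f"{m}_force_sd", INTERFACE, m, "sd")
            add(f"{m}_force_zero_crossings", INTERFACE, m, "zero_crossings")
        add("communication_proportion", INTERFACE, "comm", "dwell")

        return cls(entries=e)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.entries]

    def category_of(self, name: str) -> str:
        for s in self.entries:
            if s.name == name:
                return s.category
        raise KeyError(name)

    def names_in(self, category: str) -> list[str]:
        return [s.name for s in self.entries if s.category == category]

    @property
    def counts(self) -> dict[str, int]:
        c = {PHYSIOLOGY: 0, MACHINE: 0, INTERFACE: 0}
        for s in self.entries:
            c[s.category] += 1
        c["total"] = len(self.entries)
        return c

    def to_json_dict(self) -> dict:
        return {
            "entries": [vars(s) for s in self.entries],
            "counts": self.counts,
        }


# ---------------------------------------------------------------------------
# window geometry
# ---------------------------------------------------------------------------


def selfreport_window(
    t_report: float,
    session_duration: float,
    spec: WindowSpec = WindowSpec(),
) -> tuple[float, float, bool]:
    """Window ``[t - pre, t + post)`` around a self-report, clipped to the
    session; returns ``(t0, t1, truncated)``."""
    if not 0.0 <= t_report <= session_duration:
        raise WindowError(
            f"report time {t_report} outside session [0, {session_duration}]"
        )
    t0 = t_report - spec.pre_seconds
    t1 = t_report + spec.post_seconds
    truncated = t0 < 0.0 or t1 > session_duration
    return max(t0, 0.0), min(t1, session_duration), truncated


def _slice(channel: Channel, interval: tuple[float, float]) -> np.ndarray:
    t0, t1 = interval
    i0 = int(np.ceil((t0 - channel.start_time) * channel.rate - 1e-9))
    i1 = int(np.ceil((t1 - channel.start_time) * channel.rate - 1e-9))
    return channel.values[max(i0, 0):max(i1, 0)]


def _coverage_ok(n: int, rate: float, interval, min_coverage: float) -> bool:
    expected = (interval[1] - interval[0]) * rate
    return expected > 0 and n >= min_coverage * expected


# ---------------------------------------------------------------------------
# scalar statistics
# ---------------------------------------------------------------------------


def window_mean_std(
    channel: Channel,
    interval: tuple[float, float],
    config: FeatureConfig = FeatureConfig(),
    column: str | None = None,
) -> tuple[float, float]:
    """Sample mean and n-1 standard deviation over the window; ``(nan, nan)``
    when sample coverage falls below the configured minimum."""
    values = _slice(channel, interval)
    if column is not None:
        values = values[:, channel.columns.index(column)]
    values = values[np.isfinite(values)]
    if not _coverage_ok(len(values), channel.rate, interval,
                        config.min_coverage):
        logger.debug("window %s on %s: insufficient coverage", interval,
                     channel.name)
        return float("nan"), float("nan")
    sd = float(np.std(values, ddof=config.sd_ddof)) if len(values) > 1 else 0.0
    return float(np.mean(values)), sd


def _crossings(values: np.ndarray, center: float) -> float:
    """Strict sign changes of ``values - center``; zero deviations inherit
    the previous nonzero sign.  NaN if fewer than 2 usable samples."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 2:
        return float("nan")
    signs = np.sign(values - center)
    nonzero = signs != 0
    if not np.any(nonzero):
        return 0.0
    # propagate the last nonzero sign forward over exact-zero deviations
    idx = np.where(nonzero, np.arange(len(signs)), 0)
    np.maximum.accumulate(idx, out=idx)
    filled = signs[idx]
    first = np.argmax(nonzero)
    filled[:first] = signs[first]
    return float(np.sum(filled[1:] != filled[:-1]))


def mean_crossings(
    channel: Channel,
    interval: tuple[float, float],
    column: str | None = None,
) -> float:
    """Number of strict sign changes around the window mean."""
    values = _slice(channel, interval)
    if column is not None:
        values = values[:, channel.columns.index(column)]
    values = values[np.isfinite(values)]
    if len(values) < 2:
        return float("nan")
    return _crossings(values, float(np.mean(values)))


def zero_crossings(
    channel: Channel,
    interval: tuple[float, float],
    column: str | None = None,
) -> float:
    """Number of strict sign changes around zero."""
    values = _slice(channel, interval)
    if column is not None:
        values = values[:, channel.columns.index(column)]
    return _crossings(values, 0.0)


def prediction_ellipse_area(xy: np.ndarray) -> tuple[float, bool]:
    """Area of the 95% prediction ellipse of bivariate gaze samples.

    Under a Gaussian model the ellipse expected to contain 95% of samples
    has area ``pi * q * sqrt(l1 * l2)`` where ``q`` is the 0.95 chi-square
    quantile with 2 degrees of freedom and ``l1, l2`` the eigenvalues of the
    sample covariance.  Returns ``(area, degenerate)``; a rank-deficient
    covariance (collinear points) yields area 0 with the flag set.
    """
    xy = np.asarray(xy, dtype=float)
    xy = xy[np.all(np.isfinite(xy), axis=1)]
    if len(xy) < 3:
        return float("nan"), True
    cov = np.cov(xy, rowvar=False, ddof=1)
    eigvals = np.linalg.eigvalsh(cov)
    scale = max(float(np.max(np.abs(eigvals))), 1.0)
    if np.min(eigvals) <= 1e-12 * scale:
        return 0.0, True
    return float(np.pi * CHI2_95_2DF * np.sqrt(np.prod(eigvals))), False


@dataclass(frozen=True)
class GazeEventSummary:
    fixation_duration_mean: float
    saccade_duration_mean: float
    saccade_amplitude_mean: float   # degrees
    n_fixations: int
    n_saccades: int


def detect_fixations_saccades(
    x: np.ndarray,
    y: np.ndarray,
    rate: float,
    config: FeatureConfig = FeatureConfig(),
) -> GazeEventSummary:
    """I-VT segmentation of a gaze trace into fixations and saccades.

    A sample belongs to a saccade when the point-to-point velocity exceeds
    the configured threshold (degrees/second via the pixels-per-degree
    calibration).  Complementary runs lasting at least ``min_fixation_s``
    are fixations.  Saccade amplitude is the start-to-end displacement in
    degrees.  With no saccade detected the whole window counts as one
    fixation and saccade statistics are missing.
    """
    if config.pixels_per_degree <= 0:
        raise ValueError("pixels_per_degree calibration must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 2:
        return GazeEventSummary(float("nan"), float("nan"), float("nan"), 0, 0)
    dist = np.hypot(np.diff(x), np.diff(y))
    vel = dist * rate / config.pixels_per_degree  # deg/s between samples
    is_sacc = vel > config.velocity_threshold_deg_s  # length n-1

    fix_durs: list[float] = []
    sacc_durs: list[float] = []
    sacc_amps: list[float] = []
    # runs over the n-1 inter-sample steps
    boundaries = np.flatnonzero(np.diff(is_sacc.astype(int))) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(is_sacc)]])
    for s, e in zip(starts, ends):
        dur = (e - s) / rate
        if is_sacc[s]:
            sacc_durs.append(dur)
            amp_px = float(np.hypot(x[e] - x[s], y[e] - y[s]))
            sacc_amps.append(amp_px / config.pixels_per_degree)
        else:
            span = (e - s + 1) / rate  # samples, not steps
            if span >= config.min_fixation_s:
                fix_durs.append(span)
    if not sacc_durs:
        return GazeEventSummary(n / rate, float("nan"), float("nan"), 1, 0)
    return GazeEventSummary(
        fixation_duration_mean=float(np.mean(fix_durs)) if fix_durs
        else float("nan"),
        saccade_duration_mean=float(np.mean(sacc_durs)),
        saccade_amplitude_mean=float(np.mean(sacc_amps)),
        n_fixations=len(fix_durs),
        n_saccades=len(sacc_durs),
    )


def dwell_proportions(
    samples: np.ndarray,
    rate: float,
    interval: tuple[float, float],
    categories: tuple[str, ...],
    start_time: float = 0.0,
) -> dict[str, float]:
    """Per-category fraction of window time for a sampled categorical
    series; fractions sum to 1 for an exhaustive category set."""
    t0, t1 = interval
    i0 = max(0, int(np.ceil((t0 - start_time) * rate - 1e-9)))
    i1 = max(0, int(np.ceil((t1 - start_time) * rate - 1e-9)))
    window = np.asarray(samples[i0:i1])
    if len(window) == 0:
        return {c: float("nan") for c in categories}
    unknown = set(window) - set(categories)
    if unknown:
        raise KeyError(f"unknown categories in data: {sorted(unknown)}")
    return {c: float(np.mean(window == c)) for c in categories}


def interval_dwell(
    intervals: pd.DataFrame,
    interval: tuple[float, float],
    by: tuple[str, ...] | None = None,
    categories: dict[str, tuple[str, ...]] | None = None,
) -> dict[str, float] | float:
    """Fraction of window time covered by logged intervals.

    Without ``by``: a single occupancy fraction (radio communication).
    With ``by`` (e.g. autopilot sub-mode columns): one fraction per category
    of each grouping column, keyed ``"{col}:{category}"``.
    """
    t0, t1 = interval
    width = t1 - t0
    if width <= 0:
        raise WindowError(f"empty window {interval}")
    if not len(intervals):
        overlaps = np.array([])
    else:
        a = np.maximum(intervals["t0"].to_numpy(dtype=float), t0)
        b = np.minimum(intervals["t1"].to_numpy(dtype=float), t1)
        overlaps = np.maximum(b - a, 0.0)
    if by is None:
        return float(overlaps.sum() / width)
    out: dict[str, float] = {}
    for col in by:
        cats = categories[col] if categories else tuple(
            pd.unique(intervals[col]))
        values = intervals[col].to_numpy() if len(intervals) else np.array([])
        if len(values):
            unknown = set(values) - set(cats)
            if unknown:
                raise KeyError(
                    f"unknown {col} categories in data: {sorted(unknown)}")
        for cat in cats:
            mask = values == cat if len(values) else np.array([], dtype=bool)
            out[f"{col}:{cat}"] = float(overlaps[mask].sum() / width)
    return out


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """Windows x features, with pilot/scenario/time provenance in ``meta``.

    ``meta`` columns: pilot_id, scenario, t0, t1, truncated, raw_score (for
    self-report windows) or the TLX sub-scores (task windows), plus ``order``
    - a cohort-wide per-pilot chronological rank used by the temporal split.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    registry: FeatureRegistry
    kind: str = "selfreport"
    normalized: bool = False

    def __post_init__(self) -> None:
        if list(self.values.columns) != self.registry.names:
            raise ValueError("feature columns do not match the registry")
        if len(self.values) != len(self.meta):
            raise ValueError("values/meta row mismatch")

    def write(self, path_prefix: str) -> None:
        self.values.to_csv(f"{path_prefix}_features.csv", index=False)
        self.meta.to_csv(f"{path_prefix}_meta.csv", index=False)
        import json

        with open(f"{path_prefix}_registry.json", "w") as fh:
            json.dump(
                {
                    **self.registry.to_json_dict(),
                    "kind": self.kind,
                    "normalized": self.normalized,
                },
                fh,
                indent=1,
            )

    @classmethod
    def read(cls, path_prefix: str) -> "FeatureMatrix":
        import json

        with open(f"{path_prefix}_registry.json") as fh:
            reg_dict = json.load(fh)
        registry = FeatureRegistry(
            entries=[FeatureSpec(**e) for e in reg_dict["entries"]]
        )
        return cls(
            values=pd.read_csv(f"{path_prefix}_features.csv"),
            meta=pd.read_csv(f"{path_prefix}_meta.csv"),
            registry=registry,
            kind=reg_dict.get("kind", "selfreport"),
            normalized=reg_dict.get("normalized", False),
        )


def _session_window_features(
    session: SessionRecording,
    interval: tuple[float, float],
    registry: FeatureRegistry,
    config: FeatureConfig,
) -> dict[str, float]:
    ch = session.channels
    ev = session.events
    row: dict[str, float] = {}
    width = interval[1] - interval[0]

    for name in ("heart_rate", "ibi", "breathing_rate"):
        m, s = window_mean_std(ch[name], interval, config)
        row[f"{name}_mean"], row[f"{name}_sd"] = m, s

    gx = _slice(ch["gaze_x"], interval)
    gy = _slice(ch["gaze_y"], interval)
    summ = detect_fixations_saccades(gx, gy, ch["gaze_x"].rate, config)
    row["fixation_duration_mean"] = summ.fixation_duration_mean
    row["saccade_duration_mean"] = summ.saccade_duration_mean
    row["saccade_amplitude_mean"] = summ.saccade_amplitude_mean
    area, _ = prediction_ellipse_area(np.column_stack([gx, gy]))
    row["gaze_ellipse_area"] = area

    aoi_cats = tuple(
        s.name.removeprefix("aoi_") for s in registry.entries
        if s.source == "aoi"
    )
    for cat, frac in dwell_proportions(
        ev.aoi_samples, ev.aoi_rate, interval, aoi_cats
    ).items():
        row[f"aoi_{cat}"] = frac

    row["altitude_sd"] = window_mean_std(ch["altitude"], interval, config)[1]
    row["altitude_mean_crossings"] = mean_crossings(ch["altitude"],
                                                    interval) / width
    row["yaw_sd"] = window_mean_std(ch["yaw"], interval, config)[1]
    row["yaw_mean_crossings"] = mean_crossings(ch["yaw"], interval) / width
    for name in ("pitch", "roll"):
        m, s = window_mean_std(ch[name], interval, config)
        row[f"{name}_mean"], row[f"{name}_sd"] = m, s
        row[f"{name}_mean_crossings"] = mean_crossings(ch[name],
                                                       interval) / width

    h_modes = tuple(
        s.name.removeprefix("ap_horizontal_") for s in registry.entries
        if s.name.startswith("ap_horizontal_")
    )
    v_modes = tuple(
        s.name.removeprefix("ap_vertical_") for s in registry.entries
        if s.name.startswith("ap_vertical_")
    )
    ap = interval_dwell(
        ev.autopilot_modes, interval, by=("horizontal", "vertical"),
        categories={"horizontal": h_modes, "vertical": v_modes},
    )
    for key, frac in ap.items():
        col, cat = key.split(":")
        row[f"ap_{col}_{cat}"] = frac

    for m in MANIPULANDA:
        mu, s = window_mean_std(ch[m], interval, config, column="displacement")
        row[f"{m}_displacement_mean"], row[f"{m}_displacement_sd"] = mu, s
        row[f"{m}_displacement_mean_crossings"] = (
            mean_crossings(ch[m], interval, column="displacement") / width
        )
        mu, s = window_mean_std(ch[m], interval, config, column="force")
        row[f"{m}_force_mean"], row[f"{m}_force_sd"] = mu, s
        row[f"{m}_force_zero_crossings"] = (
            zero_crossings(ch[m], interval, column="force") / width
        )

    row["communication_proportion"] = interval_dwell(ev.comm_intervals,
                                                     interval)
    return row


def extract_feature_matrix(
    cohort: Cohort,
    kind: str = "selfreport",
    registry: FeatureRegistry | None = None,
    config: FeatureConfig = FeatureConfig(),
    window_spec: WindowSpec = WindowSpec(),
    normalize: bool = True,
) -> FeatureMatrix:
    """One row per evaluation event across the whole cohort.

    ``kind="selfreport"`` uses 50 s windows around every oral report in both
    scenarios.  ``kind="tlx"`` uses the task intervals of the demanding
    scenario.  Physiological columns are baseline-normalized per pilot
    unless ``normalize=False``.
    """
    if registry is None:
        registry = FeatureRegistry.default()
    if kind not in ("selfreport", "tlx"):
        raise ValueError(f"unknown window kind {kind!r}")

    rows: list[dict[str, float]] = []
    meta_rows: list[dict] = []
    for session in cohort.sessions:
        if kind == "selfreport":
            for _, rep in session.events.selfreports.iterrows():
                t0, t1, truncated = selfreport_window(
                    float(rep["time"]), session.duration, window_spec
                )
                rows.append(_session_window_features(session, (t0, t1),
                                                     registry, config))
                meta_rows.append(
                    {
                        "pilot_id": session.pilot_id,
                        "scenario": session.scenario,
                        "t0": t0,
                        "t1": t1,
                        "truncated": truncated,
                        "raw_score": float(rep["score"]),
                    }
                )
        else:
            for _, task in session.events.tlx_tasks.iterrows():
                t0, t1 = float(task["t0"]), float(task["t1"])
                rows.append(_session_window_features(session, (t0, t1),
                                                     registry, config))
                meta = {
                    "pilot_id": session.pilot_id,
                    "scenario": session.scenario,
                    "t0": t0,
                    "t1": t1,
                    "truncated": False,
                    "phase": task["phase"],
                }
                for col in session.events.tlx_tasks.columns:
                    if col not in ("t0", "t1", "phase"):
                        meta[col] = float(task[col])
                meta_rows.append(meta)

    values = pd.DataFrame(rows, columns=registry.names)
    meta = pd.DataFrame(meta_rows)
    if len(meta):
        # per-pilot chronological rank: baseline session precedes demanding,
        # then window end time within a session
        scen_order = meta["scenario"].map({"baseline": 0, "demanding": 1})
        sort_key = scen_order * 1e9 + meta["t1"]
        meta["order"] = sort_key.groupby(meta["pilot_id"]).rank(method="first")
    matrix = FeatureMatrix(values=values, meta=meta, registry=registry,
                           kind=kind)
    if normalize:
        normalizer = PhysiologyNormalizer.fit_cohort(cohort, registry, config,
                                                     window_spec)
        matrix = normalizer.transform(matrix)
    return matrix


@dataclass
class PhysiologyNormalizer:
    """Per-pilot baseline means of the physiological features.

    Fitted on each pilot's baseline-scenario self-report windows; applying
    it subtracts those means from the physiology columns only, leaving
    machine and interface features untouched.
    """

    baseline_means: pd.DataFrame  # index pilot_id, columns physiology features
    physiology_columns: list[str]

    @classmethod
    def fit_matrix(cls, matrix: FeatureMatrix) -> "PhysiologyNormalizer":
        phys = matrix.registry.names_in(PHYSIOLOGY)
        base = matrix.meta["scenario"] == "baseline"
        if not base.any():
            raise ValueError("no baseline-scenario windows to normalize from")
        means = (
            matrix.values.loc[base, phys]
            .groupby(matrix.meta.loc[base, "pilot_id"])
            .mean()
        )
        missing = set(matrix.meta["pilot_id"]) - set(means.index)
        if missing:
            raise ValueError(
                f"pilots without baseline windows: {sorted(missing)}"
            )
        return cls(baseline_means=means, physiology_columns=phys)

    @classmethod
    def fit_cohort(
        cls,
        cohort: Cohort,
        registry: FeatureRegistry,
        config: FeatureConfig = FeatureConfig(),
        window_spec: WindowSpec = WindowSpec(),
    ) -> "PhysiologyNormalizer":
        reference = extract_feature_matrix(
            Cohort([s for s in cohort.sessions if s.scenario == "baseline"]),
            kind="selfreport", registry=registry, config=config,
            window_spec=window_spec, normalize=False,
        )
        phys = registry.names_in(PHYSIOLOGY)
        means = reference.values[phys].groupby(
            reference.meta["pilot_id"]).mean()
        if not len(means):
            raise ValueError("no baseline-scenario windows to normalize from")
        return cls(baseline_means=means, physiology_columns=phys)

    def transform(self, matrix: FeatureMatrix) -> FeatureMatrix:
        missing = set(matrix.meta["pilot_id"]) - set(self.baseline_means.index)
        if missing:
            raise ValueError(
                f"pilots without baseline windows: {sorted(missing)}"
            )
        values = matrix.values.copy()
        offsets = self.baseline_means.reindex(
            matrix.meta["pilot_id"]).to_numpy()
        values[self.physiology_columns] = (
            values[self.physiology_columns].to_numpy() - offsets
        )
        return FeatureMatrix(values=values, meta=matrix.meta.copy(),
                             registry=matrix.registry, kind=matrix.kind,
                             normalized=True)


def normalize_physiological(matrix: FeatureMatrix) -> FeatureMatrix:
    """Baseline-normalize a self-report matrix using its own scenario-1 rows."""
    return PhysiologyNormalizer.fit_matrix(matrix).transform(matrix)
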