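"""On-disk and in-memory representation of flight-session recordings.

A session is one pilot flying one scenario in the simulator.  It bundles
uniformly sampled numeric channels (cardiac, respiratory, gaze, helicopter
state, manipulanda) with event logs (oral self-reports of mental workload,
NASA-TLX task intervals, radio-communication intervals, autopilot sub-mode
intervals, and the categorical gaze area-of-interest stream).

Storage layout is deliberately plain: one CSV per channel, one CSV per event
table and a JSON manifest, so that recordings are human-inspectable and
diff-able.  All time coordinates are seconds from session start (t = 0) and
every interval is half-open ``[t0, t1)``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: scenarios, in their within-pilot chronological order
SCENARIOS = ("baseline", "demanding")

#: the four physical flight controls instrumented for displacement and force
MANIPULANDA = ("collective", "pedals", "cyclic_pitch", "cyclic_roll")

#: default gaze area-of-interest taxonomy (13 categories, "outside" = out of
#: the cockpit through the windshield)
DEFAULT_AOI_CATEGORIES = (
    "outside",
    "pfd",
    "nd",
    "altimeter",
    "airspeed",
    "vario",
    "engine",
    "autopilot_panel",
    "radio",
    "map",
    "overhead",
    "copilot",
    "other",
)

#: default autopilot sub-mode sets ("off" = hands-on flying on that axis)
DEFAULT_HORIZONTAL_MODES = (
    "off", "hdg", "nav", "app", "loc", "vor", "gps", "hover", "trk", "beam",
)
DEFAULT_VERTICAL_MODES = (
    "off", "alt", "vs", "ias", "gs", "rht", "ga",
    "alt_acq",
)

#: mandatory channel families: name -> (columns, units)
CHANNEL_SCHEMA: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "heart_rate": (("value",), ("bpm",)),
    "ibi": (("value",), ("ms",)),
    "breathing_rate": (("value",), ("bpm",)),
    "gaze_x": (("value",), ("px",)),
    "gaze_y": (("value",), ("px",)),
    "altitude": (("value",), ("ft",)),
    "yaw": (("value",), ("deg",)),
    "pitch": (("value",), ("deg",)),
    "roll": (("value",), ("deg",)),
    "collective": (("displacement", "force"), ("%", "daN")),
    "pedals": (("displacement", "force"), ("%", "daN")),
    "cyclic_pitch": (("displacement", "force"), ("%", "daN")),
    "cyclic_roll": (("displacement", "force"), ("%", "daN")),
}

MANDATORY_CHANNELS = tuple(CHANNEL_SCHEMA)

TLX_SUBSCALES = (
    "mental", "physical", "temporal", "performance", "frustration", "effort",
)


class SessionValidationError(ValueError):
    """A recording violates the session schema."""


class SessionParseError(ValueError):
    """A stored session file could not be parsed."""


@dataclass
class Channel:
    """A uniformly sampled numeric channel.

    ``values`` has shape ``(n,)`` for single-column channels or ``(n, k)``
    for multi-column channels (the manipulanda carry displacement and force
    together).  Missing samples are NaN.
    """

    name: str
    rate: float  # Hz
    values: np.ndarray
    columns: tuple[str, ...] = ("value",)
    units: tuple[str, ...] = ("",)
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise SessionValidationError(
                f"channel {self.name!r}: rate must be > 0, got {self.rate}"
            )
        ncol = 1 if self.values.ndim == 1 else self.values.shape[1]
        if ncol != len(self.columns):
            raise SessionValidationError(
                f"channel {self.name!r}: {ncol} value columns but "
                f"{len(self.columns)} column names"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.rate

    def column(self, name: str) -> np.ndarray:
        if self.values.ndim == 1:
            if name != self.columns[0]:
                raise KeyError(name)
            return self.values
        return self.values[:, self.columns.index(name)]

    def __eq__(self, other: object) -> bool:  # value equality for tests
        if not isinstance(other, Channel):
            return NotImplemented
        return (
            self.name == other.name
            and self.rate == other.rate
            and self.columns == other.columns
            and self.start_time == other.start_time
            and self.values.shape == other.values.shape
            and np.allclose(self.values, other.values, equal_nan=True)
        )


@dataclass
class EventLog:
    """Event tables of a single session.

    selfreports:     columns ``time, score`` (oral ratings, 0-100)
    tlx_tasks:       columns ``t0, t1, phase`` plus the six experimental
                     sub-scores and six ``theo_*`` expert-consensus sub-scores
    comm_intervals:  columns ``t0, t1``
    autopilot_modes: columns ``t0, t1, horizontal, vertical``
    aoi_samples:     categorical gaze-target series sampled at ``aoi_rate``
    """

    selfreports: pd.DataFrame
    tlx_tasks: pd.DataFrame
    comm_intervals: pd.DataFrame
    autopilot_modes: pd.DataFrame
    aoi_samples: np.ndarray
    aoi_rate: float = 60.0

    @staticmethod
    def empty() -> "EventLog":
        return EventLog(
            selfreports=pd.DataFrame(columns=["time", "score"]),
            tlx_tasks=pd.DataFrame(
                columns=["t0", "t1", "phase"]
                + list(TLX_SUBSCALES)
                + [f"theo_{s}" for s in TLX_SUBSCALES]
            ),
            comm_intervals=pd.DataFrame(columns=["t0", "t1"]),
            autopilot_modes=pd.DataFrame(
                columns=["t0", "t1", "horizontal", "vertical"]
            ),
            aoi_samples=np.array([], dtype=object),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventLog):
            return NotImplemented
        for attr in ("selfreports", "tlx_tasks", "comm_intervals",
                     "autopilot_modes"):
            a = getattr(self, attr).reset_index(drop=True)
            b = getattr(other, attr).reset_index(drop=True)
            if list(a.columns) != list(b.columns) or len(a) != len(b):
                return False
            for col in a.columns:
                av, bv = a[col].to_numpy(), b[col].to_numpy()
                if av.dtype.kind in "ifu" and bv.dtype.kind in "ifu":
                    # numeric: equal within the declared storage precision
                    if not np.allclose(av.astype(float), bv.astype(float),
                                       rtol=1e-9, atol=1e-9, equal_nan=True):
                        return False
                elif not np.array_equal(av, bv):
                    return False
        return (
            self.aoi_rate == other.aoi_rate
            and len(self.aoi_samples) == len(other.aoi_samples)
            and bool(np.all(self.aoi_samples == other.aoi_samples))
        )


@dataclass
class SessionRecording:
    """All channels and event logs for one pilot x one scenario."""

    pilot_id: int
    scenario: str
    duration: float
    channels: dict[str, Channel]
    events: EventLog

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise SessionValidationError(
                f"unknown scenario {self.scenario!r}; expected one of "
                f"{SCENARIOS}"
            )

    def validate(self) -> None:
        """Raise :class:`SessionValidationError` on any schema violation."""
        for name in MANDATORY_CHANNELS:
            if name not in self.channels:
                raise SessionValidationError(
                    f"session pilot={self.pilot_id} scenario={self.scenario}:"
                    f" missing mandatory channel {name!r}"
                )
        for name, ch in self.channels.items():
            if ch.name != name:
                raise SessionValidationError(
                    f"channel key {name!r} does not match channel name "
                    f"{ch.name!r}"
                )
        ev = self.events
        scores = ev.selfreports["score"].to_numpy(dtype=float)
        if len(scores) and (np.nanmin(scores) < 0 or np.nanmax(scores) > 100):
            raise SessionValidationError("self-report scores outside [0, 100]")
        for attr in ("tlx_tasks", "comm_intervals", "autopilot_modes"):
            df = getattr(ev, attr)
            if not len(df):
                continue
            t0 = df["t0"].to_numpy(dtype=float)
            t1 = df["t1"].to_numpy(dtype=float)
            if np.any(t0 < 0) or np.any(t1 > self.duration + 1e-9):
                raise SessionValidationError(
                    f"{attr}: interval outside session bounds [0, "
                    f"{self.duration}]"
                )
            if np.any(t1 <= t0):
                raise SessionValidationError(f"{attr}: empty or reversed interval")
            order = np.argsort(t0)
            if np.any(t1[order][:-1] > t0[order][1:] + 1e-9):
                raise SessionValidationError(f"{attr}: overlapping intervals")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SessionRecording):
            return NotImplemented
        return (
            self.pilot_id == other.pilot_id
            and self.scenario == other.scenario
            and self.duration == other.duration
            and set(self.channels) == set(other.channels)
            and all(self.channels[k] == other.channels[k] for k in self.channels)
            and self.events == other.events
        )


@dataclass
class Cohort:
    """An ordered collection of sessions: per pilot, baseline then demanding."""

    sessions: list[SessionRecording] = field(default_factory=list)

    def validate(self) -> None:
        seen: dict[int, list[str]] = {}
        for s in self.sessions:
            seen.setdefault(s.pilot_id, []).append(s.scenario)
        for pilot, scens in seen.items():
            if sorted(scens) != sorted(SCENARIOS):
                raise SessionValidationError(
                    f"pilot {pilot}: expected exactly one baseline and one "
                    f"demanding session, got {scens}"
                )

    @property
    def pilots(self) -> list[int]:
        return sorted({s.pilot_id for s in self.sessions})

    def session(self, pilot_id: int, scenario: str) -> SessionRecording:
        for s in self.sessions:
            if s.pilot_id == pilot_id and s.scenario == scenario:
                return s
        raise KeyError((pilot_id, scenario))


# ---------------------------------------------------------------------------
# disk I/O
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.10g"


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _read_csv(path: Path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, **kw)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise SessionParseError(f"{path}: {exc}") from exc


def write_session(session: SessionRecording, directory: str | Path) -> Path:
    """Write a session to ``directory`` and return the manifest path.

    The session is validated before anything is written, so a schema
    violation never leaves a partial recording on disk.
    """
    session.validate()
    directory = Path(directory)
    (directory / "channels").mkdir(parents=True, exist_ok=True)
    (directory / "events").mkdir(parents=True, exist_ok=True)

    channel_entries = []
    for name, ch in session.channels.items():
        values = ch.values if ch.values.ndim == 2 else ch.values[:, None]
        df = pd.DataFrame({"time": ch.times()})
        for j, col in enumerate(ch.columns):
            df[col] = values[:, j]
        rel = f"channels/{name}.csv"
        _write_csv(df, directory / rel)
        channel_entries.append(
            {
                "name": name,
                "rate": ch.rate,
                "start_time": ch.start_time,
                "columns": list(ch.columns),
                "units": list(ch.units),
                "file": rel,
            }
        )

    ev = session.events
    event_files = {}
    for attr in ("selfreports", "tlx_tasks", "comm_intervals",
                 "autopilot_modes"):
        rel = f"events/{attr}.csv"
        _write_csv(getattr(ev, attr), directory / rel)
        event_files[attr] = rel
    aoi_df = pd.DataFrame(
        {
            "time": np.arange(len(ev.aoi_samples)) / ev.aoi_rate,
            "aoi": ev.aoi_samples,
        }
    )
    _write_csv(aoi_df, directory / "events/aoi.csv")
    event_files["aoi"] = "events/aoi.csv"

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "pilot_id": session.pilot_id,
        "scenario": session.scenario,
        "duration": session.duration,
        "aoi_rate": ev.aoi_rate,
        "channels": channel_entries,
        "events": event_files,
        "conventions": {
            "time_origin": "seconds from session start (t=0)",
            "intervals": "half-open [t0, t1)",
            "indexing": "0-based sample indices",
            "missing": "empty CSV field",
        },
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def read_session(manifest_path: str | Path) -> SessionRecording:
    """Load and validate a session previously written by :func:`write_session`."""
    manifest_path = Path(manifest_path)
    directory = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise SessionParseError(
            f"{manifest_path}: unsupported schema version "
            f"{manifest.get('schema_version')!r}"
        )

    channels: dict[str, Channel] = {}
    for entry in manifest["channels"]:
        path = directory / entry["file"]
        df = _read_csv(path)
        t = df["time"].to_numpy(dtype=float)
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            bad = int(np.argmax(np.diff(t) <= 0)) + 2  # 1-based + header row
            raise SessionValidationError(
                f"{path}: non-monotonic time column near line {bad}"
            )
        cols = entry["columns"]
        values = df[cols].to_numpy(dtype=float)
        if len(cols) == 1:
            values = values[:, 0]
        channels[entry["name"]] = Channel(
            name=entry["name"],
            rate=float(entry["rate"]),
            start_time=float(entry["start_time"]),
            values=values,
            columns=tuple(cols),
            units=tuple(entry["units"]),
        )

    known = {e["file"] for e in manifest["channels"]}
    for extra in sorted((directory / "channels").glob("*.csv")):
        if f"channels/{extra.name}" not in known:
            warnings.warn(f"ignoring unknown channel file {extra}", stacklevel=2)

    ev_files = manifest["events"]
    aoi_df = _read_csv(directory / ev_files["aoi"])
    events = EventLog(
        selfreports=_read_csv(directory / ev_files["selfreports"]),
        tlx_tasks=_read_csv(directory / ev_files["tlx_tasks"]),
        comm_intervals=_read_csv(directory / ev_files["comm_intervals"]),
        autopilot_modes=_read_csv(directory / ev_files["autopilot_modes"]),
        aoi_samples=aoi_df["aoi"].to_numpy(dtype=object),
        aoi_rate=float(manifest["aoi_rate"]),
    )

    session = SessionRecording(
        pilot_id=int(manifest["pilot_id"]),
        scenario=manifest["scenario"],
        duration=float(manifest["duration"]),
        channels=channels,
        events=events,
    )
    session.validate()
    return session


def write_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """Write every session plus a cohort-level index; return the index path."""
    cohort.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in cohort.sessions:
        sub = directory / f"pilot{s.pilot_id:02d}_{s.scenario}"
        write_session(s, sub)
        entries.append(
            {
                "pilot_id": s.pilot_id,
                "scenario": s.scenario,
                "order": SCENARIOS.index(s.scenario),
                "manifest": f"{sub.name}/manifest.json",
            }
        )
    index = {"schema_version": SCHEMA_VERSION, "sessions": entries}
    index_path = directory / "cohort.json"
    index_path.write_text(json.dumps(index, indent=1))
    return index_path


def read_cohort(index_path: str | Path) -> Cohort:
    index_path = Path(index_path)
    index = json.loads(index_path.read_text())
    sessions = [
        read_session(index_path.parent / e["manifest"])
        for e in sorted(index["sessions"],
                        key=lambda e: (e["pilot_id"], e["order"]))
    ]
    cohort = Cohort(sessions)
    cohort.validate()
    return cohort
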