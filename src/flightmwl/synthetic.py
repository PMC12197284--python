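"""Synthetic cohorts of paired flight sessions with a known latent workload.

The real study population (professional helicopter pilots in a full-flight
simulator) cannot be redistributed, so this module generates surrogate
recordings in which a latent mental-workload trajectory in [0, 100] is the
single hidden cause of every modality: cardiac and respiratory statistics,
gaze dispersion and area-of-interest choice, helicopter attitude stability,
manipulanda activity, autopilot engagement and radio traffic.  Because the
latent state is known, every downstream stage (feature extraction, label
binarization, ensemble training, temporal cross-validation) is testable:
zero effect sizes must yield chance-level models, planted effects must be
recovered.

Each pilot flies two scenarios in order: a ``baseline`` recon mission and a
``demanding`` rescue mission scripted with high-workload epochs (ship
landing, emergency landing, engine failure).  Oral self-reports are emitted
at key moments as the latent value plus Gaussian noise; NASA-TLX task
intervals (demanding scenario only) carry six sub-scores derived from the
interval-mean latent, with "physical demand" given a low ceiling and
"performance" a high floor so those two sub-scales stay single-class after
binarization, as observed in cockpit studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import lfilter

from .session_io import (
    DEFAULT_AOI_CATEGORIES,
    DEFAULT_HORIZONTAL_MODES,
    DEFAULT_VERTICAL_MODES,
    MANIPULANDA,
    SCENARIOS,
    TLX_SUBSCALES,
    Channel,
    Cohort,
    EventLog,
    SessionRecording,
)

#: feature families a workload effect can be planted in
FEATURE_FAMILIES = (
    "cardiac",
    "respiratory",
    "gaze_dispersion",
    "gaze_outside",
    "helicopter",
    "autopilot",
    "controls_displacement",
    "controls_force",
    "communication",
)

#: default planted set: >=5 families spanning physiology, machine, interface
DEFAULT_PLANTED_FAMILIES = (
    "cardiac",
    "gaze_outside",
    "helicopter",
    "controls_displacement",
    "controls_force",
)

#: features that respond strongly and directly to each family's effect
FAMILY_SIGNAL_FEATURES: dict[str, tuple[str, ...]] = {
    "cardiac": ("heart_rate_mean", "ibi_mean"),
    "respiratory": ("breathing_rate_mean",),
    "gaze_dispersion": ("gaze_ellipse_area", "saccade_amplitude_mean"),
    "gaze_outside": ("aoi_outside",),
    "helicopter": ("altitude_sd", "yaw_sd", "pitch_sd", "roll_sd"),
    "autopilot": ("ap_horizontal_off", "ap_vertical_off"),
    "controls_displacement": tuple(
        f"{m}_displacement_sd" for m in MANIPULANDA
    ),
    "controls_force": tuple(f"{m}_force_sd" for m in MANIPULANDA),
    "communication": ("communication_proportion",),
}

#: features computed from the same modulated channels that may pick up
#: weaker, indirect signal (excluded from both signal and noise sets when
#: reasoning about a planted configuration)
FAMILY_COUPLED_FEATURES: dict[str, tuple[str, ...]] = {
    "cardiac": ("heart_rate_sd", "ibi_sd"),
    "respiratory": ("breathing_rate_sd",),
    "gaze_dispersion": ("saccade_duration_mean", "fixation_duration_mean"),
    "gaze_outside": tuple(
        f"aoi_{c}" for c in DEFAULT_AOI_CATEGORIES if c != "outside"
    ),
    "helicopter": (
        "altitude_mean_crossings", "yaw_mean_crossings",
        "pitch_mean_crossings", "roll_mean_crossings",
        "pitch_mean", "roll_mean",
    ),
    "autopilot": tuple(
        f"ap_horizontal_{m}" for m in DEFAULT_HORIZONTAL_MODES if m != "off"
    ) + tuple(f"ap_vertical_{m}" for m in DEFAULT_VERTICAL_MODES
              if m != "off"),
    "controls_displacement": tuple(
        f"{m}_displacement_{s}" for m in MANIPULANDA
        for s in ("mean", "mean_crossings")
    ),
    "controls_force": tuple(
        f"{m}_force_{s}" for m in MANIPULANDA
        for s in ("mean", "zero_crossings")
    ),
    "communication": (),
}


def signal_features(config: "GeneratorConfig") -> list[str]:
    """Feature names expected to carry strong signal under ``config``."""
    out: list[str] = []
    for fam, effect in config.effect_sizes.items():
        if effect != 0.0:
            out.extend(FAMILY_SIGNAL_FEATURES[fam])
    return out


def noise_features(config: "GeneratorConfig", feature_names) -> list[str]:
    """Feature names untouched by every active family under ``config``:
    pure noise for the downstream model."""
    touched: set[str] = set()
    for fam, effect in config.effect_sizes.items():
        if effect != 0.0:
            touched.update(FAMILY_SIGNAL_FEATURES[fam])
            touched.update(FAMILY_COUPLED_FEATURES[fam])
    return [f for f in feature_names if f not in touched]


#: scripted scenario events: (start fraction, end fraction, amplitude, phase)
SCENARIO_EVENTS: dict[str, list[tuple[float, float, float, str]]] = {
    "baseline": [
        (0.00, 0.05, 15.0, "takeoff"),
        (0.40, 0.50, 12.0, "boat_search"),
        (0.93, 1.00, 18.0, "landing"),
    ],
    "demanding": [
        (0.00, 0.05, 22.0, "takeoff"),
        (0.10, 0.18, 32.0, "medevac_pickup"),
        (0.32, 0.42, 44.0, "ship_landing"),
        (0.55, 0.65, 48.0, "emergency_landing"),
        (0.78, 0.88, 52.0, "engine_failure"),
        (0.95, 1.00, 32.0, "final_landing"),
    ],
}

_SCENARIO_BASE = {"baseline": 28.0, "demanding": 34.0}

#: cruise segments of the demanding scenario used as extra TLX tasks
_CRUISE_TASKS = [(0.22, 0.28), (0.46, 0.52), (0.70, 0.76), (0.90, 0.94)]

_SCREEN = (1920.0, 1080.0)

class InvalidScenarioError(ValueError):
    """Raised for a scenario tag outside the supported set."""


@dataclass
class LatentWorkloadProfile:
    """A piecewise-smooth latent workload trajectory in [0, 100].

    ``key_moments`` are the (time, phase-label) pairs at which the pilot
    emits an oral self-report.
    """

    times: np.ndarray
    values: np.ndarray
    key_moments: list[tuple[float, str]]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("profile times must be strictly increasing")
        if self.values.min() < 0 or self.values.max() > 100:
            raise ValueError("latent workload must stay within [0, 100]")

    def at(self, t: np.ndarray | float) -> np.ndarray | float:
        return np.interp(t, self.times, self.values)


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic cohort.

    ``effect_sizes`` maps each feature family to a standardized shift: the
    channel statistics tied to that family move by ``effect * noise_sd`` per
    25 latent-workload points away from the mid-scale value of 50.
    """

    n_pilots: int = 7
    session_duration: float = 3600.0
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: {f: 1.0 for f in FEATURE_FAMILIES}
    )
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {
            "heart_rate": 5.0,      # bpm
            "ibi": 45.0,            # ms
            "breathing_rate": 2.0,  # bpm
            "altitude": 30.0,       # ft
            "yaw": 4.0,             # deg
            "pitch": 2.0,           # deg
            "roll": 2.5,            # deg
            "displacement": 6.0,    # %
            "force": 1.2,           # daN
            "gaze_jitter": 3.0,     # px within a fixation
        }
    )
    selfreport_noise_sd: float = 8.0
    tlx_noise_sd: float = 8.0
    n_selfreports: int = 15
    seed: int = 0
    event_gain: float = 1.0
    gaze_rate: float = 60.0
    machine_rate: float = 25.0
    cardiac_rate: float = 1.0
    breathing_sample_rate: float = 0.068
    pixels_per_degree: float = 35.0
    aoi_categories: tuple[str, ...] = DEFAULT_AOI_CATEGORIES
    horizontal_modes: tuple[str, ...] = DEFAULT_HORIZONTAL_MODES
    vertical_modes: tuple[str, ...] = DEFAULT_VERTICAL_MODES

    def validate(self) -> None:
        if self.n_pilots < 1:
            raise ValueError("n_pilots must be >= 1")
        for name in ("gaze_rate", "machine_rate", "cardiac_rate",
                     "breathing_sample_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if set(self.effect_sizes) != set(FEATURE_FAMILIES):
            raise ValueError(
                "effect_sizes must cover exactly the feature families "
                f"{sorted(FEATURE_FAMILIES)}, got "
                f"{sorted(self.effect_sizes)}"
            )

    @classmethod
    def null(cls, **kw) -> "GeneratorConfig":
        """All workload effects switched off: channels carry pure noise."""
        return cls(effect_sizes={f: 0.0 for f in FEATURE_FAMILIES}, **kw)

    @classmethod
    def planted(
        cls,
        families: tuple[str, ...] = DEFAULT_PLANTED_FAMILIES,
        effect: float = 1.0,
        **kw,
    ) -> "GeneratorConfig":
        """Effects planted only in ``families``; every other family is noise."""
        sizes = {f: (effect if f in families else 0.0) for f in FEATURE_FAMILIES}
        return cls(effect_sizes=sizes, **kw)

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# random-number plumbing: per-pilot / per-scenario substreams
# ---------------------------------------------------------------------------


def _rng(config: GeneratorConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=tuple(key))
    )


def _slow_drift(
    rng: np.random.Generator,
    duration: float,
    t_out: np.ndarray,
    sigma_s: float,
    sd: float,
) -> np.ndarray:
    """Smooth random drift with correlation scale ``sigma_s`` seconds,
    built on a 1 Hz grid and interpolated to the output timestamps."""
    t_coarse = np.arange(0.0, duration, 1.0)
    drift = gaussian_filter1d(rng.normal(0.0, 1.0, len(t_coarse)),
                              sigma=sigma_s)
    drift *= sd / max(drift.std(), 1e-12)
    return np.interp(t_out, t_coarse, drift)


def _ar1(rng: np.random.Generator, n: int, rate: float,
         tau: float = 5.0) -> np.ndarray:
    """Stationary AR(1) noise with unit marginal variance and time constant
    ``tau`` seconds."""
    phi = float(np.exp(-1.0 / (rate * tau)))
    eps = rng.normal(0.0, np.sqrt(1.0 - phi * phi), n)
    if n == 0:
        return eps
    eps[0] = rng.normal(0.0, 1.0)
    return lfilter([1.0], [1.0, -phi], eps)


# ---------------------------------------------------------------------------
# latent profile
# ---------------------------------------------------------------------------


def generate_latent_profile(
    config: GeneratorConfig,
    scenario: str,
    rng: np.random.Generator | None = None,
    pilot_id: int | None = None,
) -> LatentWorkloadProfile:
    """Scripted events plus a slow random walk, clipped to [0, 100].

    The demanding scenario carries high-amplitude scripted epochs (ship
    landing, emergency landing, engine failure) absent from the baseline
    recon mission, so its mean and upper quartile sit above the baseline's.
    """
    config.validate()
    if scenario not in SCENARIOS:
        raise InvalidScenarioError(
            f"unknown scenario {scenario!r}; expected one of {SCENARIOS}"
        )
    if rng is None:
        rng = _rng(config, 0 if pilot_id is None else pilot_id,
                   SCENARIOS.index(scenario), 0)

    duration = config.session_duration
    t = np.arange(0.0, duration, 1.0)
    level = np.full_like(t, _SCENARIO_BASE[scenario])
    for f0, f1, amp, _ in SCENARIO_EVENTS[scenario]:
        mask = (t >= f0 * duration) & (t < f1 * duration)
        level[mask] += amp * config.event_gain
    # smooth event edges and add a slow wander
    level = gaussian_filter1d(level, sigma=10.0)
    walk = gaussian_filter1d(rng.normal(0.0, 1.0, len(t)), sigma=60.0)
    sd = walk.std()
    if sd > 0:
        walk *= 6.0 / sd
    values = np.clip(level + walk, 0.0, 100.0)

    # key moments: evenly spread with jitter, labelled by the active phase
    n = config.n_selfreports
    lo, hi = min(120.0, 0.1 * duration), duration - min(60.0, 0.05 * duration)
    base_times = np.linspace(lo, hi, n)
    jitter = rng.uniform(-20.0, 20.0, n) if n else np.array([])
    times = np.clip(np.sort(base_times + jitter), 1.0, duration - 1.0)
    key_moments = [(float(tm), _phase_at(tm, scenario, duration))
                   for tm in times]
    return LatentWorkloadProfile(times=t, values=values,
                                 key_moments=key_moments)


def _phase_at(t: float, scenario: str, duration: float) -> str:
    for f0, f1, _, phase in SCENARIO_EVENTS[scenario]:
        if f0 * duration <= t < f1 * duration:
            return phase
    return "cruise"


# ---------------------------------------------------------------------------
# channels
# ---------------------------------------------------------------------------


def _amplitude(z: np.ndarray, effect: float) -> np.ndarray:
    """Noise-amplitude modulation: unity at mid workload, growing with z."""
    return np.clip(1.0 + effect * z, 0.2, 4.0)


def _gen_gaze(
    rng: np.random.Generator,
    config: GeneratorConfig,
    z_of_t,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fixation/saccade gaze process at ``gaze_rate`` plus the AoI stream.

    Fixations are gamma-distributed epochs of small jitter around a centre;
    saccades are instantaneous centre jumps whose pixel amplitude scales
    with the gaze-dispersion effect.  Each fixation is assigned an AoI; the
    probability of looking "outside" the cockpit increases with workload
    under a positive ``gaze_outside`` effect.
    """
    rate = config.gaze_rate
    n = int(round(config.session_duration * rate))
    e_disp = config.effect_sizes["gaze_dispersion"]
    e_out = config.effect_sizes["gaze_outside"]
    jitter_sd = config.noise_sd["gaze_jitter"]
    ppd = config.pixels_per_degree
    cx, cy = _SCREEN[0] / 2.0, _SCREEN[1] / 2.0

    # latent z on a 1 s grid for cheap lookup inside the fixation loop
    z_grid = np.asarray(
        z_of_t(np.arange(0.0, config.session_duration, 1.0)), dtype=float
    )

    x = np.empty(n)
    y = np.empty(n)
    aoi = np.empty(n, dtype=object)
    other = [c for c in config.aoi_categories if c != "outside"]

    # pre-draw per-fixation randomness in bulk (refilled if exhausted)
    n_est = int(n / (0.44 * rate) * 1.4) + 16
    durs = rng.gamma(4.0, 0.09, n_est) + 0.08
    amps = rng.exponential(2.5, n_est) + 0.8
    thetas = rng.uniform(0.0, 2.0 * np.pi, n_est)
    u_out = rng.random(n_est)
    cat_idx = rng.integers(len(other), size=n_est)
    jitter_x = rng.normal(0.0, jitter_sd, n)
    jitter_y = rng.normal(0.0, jitter_sd, n)

    px, py = cx, cy
    i = 0
    k = 0
    while i < n:
        if k >= n_est:  # pragma: no cover - generous pre-draw
            k = 0
            durs = rng.gamma(4.0, 0.09, n_est) + 0.08
            amps = rng.exponential(2.5, n_est) + 0.8
            thetas = rng.uniform(0.0, 2.0 * np.pi, n_est)
            u_out = rng.random(n_est)
            cat_idx = rng.integers(len(other), size=n_est)
        z = z_grid[min(int(i / rate), len(z_grid) - 1)]
        m = max(1, min(n - i, int(round(durs[k] * rate))))
        x[i:i + m] = px + jitter_x[i:i + m]
        y[i:i + m] = py + jitter_y[i:i + m]
        p_out = min(max(0.25 + 0.12 * e_out * z, 0.02), 0.95)
        aoi[i:i + m] = "outside" if u_out[k] < p_out else other[cat_idx[k]]
        i += m
        # saccade: instantaneous jump to the next fixation centre
        amp_px = amps[k] * ppd * min(max(1.0 + e_disp * z, 0.2), 4.0)
        px += amp_px * np.cos(thetas[k])
        py += amp_px * np.sin(thetas[k])
        # soft pull toward screen centre keeps gaze on screen
        px = min(max(0.85 * px + 0.15 * cx, 0.0), _SCREEN[0])
        py = min(max(0.85 * py + 0.15 * cy, 0.0), _SCREEN[1])
        k += 1
    return x, y, aoi


def _gen_autopilot(
    rng: np.random.Generator,
    config: GeneratorConfig,
    profile: LatentWorkloadProfile,
) -> pd.DataFrame:
    """Blockwise autopilot engagement; engagement drops as workload rises."""
    e = config.effect_sizes["autopilot"]
    duration = config.session_duration
    block = 30.0
    edges = np.arange(0.0, duration, block)
    rows = []
    for t0 in edges:
        t1 = min(t0 + block, duration)
        z = (float(np.mean(profile.at(np.linspace(t0, t1, 8)))) - 50.0) / 25.0
        p = float(np.clip(0.75 - 0.30 * e * z, 0.05, 0.95))
        h = ("off" if rng.random() > p
             else config.horizontal_modes[
                 1 + rng.integers(len(config.horizontal_modes) - 1)])
        v = ("off" if rng.random() > p
             else config.vertical_modes[
                 1 + rng.integers(len(config.vertical_modes) - 1)])
        rows.append((t0, t1, h, v))
    # merge consecutive identical mode pairs
    merged = [list(rows[0])]
    for t0, t1, h, v in rows[1:]:
        if (h, v) == (merged[-1][2], merged[-1][3]):
            merged[-1][1] = t1
        else:
            merged.append([t0, t1, h, v])
    return pd.DataFrame(merged, columns=["t0", "t1", "horizontal", "vertical"])


def _gen_comm(
    rng: np.random.Generator,
    config: GeneratorConfig,
    profile: LatentWorkloadProfile,
) -> pd.DataFrame:
    """Radio calls: at most one per minute, likelier under high workload."""
    e = config.effect_sizes["communication"]
    duration = config.session_duration
    rows = []
    for t0 in np.arange(0.0, duration, 60.0):
        t1 = min(t0 + 60.0, duration)
        z = (float(np.mean(profile.at(np.linspace(t0, t1, 8)))) - 50.0) / 25.0
        p = float(np.clip(0.30 + 0.15 * e * z, 0.02, 0.90))
        if rng.random() < p:
            dur = rng.uniform(5.0, 20.0)
            start = t0 + rng.uniform(0.0, max(1e-6, (t1 - t0) - dur))
            rows.append((start, min(start + dur, t1)))
    return pd.DataFrame(rows, columns=["t0", "t1"])


def _tlx_row(m: float, rng: np.random.Generator, noise_sd: float) -> dict:
    """Six NASA-TLX sub-scores from an interval-mean latent value ``m``.

    Physical demand is capped at 45 (flying a certified simulator is not
    physically taxing) and performance floored at 48, so neither sub-scale
    ever crosses the 47.78 binarization threshold in the wrong direction.
    """
    eps = rng.normal(0.0, noise_sd, 6)
    return {
        "mental": float(np.clip(1.00 * m + eps[0], 0.0, 100.0)),
        "physical": float(np.clip(8.0 + 0.25 * m + 0.5 * eps[1], 0.0, 45.0)),
        "temporal": float(np.clip(0.85 * m + 8.0 + eps[2], 0.0, 100.0)),
        "performance": float(np.clip(55.0 + 0.15 * m + eps[3], 48.0, 100.0)),
        "frustration": float(np.clip(0.70 * m + eps[4], 0.0, 100.0)),
        "effort": float(np.clip(0.90 * m + 5.0 + eps[5], 0.0, 100.0)),
    }


def demanding_task_intervals(duration: float) -> list[tuple[float, float, str]]:
    """Scripted NASA-TLX task intervals of the demanding scenario."""
    tasks = [(f0 * duration, f1 * duration, phase)
             for f0, f1, _, phase in SCENARIO_EVENTS["demanding"]]
    tasks += [(f0 * duration, f1 * duration, f"cruise_{k}")
              for k, (f0, f1) in enumerate(_CRUISE_TASKS)]
    return sorted(tasks)


def theoretical_tlx_scores(config: GeneratorConfig) -> pd.DataFrame:
    """Expert-consensus (theoretical) NASA-TLX answers, shared by all pilots.

    Experts score the scripted expectation of each task (scenario base plus
    event amplitude), not any pilot's realized trajectory.
    """
    rng = _rng(config, 10_000)
    duration = config.session_duration
    amp_by_phase = {phase: amp for _, _, amp, phase
                    in SCENARIO_EVENTS["demanding"]}
    rows = []
    for t0, t1, phase in demanding_task_intervals(duration):
        m = _SCENARIO_BASE["demanding"] + amp_by_phase.get(phase, 0.0)
        row = _tlx_row(m, rng, 6.0)
        rows.append({"phase": phase,
                     **{f"theo_{k}": v for k, v in row.items()}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sessions and cohorts
# ---------------------------------------------------------------------------


def generate_session(
    config: GeneratorConfig,
    pilot_id: int,
    scenario: str,
    profile: LatentWorkloadProfile | None = None,
    theo_scores: pd.DataFrame | None = None,
) -> SessionRecording:
    """Generate one pilot x one scenario recording from the latent profile."""
    config.validate()
    if scenario not in SCENARIOS:
        raise InvalidScenarioError(
            f"unknown scenario {scenario!r}; expected one of {SCENARIOS}"
        )
    scen_idx = SCENARIOS.index(scenario)
    if profile is None:
        profile = generate_latent_profile(
            config, scenario, rng=_rng(config, pilot_id, scen_idx, 0)
        )
    rng = _rng(config, pilot_id, scen_idx, 1)
    traits = _rng(config, pilot_id)  # stable across the pilot's two sessions
    hr_base = 72.0 + traits.normal(0.0, 5.0)
    ibi_base = 60_000.0 / hr_base
    br_base = 15.0 + traits.normal(0.0, 1.5)

    duration = config.session_duration
    eff = config.effect_sizes
    sd = config.noise_sd

    def z_at(times: np.ndarray) -> np.ndarray:
        return (profile.at(times) - 50.0) / 25.0

    channels: dict[str, Channel] = {}

    def add(name: str, rate: float, values: np.ndarray,
            columns=("value",), units=("",)) -> None:
        channels[name] = Channel(name=name, rate=rate, values=values,
                                 columns=columns, units=units)

    # cardiac / respiratory: latent shifts the local mean
    for name, base, scale, sign, rate in (
        ("heart_rate", hr_base, sd["heart_rate"], +1.0, config.cardiac_rate),
        ("ibi", ibi_base, sd["ibi"], -1.0, config.cardiac_rate),
    ):
        n = int(round(duration * rate))
        t = np.arange(n) / rate
        vals = (base + sign * eff["cardiac"] * scale * z_at(t)
                + scale * _ar1(rng, n, rate, tau=10.0))
        add(name, rate, vals, units=("bpm" if name == "heart_rate" else "ms",))

    n_br = int(round(duration * config.breathing_sample_rate))
    t_br = np.arange(n_br) / config.breathing_sample_rate
    br = (br_base + eff["respiratory"] * sd["breathing_rate"] * z_at(t_br)
          + sd["breathing_rate"] * _ar1(rng, n_br, config.breathing_sample_rate,
                                        tau=60.0))
    add("breathing_rate", config.breathing_sample_rate, br, units=("bpm",))

    # gaze + AoI
    gx, gy, aoi = _gen_gaze(rng, config,
                            z_of_t=lambda t: (profile.at(t) - 50.0) / 25.0)
    add("gaze_x", config.gaze_rate, gx, units=("px",))
    add("gaze_y", config.gaze_rate, gy, units=("px",))

    # helicopter state: latent modulates the fluctuation amplitude
    mrate = config.machine_rate
    n_m = int(round(duration * mrate))
    t_m = np.arange(n_m) / mrate
    # trajectory drifts are smoothed over scales well beyond the 50 s
    # evaluation window, so windowed variability stays dominated by the
    # latent-modulated fluctuation term
    a_heli = _amplitude(z_at(t_m), eff["helicopter"])
    alt_drift = _slow_drift(rng, duration, t_m, sigma_s=240.0, sd=120.0)
    add("altitude", mrate,
        1200.0 + alt_drift + sd["altitude"] * a_heli * _ar1(rng, n_m, mrate),
        units=("ft",))
    yaw_drift = _slow_drift(rng, duration, t_m, sigma_s=300.0, sd=25.0)
    add("yaw", mrate,
        yaw_drift + sd["yaw"] * a_heli * _ar1(rng, n_m, mrate), units=("deg",))
    add("pitch", mrate,
        2.0 + sd["pitch"] * a_heli * _ar1(rng, n_m, mrate), units=("deg",))
    add("roll", mrate,
        sd["roll"] * a_heli * _ar1(rng, n_m, mrate), units=("deg",))

    # manipulanda: displacement around a trim point, force around zero
    a_disp = _amplitude(z_at(t_m), eff["controls_displacement"])
    a_force = _amplitude(z_at(t_m), eff["controls_force"])
    trim = {"collective": 40.0, "pedals": 50.0,
            "cyclic_pitch": 50.0, "cyclic_roll": 50.0}
    for m in MANIPULANDA:
        disp = trim[m] + sd["displacement"] * a_disp * _ar1(rng, n_m, mrate,
                                                            tau=2.0)
        force = sd["force"] * a_force * _ar1(rng, n_m, mrate, tau=1.0)
        add(m, mrate, np.column_stack([disp, force]),
            columns=("displacement", "force"), units=("%", "daN"))

    # event logs
    report_times = np.array([t for t, _ in profile.key_moments])
    scores = np.clip(
        profile.at(report_times)
        + rng.normal(0.0, config.selfreport_noise_sd, len(report_times)),
        0.0, 100.0,
    )
    selfreports = pd.DataFrame({"time": report_times, "score": scores})

    if scenario == "demanding":
        if theo_scores is None:
            theo_scores = theoretical_tlx_scores(config)
        theo_by_phase = theo_scores.set_index("phase")
        rows = []
        for t0, t1, phase in demanding_task_intervals(duration):
            m = float(np.mean(profile.at(np.linspace(t0, t1, 32))))
            row = {"t0": t0, "t1": t1, "phase": phase}
            row.update(_tlx_row(m, rng, config.tlx_noise_sd))
            row.update(theo_by_phase.loc[phase].to_dict())
            rows.append(row)
        tlx_tasks = pd.DataFrame(rows)
    else:
        tlx_tasks = EventLog.empty().tlx_tasks

    events = EventLog(
        selfreports=selfreports,
        tlx_tasks=tlx_tasks,
        comm_intervals=_gen_comm(rng, config, profile),
        autopilot_modes=_gen_autopilot(rng, config, profile),
        aoi_samples=aoi,
        aoi_rate=config.gaze_rate,
    )
    session = SessionRecording(
        pilot_id=pilot_id,
        scenario=scenario,
        duration=duration,
        channels=channels,
        events=events,
    )
    session.validate()
    return session


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate ``n_pilots`` pilots x 2 ordered sessions (baseline first).

    Pilot ids start at 3: the study numbering after exclusion of the first
    two participants for sensor faults.
    """
    config.validate()
    theo = theoretical_tlx_scores(config)
    sessions = []
    for k in range(config.n_pilots):
        pilot_id = 3 + k
        for scenario in SCENARIOS:
            sessions.append(
                generate_session(config, pilot_id, scenario, theo_scores=theo)
            )
    cohort = Cohort(sessions)
    cohort.validate()
    return cohort
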