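"""Feature registry, window statistics and baseline normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flightmwl import features
from flightmwl.features import (
    CHI2_95_2DF,
    FeatureConfig,
    FeatureRegistry,
    PhysiologyNormalizer,
    WindowError,
    detect_fixations_saccades,
    dwell_proportions,
    interval_dwell,
    mean_crossings,
    normalize_physiological,
    prediction_ellipse_area,
    selfreport_window,
    window_mean_std,
    zero_crossings,
)
from flightmwl.session_io import Channel


def make_channel(values, rate=1.0, columns=("value",)):
    return Channel("test", rate=rate, values=np.asarray(values, dtype=float),
                   columns=columns, units=("",) * len(columns))


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------


def test_registry_counts_match_study_partition():
    counts = FeatureRegistry.default().counts
    assert counts == {"physiology": 23, "machine": 28, "interface": 25,
                      "total": 76}


def test_interface_count_is_cardinality_independent():
    reg = FeatureRegistry.default(
        aoi_categories=("outside", "inside"),
        horizontal_modes=("off", "hdg"),
        vertical_modes=("off",),
    )
    counts = reg.counts
    # 4 manipulanda x 6 statistics + communication, regardless of AoI and
    # autopilot cardinalities
    assert counts["interface"] == 4 * 6 + 1 == 25
    assert counts["machine"] == 10 + 2 + 1
    assert counts["physiology"] == 10 + 2


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


def test_selfreport_window_geometry():
    assert selfreport_window(100.0, 3600.0) == (60.0, 110.0, False)
    assert selfreport_window(30.0, 3600.0) == (0.0, 40.0, True)
    t0, t1, truncated = selfreport_window(500.0, 3600.0)
    assert t1 - t0 == 50.0 and not truncated
    with pytest.raises(WindowError):
        selfreport_window(4000.0, 3600.0)


# ---------------------------------------------------------------------------
# scalar statistics
# ---------------------------------------------------------------------------


def test_window_mean_std_examples():
    const = make_channel([70.0] * 10)
    assert window_mean_std(const, (0.0, 10.0)) == (70.0, 0.0)
    ch = make_channel([1.0, 2.0, 3.0, 4.0])
    m, s = window_mean_std(ch, (0.0, 4.0))
    assert m == 2.5
    assert s == pytest.approx(1.2909944, abs=1e-6)
    m, s = window_mean_std(ch, (0.0, 0.0))
    assert np.isnan(m) and np.isnan(s)


def test_low_coverage_yields_missing():
    ch = make_channel([1.0, 2.0], rate=1.0)
    # interval expects 10 samples, channel provides 2 -> below 80% coverage
    m, s = window_mean_std(ch, (0.0, 10.0))
    assert np.isnan(m)


def test_crossing_examples():
    assert mean_crossings(make_channel([5, 5, 5]), (0, 3)) == 0
    assert mean_crossings(make_channel([0, 1, 0, 1]), (0, 4)) == 3
    assert mean_crossings(make_channel([1, 2, 3, 4]), (0, 4)) == 1
    assert zero_crossings(make_channel([0, 0, 0]), (0, 3)) == 0
    assert zero_crossings(make_channel([-1, 1, -1]), (0, 3)) == 2
    assert zero_crossings(make_channel([1, -2, 3, -4]), (0, 4)) == 3
    assert np.isnan(mean_crossings(make_channel([1.0]), (0, 1)))


def crossings_oracle(values, center):
    """Independent enumeration: walk the sequence, track the last nonzero
    sign of (x - center), count strict flips."""
    last = 0
    count = 0
    for v in values:
        s = (v > center) - (v < center)
        if s != 0:
            if last != 0 and s != last:
                count += 1
            last = s
    return count


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.integers(-3, 3), min_size=2, max_size=12))
def test_crossings_match_enumeration_oracle(values):
    ch = make_channel(values)
    n = len(values)
    assert zero_crossings(ch, (0, n)) == crossings_oracle(values, 0.0)
    m = float(np.mean(values))
    assert mean_crossings(ch, (0, n)) == crossings_oracle(values, m)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.integers(-3, 3), min_size=2, max_size=12),
       st.integers(-5, 5))
def test_mean_crossings_shift_invariant(values, shift):
    n = len(values)
    a = mean_crossings(make_channel(values), (0, n))
    b = mean_crossings(make_channel(np.asarray(values) + shift), (0, n))
    assert a == b


def test_zero_crossings_not_shift_invariant():
    ch = make_channel([-1, 1, -1, 1])
    shifted = make_channel([9, 11, 9, 11])
    assert zero_crossings(ch, (0, 4)) == 3
    assert zero_crossings(shifted, (0, 4)) == 0


# ---------------------------------------------------------------------------
# gaze statistics
# ---------------------------------------------------------------------------


def test_ellipse_area_closed_form():
    # four points whose sample covariance is exactly the identity
    a = np.sqrt(1.5)
    pts = np.array([[a, 0], [-a, 0], [0, a], [0, -a]])
    area, degenerate = prediction_ellipse_area(pts)
    assert not degenerate
    assert area == pytest.approx(np.pi * CHI2_95_2DF, rel=1e-9)
    assert area == pytest.approx(18.8227, abs=1e-3)


def test_ellipse_area_homogeneity_and_rotation():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(50, 2)) @ np.array([[2.0, 0.3], [0.0, 1.0]])
    area, _ = prediction_ellipse_area(pts)
    scaled, _ = prediction_ellipse_area(2.0 * pts)
    assert scaled == pytest.approx(4.0 * area, rel=1e-9)
    th = 0.7
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    rotated, _ = prediction_ellipse_area(pts @ rot.T)
    assert rotated == pytest.approx(area, rel=1e-9)


def test_ellipse_degenerate_collinear():
    pts = np.column_stack([np.arange(10.0), 2.0 * np.arange(10.0)])
    area, degenerate = prediction_ellipse_area(pts)
    assert area == 0.0 and degenerate


def test_fixation_saccade_detection_on_scripted_trace():
    """300 ms stationary epochs separated by instantaneous 5 deg jumps."""
    config = FeatureConfig(pixels_per_degree=35.0)
    rate = 60.0
    n_fix, fix_len = 20, 18  # 18 samples = 300 ms
    x, y = [], []
    pos = 0.0
    for _ in range(n_fix):
        x.extend([pos] * fix_len)
        y.extend([0.0] * fix_len)
        pos += 5.0 * config.pixels_per_degree
    out = detect_fixations_saccades(np.array(x), np.array(y), rate, config)
    assert out.fixation_duration_mean == pytest.approx(0.3, abs=0.02)
    assert out.saccade_amplitude_mean == pytest.approx(5.0, abs=1e-9)
    assert out.n_saccades == n_fix - 1
    assert out.saccade_duration_mean == pytest.approx(1 / rate)


def test_stationary_gaze_has_no_saccades():
    x = np.zeros(120)
    out = detect_fixations_saccades(x, x, 60.0, FeatureConfig())
    assert out.n_saccades == 0
    assert out.fixation_duration_mean == pytest.approx(2.0)
    assert np.isnan(out.saccade_duration_mean)


def test_velocity_threshold_above_everything_detects_nothing():
    rng = np.random.default_rng(1)
    x = rng.normal(0, 50, 200)
    config = FeatureConfig(velocity_threshold_deg_s=1e9)
    out = detect_fixations_saccades(x, x, 60.0, config)
    assert out.n_saccades == 0


def test_missing_calibration_rejected():
    with pytest.raises(ValueError, match="pixels_per_degree"):
        detect_fixations_saccades(np.zeros(10), np.zeros(10), 60.0,
                                  FeatureConfig(pixels_per_degree=0.0))


# ---------------------------------------------------------------------------
# dwell
# ---------------------------------------------------------------------------


def test_dwell_proportions_sum_to_one():
    samples = np.array(["a"] * 30 + ["b"] * 60 + ["c"] * 30, dtype=object)
    out = dwell_proportions(samples, 60.0, (0.0, 2.0), ("a", "b", "c"))
    assert sum(out.values()) == pytest.approx(1.0, abs=1e-12)
    assert out["a"] == pytest.approx(0.25)


def test_dwell_single_category_full_window():
    samples = np.array(["outside"] * 60, dtype=object)
    out = dwell_proportions(samples, 60.0, (0.0, 1.0),
                            ("outside", "pfd"))
    assert out == {"outside": 1.0, "pfd": 0.0}


def test_dwell_unknown_category_is_named():
    samples = np.array(["mystery"], dtype=object)
    with pytest.raises(KeyError, match="mystery"):
        dwell_proportions(samples, 1.0, (0.0, 1.0), ("a",))


def test_interval_dwell_half_window():
    comm = pd.DataFrame({"t0": [10.0], "t1": [35.0]})
    assert interval_dwell(comm, (10.0, 60.0)) == pytest.approx(0.5)


def test_interval_dwell_by_mode_sums_to_one():
    modes = pd.DataFrame(
        {"t0": [0.0, 30.0], "t1": [30.0, 60.0],
         "horizontal": ["off", "hdg"], "vertical": ["alt", "alt"]}
    )
    out = interval_dwell(modes, (0.0, 60.0), by=("horizontal", "vertical"),
                         categories={"horizontal": ("off", "hdg"),
                                     "vertical": ("off", "alt")})
    assert out["horizontal:off"] == pytest.approx(0.5)
    assert sum(v for k, v in out.items()
               if k.startswith("horizontal")) == pytest.approx(1.0)
    assert sum(v for k, v in out.items()
               if k.startswith("vertical")) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# matrix extraction and normalization
# ---------------------------------------------------------------------------


def test_matrix_shape_and_window_widths(small_matrix, small_config):
    n_rows = 2 * small_config.n_pilots * small_config.n_selfreports
    assert small_matrix.values.shape == (n_rows, 76)
    unclipped = ~small_matrix.meta["truncated"]
    widths = (small_matrix.meta["t1"] - small_matrix.meta["t0"])[unclipped]
    assert (widths == 50.0).all()


def test_tlx_windows_span_task_duration(small_cohort):
    m = features.extract_feature_matrix(small_cohort, kind="tlx")
    session = small_cohort.session(3, "demanding")
    tasks = session.events.tlx_tasks
    rows = m.meta[m.meta["pilot_id"] == 3]
    assert len(rows) == len(tasks)
    np.testing.assert_allclose(
        (rows["t1"] - rows["t0"]).to_numpy(),
        (tasks["t1"] - tasks["t0"]).to_numpy(),
    )


def test_extraction_is_deterministic(small_cohort):
    a = features.extract_feature_matrix(small_cohort)
    b = features.extract_feature_matrix(small_cohort)
    pd.testing.assert_frame_equal(a.values, b.values)


def test_normalization_zeroes_baseline_physiology(small_matrix):
    phys = small_matrix.registry.names_in("physiology")
    base = small_matrix.meta["scenario"] == "baseline"
    means = small_matrix.values.loc[base, phys].groupby(
        small_matrix.meta.loc[base, "pilot_id"]).mean()
    assert np.nanmax(np.abs(means.to_numpy())) < 1e-9


def test_normalization_leaves_other_categories_untouched(small_cohort):
    raw = features.extract_feature_matrix(small_cohort, normalize=False)
    norm = normalize_physiological(raw)
    other = (raw.registry.names_in("machine")
             + raw.registry.names_in("interface"))
    pd.testing.assert_frame_equal(raw.values[other], norm.values[other])
    phys = raw.registry.names_in("physiology")
    assert not np.allclose(raw.values[phys].to_numpy(),
                           norm.values[phys].to_numpy())


def test_constant_physiological_feature_normalizes_to_zero(small_cohort):
    raw = features.extract_feature_matrix(small_cohort, normalize=False)
    raw.values["heart_rate_mean"] = 64.0
    norm = normalize_physiological(raw)
    assert (norm.values["heart_rate_mean"] == 0.0).all()


def test_missing_baseline_windows_rejected(small_cohort):
    raw = features.extract_feature_matrix(small_cohort, normalize=False)
    demanding_only = raw.meta["scenario"] == "demanding"
    clipped = features.FeatureMatrix(
        values=raw.values[demanding_only].reset_index(drop=True),
        meta=raw.meta[demanding_only].reset_index(drop=True),
        registry=raw.registry,
    )
    with pytest.raises(ValueError, match="baseline"):
        PhysiologyNormalizer.fit_matrix(clipped)


def test_matrix_csv_roundtrip(small_matrix, tmp_path):
    prefix = str(tmp_path / "fm")
    small_matrix.write(prefix)
    loaded = features.FeatureMatrix.read(prefix)
    pd.testing.assert_frame_equal(loaded.values, small_matrix.values,
                                  check_exact=False, rtol=1e-12)
    assert loaded.registry.counts == small_matrix.registry.counts
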