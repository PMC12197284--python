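"""The weak-classifier ensemble: AUC, top-left calibration, gating, votes."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flightmwl import hbagging
from flightmwl.hbagging import (
    DECREASES,
    INCREASES,
    HBaggingConfig,
    Heuristic,
    Rejection,
    SingleClassError,
    WeakClassifier,
    fit_weak_classifier,
    predict_score,
    roc_auc,
    topleft_threshold,
)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def auc_oracle(values, y):
    """Concordant-pair counting over all (high, low) pairs, ties half."""
    highs = [v for v, label in zip(values, y) if label]
    lows = [v for v, label in zip(values, y) if not label]
    total = 0.0
    for h in highs:
        for low in lows:
            total += 1.0 if h > low else (0.5 if h == low else 0.0)
    return total / (len(highs) * len(lows))


def topleft_oracle(values, y, orientation):
    """Exhaustive candidate scan with explicit tie-breaking."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(y, dtype=bool)
    distinct = np.unique(x)
    candidates = [-np.inf, *((distinct[:-1] + distinct[1:]) / 2.0), np.inf]
    best = None
    for t in candidates:
        pred = orientation * x > orientation * t
        tpr = (pred & y).sum() / y.sum()
        fpr = (pred & ~y).sum() / (~y).sum()
        d = np.hypot(1 - tpr, fpr)
        key = (d, -tpr, t)
        if best is None or key < best:
            best = key
    return best


def label_cases(n):
    """Every two-class label pattern of length n."""
    for bits in itertools.product([False, True], repeat=n):
        if any(bits) and not all(bits):
            yield np.array(bits)


# ---------------------------------------------------------------------------
# roc_auc
# ---------------------------------------------------------------------------


def test_roc_auc_examples():
    assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
    assert roc_auc([1, 2, 3, 4], [1, 1, 0, 0]) == 0.0
    assert roc_auc([1, 2, 2, 3], [0, 1, 0, 1]) == 0.875
    with pytest.raises(SingleClassError):
        roc_auc([1, 2], [1, 1])


@settings(max_examples=150, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 5), min_size=2, max_size=8),
       st.integers(0, 2**8 - 1))
def test_roc_auc_matches_pair_counting_and_symmetry(values, label_bits):
    y = np.array([(label_bits >> i) & 1 for i in range(len(values))],
                 dtype=bool)
    if y.all() or not y.any():
        return
    x = np.asarray(values, dtype=float)
    assert roc_auc(x, y) == pytest.approx(auc_oracle(x, y), abs=1e-12)
    assert roc_auc(x, y) + roc_auc(-x, y) == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# topleft_threshold
# ---------------------------------------------------------------------------


def test_topleft_separable_case():
    out = topleft_threshold([1, 2, 3, 4], [0, 0, 1, 1], orientation=1)
    assert out.threshold == 2.5
    assert out.distance == 0.0


def test_topleft_anti_separable_is_boundary():
    out = topleft_threshold([1, 2, 3, 4], [1, 1, 0, 0], orientation=1)
    assert out.distance == pytest.approx(1.0)
    assert out.boundary


def test_topleft_exhaustive_equivalence_small_instances():
    """Exact agreement with the brute-force scan on every label pattern of
    every small instance."""
    rng = np.random.default_rng(7)
    for n in range(2, 8):
        for _ in range(6):
            x = rng.integers(0, 4, size=n).astype(float)
            for y in label_cases(n):
                for orientation in (1, -1):
                    out = topleft_threshold(x, y, orientation)
                    d, neg_tpr, t = topleft_oracle(x, y, orientation)
                    assert out.distance == pytest.approx(d, abs=1e-12)
                    assert out.tpr == pytest.approx(-neg_tpr, abs=1e-12)
                    assert out.threshold == t


def test_topleft_random_larger_instances_match_oracle():
    rng = np.random.default_rng(8)
    for _ in range(100):
        n = rng.integers(4, 40)
        x = rng.normal(size=n).round(1)
        y = rng.random(n) < 0.4
        if y.all() or not y.any():
            continue
        out = topleft_threshold(x, y, 1)
        d, _, t = topleft_oracle(x, y, 1)
        assert out.distance == pytest.approx(d, abs=1e-12)
        assert out.threshold == t


# ---------------------------------------------------------------------------
# weak classifiers
# ---------------------------------------------------------------------------


def test_separable_feature_retained_with_auc_one():
    w = fit_weak_classifier("f", [1, 2, 3, 4], [0, 0, 1, 1])
    assert isinstance(w, WeakClassifier)
    assert w.train_auc == 1.0
    assert w.orientation == 1
    assert w.threshold == 2.5


def test_constant_feature_rejected_as_degenerate():
    out = fit_weak_classifier("f", [5, 5, 5, 5], [0, 0, 1, 1])
    assert isinstance(out, Rejection)
    assert out.reason == "degenerate"


def test_null_features_mostly_rejected():
    """Permuted labels, n=200: the AUC gate rejects in >=90/100 trials."""
    rng = np.random.default_rng(0)
    y = np.array([False, True] * 100)
    rejections = 0
    for _ in range(100):
        x = rng.normal(size=200)
        out = fit_weak_classifier("f", x, rng.permutation(y))
        rejections += isinstance(out, Rejection)
    assert rejections >= 90


def test_wrong_direction_heuristic_causes_rejection():
    config = HBaggingConfig(heuristics=(Heuristic("f", INCREASES),))
    out = fit_weak_classifier("f", [4, 3, 2, 1], [0, 0, 1, 1], config)
    assert isinstance(out, Rejection)
    assert out.train_auc == 0.0


def test_negation_symmetry():
    """Negating a feature and flipping its heuristic mirrors the rule."""
    x = np.array([0.1, 0.9, 0.4, 0.8, 0.2, 0.7])
    y = np.array([0, 1, 0, 1, 0, 1], dtype=bool)
    up = fit_weak_classifier("f", x, y,
                             HBaggingConfig(heuristics=(Heuristic("f",
                                                                  INCREASES),)))
    down = fit_weak_classifier("f", -x, y,
                               HBaggingConfig(heuristics=(Heuristic("f",
                                                                    DECREASES),)))
    assert isinstance(up, WeakClassifier) and isinstance(down, WeakClassifier)
    assert up.train_auc == down.train_auc
    assert down.threshold == pytest.approx(-up.threshold)
    np.testing.assert_array_equal(up.votes(x), down.votes(-x))


def test_ensemble_fit_selects_planted_feature():
    rng = np.random.default_rng(1)
    n = 200
    y = rng.random(n) < 0.5
    if y.all() or not y.any():
        y[0] = ~y[0]
    X = pd.DataFrame({f"noise_{i}": rng.normal(size=n) for i in range(20)})
    X["planted"] = y + rng.normal(0, 0.4, n)
    model = hbagging.fit(X, y)
    assert "planted" in model.feature_names
    noise_retained = sum(1 for f in model.feature_names if f != "planted")
    assert noise_retained <= 2  # >=18/20 rejected


def test_all_noise_matrix_usually_empty():
    rng = np.random.default_rng(2)
    empties = 0
    trials = 30
    for _ in range(trials):
        n = 200
        y = np.array([False, True] * 100)
        X = pd.DataFrame({f"n{i}": rng.normal(size=n) for i in range(20)})
        empties += hbagging.fit(X, y).empty
    assert empties > trials / 2


def test_min_auc_half_retains_every_nondegenerate_feature():
    rng = np.random.default_rng(3)
    X = pd.DataFrame(rng.normal(size=(50, 10)),
                     columns=[f"f{i}" for i in range(10)])
    y = rng.random(50) < 0.5
    model = hbagging.fit(X, y, HBaggingConfig(min_auc=0.5))
    assert len(model.retained) == 10


def test_gate_monotonicity():
    rng = np.random.default_rng(4)
    n = 60
    y = rng.random(n) < 0.5
    X = pd.DataFrame({f"f{i}": rng.normal(size=n) + 0.3 * y
                      for i in range(12)})
    retained = [
        set(hbagging.fit(X, y, HBaggingConfig(min_auc=m)).feature_names)
        for m in (0.5, 0.55, 0.6, 0.65, 0.7)
    ]
    for lower, higher in zip(retained, retained[1:]):
        assert higher <= lower


def test_single_class_labels_rejected():
    X = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
    with pytest.raises(SingleClassError):
        hbagging.fit(X, [True, True, True])


# ---------------------------------------------------------------------------
# prediction and description
# ---------------------------------------------------------------------------


def _model(classifiers):
    return hbagging.HBaggingModel(retained=classifiers, rejected=[],
                                  config=HBaggingConfig())


def test_single_classifier_scores_are_binary():
    model = _model([WeakClassifier("f", 1, 0.5, 0.9)])
    X = pd.DataFrame({"f": [0.0, 0.4, 0.6, 1.0]})
    np.testing.assert_array_equal(predict_score(model, X), [0, 0, 1, 1])


def test_empty_ensemble_abstains_at_half():
    model = _model([])
    X = pd.DataFrame({"f": [0.0, 1.0]})
    np.testing.assert_array_equal(predict_score(model, X), [0.5, 0.5])


def test_vote_arithmetic_two_of_three():
    model = _model([
        WeakClassifier("a", 1, 0.5, 0.9),
        WeakClassifier("b", 1, 0.5, 0.9),
        WeakClassifier("c", 1, 0.5, 0.9),
    ])
    X = pd.DataFrame({"a": [1.0], "b": [1.0], "c": [0.0]})
    assert predict_score(model, X)[0] == pytest.approx(2 / 3)


def test_missing_retained_feature_is_error():
    model = _model([WeakClassifier("f", 1, 0.5, 0.9)])
    with pytest.raises(KeyError, match="f"):
        predict_score(model, pd.DataFrame({"g": [1.0]}))
    with pytest.raises(ValueError, match="missing"):
        predict_score(model, pd.DataFrame({"f": [np.nan]}))


def test_describe_and_json_roundtrip(tmp_path):
    model = _model([
        WeakClassifier("a", 1, 0.5, 0.91),
        WeakClassifier("b", -1, -2.0, 0.77),
    ])
    table = hbagging.describe(model)
    assert len(table) == 2
    assert set(table["feature"]) == {"a", "b"}
    path = tmp_path / "model.json"
    model.save(str(path))
    loaded = hbagging.HBaggingModel.load(str(path))
    pd.testing.assert_frame_equal(hbagging.describe(loaded), table)
    assert not loaded.empty


def test_empty_model_describe(tmp_path):
    model = _model([])
    assert len(hbagging.describe(model)) == 0
    assert model.empty
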