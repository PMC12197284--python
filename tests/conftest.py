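"""Shared fixtures: synthetic cohorts at two scales.

The "small" cohort (2 pilots, 10-minute sessions) keeps unit tests fast;
the full-scale cohorts reproduce the study conditions (7 pilots, hour-long
sessions, 15 self-reports per session) for the calibration and recovery
checks.  All seeds are fixed so the suite is deterministic.
"""

from __future__ import annotations

import pytest

from flightmwl import features, ground_truth, synthetic


SMALL_KW = dict(n_pilots=2, session_duration=600.0, n_selfreports=6)


@pytest.fixture(scope="session")
def small_config():
    return synthetic.GeneratorConfig.planted(seed=11, **SMALL_KW)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return synthetic.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    return features.extract_feature_matrix(small_cohort)


@pytest.fixture(scope="session")
def small_labels(small_matrix):
    return ground_truth.build_labels(small_matrix.meta, "selfreport")


@pytest.fixture(scope="session")
def planted_config():
    return synthetic.GeneratorConfig.planted(seed=0)


@pytest.fixture(scope="session")
def planted_cohort(planted_config):
    return synthetic.generate_cohort(planted_config)


@pytest.fixture(scope="session")
def planted_matrix(planted_cohort):
    return features.extract_feature_matrix(planted_cohort)


@pytest.fixture(scope="session")
def planted_labels(planted_matrix):
    return ground_truth.build_labels(planted_matrix.meta, "selfreport")


@pytest.fixture(scope="session")
def null_config():
    return synthetic.GeneratorConfig.null(seed=0)


@pytest.fixture(scope="session")
def null_cohort(null_config):
    return synthetic.generate_cohort(null_config)


@pytest.fixture(scope="session")
def null_matrix(null_cohort):
    return features.extract_feature_matrix(null_cohort)
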