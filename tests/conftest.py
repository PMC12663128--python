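"""Shared fixtures: synthetic datasets and fitted models (session-scoped so
expensive fits run once per test session)."""

import logging

import numpy as np
import pytest

import normbench as nb

logging.getLogger("normbench").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def vo2_curves():
    return nb.preset_vo2max_like()


@pytest.fixture(scope="session")
def bmi_curves():
    return nb.preset_bmi_like()


@pytest.fixture(scope="session")
def vo2_sample(vo2_curves):
    """7 cohorts x 150 per cohort, undistorted; with true percentiles."""
    return nb.generate_sample(vo2_curves, 150, seed=20101)


@pytest.fixture(scope="session")
def vo2_data(vo2_sample):
    return vo2_sample[0]


@pytest.fixture(scope="session")
def lms_model(vo2_data):
    return nb.fit_lms(vo2_data)


@pytest.fixture(scope="session")
def cnorm_model(vo2_data):
    return nb.fit_cnorm(vo2_data)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
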