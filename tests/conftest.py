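"""Shared fixtures: small synthetic records and the session-scoped cohort runs.

The heavy study-analog computations (training cohort CV, held-out validation,
negative control) are session-scoped so the acceptance tests and the unit
tests that inspect the same artifacts share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

import sdbscreen as sdb

#: One seed for the whole suite's stochastic fixtures.
SUITE_SEED = 20260301


@pytest.fixture(scope="session")
def sdb_record():
    """One severe-SDB synthetic subject (1 h, AHI target 45), RR mode."""
    params = sdb.SubjectParams(duration=3600.0, target_ahi=45.0, seed=SUITE_SEED)
    return sdb.simulate_subject(params, subject_id="sdb-fixture")


@pytest.fixture(scope="session")
def normal_record():
    """One normal synthetic subject (1 h, AHI target 2), RR mode."""
    params = sdb.SubjectParams(duration=3600.0, target_ahi=2.0, seed=SUITE_SEED + 1)
    return sdb.simulate_subject(params, subject_id="normal-fixture")


@pytest.fixture(scope="session")
def ecg_record():
    """A 5-minute subject with the 256 Hz ECG waveform rendered (quiet noise),
    for exercising the R-peak detector."""
    params = sdb.SubjectParams(duration=300.0, target_ahi=0.0, seed=SUITE_SEED + 2)
    return sdb.simulate_subject(
        params, subject_id="ecg-fixture", render_ecg_waveform=True, ecg_noise_sd=0.1
    )


@pytest.fixture(scope="session")
def training_analog():
    """The scaled training run: 14 SDB + 15 normal subjects, 1 h each,
    stage-1 10-fold CV and stage-2 fit."""
    return sdb.run_training_analog(seed=SUITE_SEED)


@pytest.fixture(scope="session")
def validation_analog(training_analog):
    """Held-out 30 + 30 subject cohort classified with the trained models."""
    return sdb.run_validation_analog(
        training_analog.window_model,
        training_analog.subject_model,
        seed=SUITE_SEED + 1,
    )


@pytest.fixture(scope="session")
def negative_control():
    """Null-physiology cohort control (subject-grouped CV)."""
    return sdb.run_negative_control(seed=SUITE_SEED)
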