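"""Shared fixtures: subject, body parameters, and cached synthetic trials.

The noiseless trials and their fitted results are session-scoped because
several test modules probe different stages of the same pipeline run.
"""

import numpy as np
import pytest

from stancecom import (MotionPreset, SingleLegStanceModel, SubjectProfile,
                       compute_body_params, generate_trial)

# evaluation window: samples covering 10-40 s at 100 Hz
WINDOW = slice(1000, 4000)


@pytest.fixture(scope="session")
def profile():
    return SubjectProfile(height=1.70, mass=62.0, stance_side="right")


@pytest.fixture(scope="session")
def params(profile):
    return compute_body_params(profile)


def _make(condition, profile, **kw):
    return generate_trial(MotionPreset(condition, seed=1, **kw), profile)


@pytest.fixture(scope="session")
def trial_quiet(profile):
    return _make("A_quiet", profile)


@pytest.fixture(scope="session")
def trial_updown(profile):
    return _make("B_updown", profile)


@pytest.fixture(scope="session")
def trial_yaw(profile):
    return _make("C_yaw", profile)


@pytest.fixture(scope="session")
def result_quiet(trial_quiet):
    return SingleLegStanceModel.from_trial(trial_quiet).fit()


@pytest.fixture(scope="session")
def result_updown(trial_updown):
    return SingleLegStanceModel.from_trial(trial_updown).fit()


@pytest.fixture(scope="session")
def result_yaw(trial_yaw):
    return SingleLegStanceModel.from_trial(trial_yaw).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
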