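import dataclasses

import numpy as np
import pytest

from pedalbci import ProtocolSpec, SubjectProfile, generate_session


@pytest.fixture(scope="session")
def default_spec():
    return ProtocolSpec()


@pytest.fixture(scope="session")
def tiny_spec():
    """2 tasks of each type, 3 trials: structural tests in seconds."""
    return dataclasses.replace(ProtocolSpec(), tasks_per_type_per_trial=2,
                               trials_per_session=3, training_trials=2)


@pytest.fixture(scope="session")
def small_spec():
    """5 tasks per type, 2 trials (1 training): full-pipeline unit tests."""
    return dataclasses.replace(ProtocolSpec(), tasks_per_type_per_trial=5,
                               trials_per_session=2, training_trials=1)


@pytest.fixture(scope="session")
def clean_profile():
    """Noise-free mu-only subject: analytic ground truth holds exactly."""
    return SubjectProfile(noise_amplitude=0.0, line_noise_amplitude=0.0,
                          beta_amplitude=0.0)


@pytest.fixture(scope="session")
def clean_small_session(clean_profile, small_spec):
    return generate_session(clean_profile, small_spec, day=1, seed=2)


@pytest.fixture(scope="session")
def clean_full_session(clean_profile, default_spec):
    """Full 10-trial noise-free session: band-power ratios concentrate to
    sampling std ~0.01, tight enough for +/-0.02 ground-truth checks."""
    return generate_session(clean_profile, default_spec, day=1, seed=2)


@pytest.fixture(scope="session")
def zeros_session(default_spec):
    """A default-protocol recording of zeros: cheap structural slicing."""
    from pedalbci.montage import CHANNELS_30
    from pedalbci.protocol import build_session_schedule
    from pedalbci.synthetic import SessionRecording

    n = int(round(default_spec.session_duration_s * default_spec.sampling_rate_hz))
    return SessionRecording(
        np.zeros((len(CHANNELS_30), n)), default_spec.sampling_rate_hz,
        list(CHANNELS_30), build_session_schedule(default_spec, seed=11))
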