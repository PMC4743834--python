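import numpy as np
import pytest

from pupilhci import DisplayConfig, ParticipantProfile, PupilTrace
from pupilhci.pupilsim import oracle_selector


@pytest.fixture
def display():
    return DisplayConfig()


@pytest.fixture
def quiet_profile():
    """Strong-signal, noise-free participant (for deterministic checks)."""
    return ParticipantProfile(
        modulation_gain=100.0, transient_amplitude=0.0, drift_sd=0.0,
        sample_noise_sd=0.0, blink_rate=0.0, seed=0,
    )


@pytest.fixture
def oracle():
    return oracle_selector()


def make_trace(samples, valid=None, rate=100.0):
    samples = np.asarray(samples, dtype=float)
    if valid is None:
        valid = np.ones(len(samples), dtype=bool)
    return PupilTrace(sample_rate=rate, samples=samples,
                      valid=np.asarray(valid, dtype=bool))
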