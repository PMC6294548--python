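import numpy as np
import pytest

from meploop.participant import Participant, ParticipantParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def participant():
    """Default synthetic subject with a fixed seed."""
    return Participant(ParticipantParams(seed=7))


@pytest.fixture
def noiseless_participant():
    """Deterministic subject: no amplitude noise, no excitability jitter."""
    return Participant(ParticipantParams(seed=7, mep_noise_cv=0.0,
                                         exc_jitter_sd=0.0, slope_k=0.3363))
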