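import numpy as np
import pytest
from dataclasses import replace

import pupilfmri as pf


@pytest.fixture(scope="session")
def schedule():
    return pf.build_schedule(seed=1)


@pytest.fixture(scope="session")
def noiseless_pupil(schedule):
    """Noiseless, blink-free pupil recording with default amplitudes."""
    cfg = pf.PupilGenConfig(seed=0, noise_sd=0.0, blink_rate=0.0,
                            gaze_excursion_rate=0.0)
    return pf.simulate_pupil(schedule, cfg)


@pytest.fixture(scope="session")
def default_pupil(schedule):
    """Default-condition pupil recording (noise, blinks, gaze drift)."""
    return pf.simulate_pupil(schedule, pf.PupilGenConfig(seed=7))


@pytest.fixture(scope="session")
def clean_recording(noiseless_pupil):
    rec, truth = noiseless_pupil
    return replace(rec, pupil=truth["trace_nogaps"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
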