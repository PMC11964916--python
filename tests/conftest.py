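import numpy as np
import pytest

from spikehr import signals as sg


@pytest.fixture(scope="session")
def ppg60():
    """Ten seconds of clean synthetic PPG at 60 bpm, 125 Hz."""
    return sg.generate_ppg(sg.HRTrajectory.constant(60), fs=125, duration=10)


@pytest.fixture(scope="session")
def table_pulse():
    return sg.PPGPulseSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
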