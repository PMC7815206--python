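import numpy as np
import pytest

from cspgram import TimeCourse


@pytest.fixture
def noiseless_sine_72h() -> TimeCourse:
    """Pure amplitude-2 sinusoid, period 24 h, 72 h at 0.1-h sampling."""
    t = np.arange(720) * 0.1
    return TimeCourse(2.0 * np.sin(2.0 * np.pi * t / 24.0), 0.1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
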