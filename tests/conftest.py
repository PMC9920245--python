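import numpy as np
import pytest

from treeaemc.signal_sim import SimConfig, Waveform


@pytest.fixture
def tone():
    """2 s pure 200 Hz cosine of amplitude 2 at 5 kHz."""
    rate = 5000.0
    t = np.arange(int(2 * rate)) / rate
    return Waveform(2.0 * np.cos(2 * np.pi * 200.0 * t), rate)


@pytest.fixture
def two_tone():
    """Equal-amplitude 200 Hz + 500 Hz tones, 2 s at 5 kHz, noise-free."""
    rate = 5000.0
    t = np.arange(int(2 * rate)) / rate
    x = np.cos(2 * np.pi * 200.0 * t) + np.cos(2 * np.pi * 500.0 * t)
    return Waveform(x, rate)


@pytest.fixture
def desk_sim_cfg():
    """Short, low-rate record configuration for fast end-to-end tests."""
    return SimConfig(rate=2000.0, duration=0.4, excitation_period=0.15)


def interior(n, frac=0.05):
    """Slice excluding an edge band of `frac` of the length at each end."""
    k = max(int(frac * n), 1)
    return slice(k, n - k)
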