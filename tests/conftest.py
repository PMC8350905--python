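import numpy as np
import pytest

from organoid_ephys.io import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def white_recording(rng):
    """240 s of unit-variance white noise at 1 kHz."""
    fs = 1000.0
    return Recording(rng.standard_normal(int(240 * fs)), fs)


def sine_recording(freq, fs, duration, amplitude=1.0, modality="lfp"):
    t = np.arange(int(duration * fs)) / fs
    return Recording(amplitude * np.sin(2 * np.pi * freq * t), fs,
                     modality=modality)
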