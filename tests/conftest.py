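import numpy as np
import pytest

from pcgfusion import SignalTrace, SynthConfig, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sine_trace():
    """3 s of a 1 Hz unit sine at 100 Hz (crests at 0.25, 1.25, 2.25 s)."""
    fs = 100.0
    t = np.arange(300) / fs
    return SignalTrace(samples=np.sin(2 * np.pi * t), fs=fs, label="sine")


@pytest.fixture(scope="session")
def clean_recording():
    """Noiseless 60 s paired recording, fixed seed."""
    return generate_recording(SynthConfig(seed=42))


@pytest.fixture(scope="session")
def noisy_recording():
    """Same recording with 20 dB additive noise on both channels."""
    return generate_recording(SynthConfig(seed=42, snr_db=20.0))
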