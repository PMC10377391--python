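import numpy as np
import pytest

from voicegate import StftConfig, SynthSpec, Waveform, generate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cfg():
    """A fast COLA-compliant STFT config for unit tests."""
    return StftConfig(window_length=256, hop_length=64)


@pytest.fixture
def speech_like(rng):
    """A 0.5 s speech-band clip at 8 kHz: harmonic + noise, zero-mean."""
    sr = 8000
    t = np.arange(int(0.5 * sr)) / sr
    x = 0.4 * np.sin(2 * np.pi * 120 * t) + 0.15 * np.sin(2 * np.pi * 360 * t)
    x += 0.05 * rng.standard_normal(t.size)
    return Waveform(x / np.max(np.abs(x)) * 0.8, sr)


@pytest.fixture
def small_pair():
    """A compact synthetic clean/degraded pair (16 kHz, 1.2 s)."""
    return generate(SynthSpec(duration=1.2, sample_rate=16000, seed=99))
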