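import numpy as np
import pytest

from megdecode.features import SAMPLE_RATE, Waveform, preprocess_audio
from megdecode.synthetic import (
    GroundTruthEncoding,
    SimulationConfig,
    StimulusDesign,
    make_experiment,
)


def tone(freq_hz, duration_s=1.0, rate=SAMPLE_RATE, amp=0.1, item_id="tone"):
    t = np.arange(int(duration_s * rate)) / rate
    return Waveform(amp * np.sin(2 * np.pi * freq_hz * t), rate, item_id)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def word_waveform():
    """One preprocessed word-like stimulus, shared across feature tests."""
    rng = np.random.default_rng(11)
    t = np.arange(int(0.87 * SAMPLE_RATE)) / SAMPLE_RATE
    x = np.zeros_like(t)
    for f in (220, 440, 880, 1760):
        x += np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    x *= 0.4 + 0.6 * 0.5 * (1 - np.cos(2 * np.pi * 4.0 * t))
    x += 0.05 * rng.standard_normal(t.size)
    return preprocess_audio(Waveform(x, SAMPLE_RATE, "word87"))


@pytest.fixture(scope="session")
def small_experiment():
    """12-item time-locked synthetic experiment at gentle noise, reused by
    decoder/evaluation tests."""
    cfg = SimulationConfig(
        design=StimulusDesign(n_items=12),
        encoding=GroundTruthEncoding(regime="time_locked", noise_sd=2.0),
        n_channels=6, inventory_size=8, seed=7)
    return make_experiment(cfg)
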