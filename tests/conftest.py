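import numpy as np
import pytest

from swdnet.eeg_io import CANONICAL_CHANNELS, Recording
from swdnet.preprocess import preprocess_recording
from swdnet.synth_eeg import SynthConfig, simulate_recording


@pytest.fixture(scope="session")
def balanced_recording():
    """One 120 s balanced-preset synthetic recording with its truth events."""
    cfg = SynthConfig.balanced(duration_s=120.0, seed=11)
    rec, events = simulate_recording(cfg)
    return rec, events


@pytest.fixture(scope="session")
def small_example_corpus():
    """Preprocessed examples from 6 balanced 120 s records, split by record.

    Shared by the training-behavior tests so the (relatively expensive)
    simulation + preprocessing runs once per session.
    """
    cfg = SynthConfig.balanced(duration_s=120.0, seed=23)
    train, val = [], []
    for i in range(6):
        rec, _ = simulate_recording(cfg, i)
        exs = preprocess_recording(rec)
        (val if i >= 4 else train).extend(exs)
    return train, val


@pytest.fixture()
def sine_recording():
    """19-channel recording of pure sinusoids at 500 Hz, for filter tests."""
    fs = 500.0
    t = np.arange(int(10 * fs)) / fs
    data = np.tile(np.sin(2 * np.pi * 3.0 * t), (19, 1))
    return Recording(data, fs, list(CANONICAL_CHANNELS), record_id="sine3")
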