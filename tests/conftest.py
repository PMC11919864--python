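import numpy as np
import pytest

from emophys.io import Recording, TrialScores
from emophys.synth import SynthSpec, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_trial():
    """One 60 s separable-preset trial (EEG, ECG, scores, ground truth)."""
    spec = SynthSpec.separable(duration=60.0)
    return generate_recording(spec, class_label=1, subject_id=0, trial_id=0)


@pytest.fixture
def sine_recording():
    """Single-channel pure 10 Hz sine at 128 Hz, 30 s."""
    rate = 128.0
    t = np.arange(int(30 * rate)) / rate
    data = np.sin(2 * np.pi * 10.0 * t)[None, :]
    return Recording(data, rate, ["ch1"], "EEG")


def make_recording(data, rate=128.0, modality="EEG", names=None):
    data = np.atleast_2d(data)
    names = names or [f"c{i}" for i in range(data.shape[0])]
    return Recording(data, rate, names, modality)


@pytest.fixture
def scores():
    return TrialScores(2, 3, 5)
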