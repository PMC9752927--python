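import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from plinet.connectivity import ConnectivityMatrix
from plinet.montage import MONTAGE_25
from plinet.preprocess import EEGRecording


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def noise_recording(rng):
    """2 s of white noise on the full 25-channel montage."""
    data = rng.standard_normal((25, 1000)) * 20
    return EEGRecording(data=data, fs=500.0, labels=MONTAGE_25, subject_id="noise")


@pytest.fixture
def random_cm(rng):
    """Random symmetric PLI matrix on the full montage."""
    w = rng.uniform(0.02, 0.9, size=(25, 25))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(pli=w, band="theta", labels=MONTAGE_25)


def sine_recording(freq, fs=500.0, duration=4.0, labels=("C3", "C4")):
    t = np.arange(int(duration * fs)) / fs
    data = np.vstack([np.sin(2 * np.pi * freq * t) for _ in labels])
    return EEGRecording(data=data, fs=fs, labels=labels, subject_id="sine")
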