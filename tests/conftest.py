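import numpy as np
import pandas as pd
import pytest

from hipposture.features import Window

RATE = 30
WLEN = 150  # 5 s at 30 Hz
T0 = pd.Timestamp("2024-03-04T08:00:00")


def make_window(x, y, z, index=0):
    return Window(
        window_index=index,
        start_time=T0,
        x=np.asarray(x, float),
        y=np.asarray(y, float),
        z=np.asarray(z, float),
        sampling_rate_hz=RATE,
    )


@pytest.fixture
def constant_window():
    """Perfectly still device, z axis along gravity."""
    zeros = np.zeros(WLEN)
    return make_window(zeros, zeros, np.ones(WLEN))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def probs_from_labels(labels, p=0.9):
    """Probability matrix concentrated on the given labels."""
    labels = np.asarray(labels)
    probs = np.full((labels.size, 5), (1 - p) / 4)
    probs[np.arange(labels.size), labels] = p
    return probs
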