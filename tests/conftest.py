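import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from neobg.core import EPOCH_SAMPLES, EpochSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_epochset(epochs: np.ndarray, mask: np.ndarray | None = None,
                  labels: list[str] | None = None) -> EpochSet:
    epochs = np.asarray(epochs, dtype=float)
    if mask is None:
        mask = np.zeros(epochs.shape, dtype=bool)
    if labels is None:
        labels = [f"C{i}" for i in range(epochs.shape[1])]
    return EpochSet(epochs=epochs, artifact_mask=mask, channel_labels=labels)


@pytest.fixture
def epochset_factory():
    return make_epochset


@pytest.fixture(scope="session")
def sine_epoch():
    """10 Hz, 10 uV-amplitude sine, one 5-min epoch at 64 Hz."""
    t = np.arange(EPOCH_SAMPLES) / 64.0
    return 10.0 * np.sin(2 * np.pi * 10.0 * t)
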