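import numpy as np
import pytest

from eegmvpa import ChannelInfo, EpochedDataset


def make_dataset(
    data: np.ndarray,
    sfreq: float = 100.0,
    t0: float = 0.0,
    labels=None,
    channels=None,
    conditions=(),
) -> EpochedDataset:
    """Wrap a raw (trials, channels, times) array in a valid dataset."""
    n, c, T = data.shape
    times = t0 + 1000.0 / sfreq * np.arange(T)
    if channels is None:
        channels = [ChannelInfo(f"E{i:02d}") for i in range(c)]
    if labels is None:
        labels = np.array(["a"] * n)
    return EpochedDataset(
        data=data, times=times, sfreq=sfreq, labels=np.asarray(labels),
        channels=channels, conditions=tuple(conditions),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
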