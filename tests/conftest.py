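import numpy as np
import pytest

from bluediff.data import SyntheticConfig, TimeSeriesDataset, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_dataset():
    """20 records of 4 features x 24 time points, fully observed."""
    return simulate(SyntheticConfig(n_samples=20, K=4, L=24, seed=7))


@pytest.fixture
def ragged_dataset(rng):
    """Random small dataset with scattered missingness."""
    values = rng.standard_normal((6, 3, 10))
    mask = (rng.random((6, 3, 10)) < 0.8).astype(np.uint8)
    # keep at least one observed entry per feature
    mask[:, :, 0] = 1
    ts = np.broadcast_to(np.arange(10.0), (6, 10)).copy()
    return TimeSeriesDataset(np.where(mask, values, np.nan), mask, ts)
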