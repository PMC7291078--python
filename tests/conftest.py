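import numpy as np
import pytest

from scsdae.preprocess import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts(rng):
    """A 20 x 15 sparse-ish count matrix with no degenerate rows/columns."""
    values = rng.poisson(3.0, size=(20, 15)).astype(float)
    values[values < 2] = 0.0
    values[:, 0] += 1.0  # guarantee nonzero column
    values[0, :] += 1.0  # guarantee nonzero row
    values += np.eye(20, 15)  # keep every row and column expressed
    return CountMatrix(values)
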