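import numpy as np
import pytest

from netcure import NumericMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_matrix(rng):
    return NumericMatrix(rng.normal(size=(20, 6)))


@pytest.fixture
def rank1_missing():
    """Noiseless rank-1 outer product with one masked cell (truth 6)."""
    a = np.array([1.0, 2.0, 3.0, 4.0])
    b = np.array([1.0, 2.0, 3.0])
    values = np.outer(a, b)
    values[1, 2] = np.nan
    return NumericMatrix(values), 6.0
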