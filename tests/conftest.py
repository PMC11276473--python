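import numpy as np
import pytest

from dpmlpa.io_config import IndicatorMatrix, standardize_columns


def make_mixture(n_per, centers, seed, scale=1.0):
    """Balanced Gaussian draws around the given T x m centers; returns
    (raw matrix, 1-based labels)."""
    centers = np.asarray(centers, dtype=float)
    T = centers.shape[0]
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(1, T + 1), n_per)
    x = centers[labels - 1] + scale * rng.standard_normal((T * n_per, centers.shape[1]))
    return x, labels


@pytest.fixture(scope="session")
def three_profile_data():
    """n=300, m=4, three well-separated profiles (adjacent Mahalanobis 8)."""
    x, labels = make_mixture(100, [[-4.0] * 4, [0.0] * 4, [4.0] * 4], seed=11)
    return IndicatorMatrix(values=standardize_columns(x)), labels


@pytest.fixture(scope="session")
def single_profile_data():
    rng = np.random.default_rng(5)
    return IndicatorMatrix(values=standardize_columns(rng.standard_normal((200, 4))))
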