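import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_weights():
    """Factory for random symmetric weight matrices with zero diagonal."""

    def make(n, rng, low=0.05, high=1.0):
        W = rng.uniform(low, high, size=(n, n))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        return W

    return make
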