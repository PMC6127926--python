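import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_logistic_data(rng):
    """Well-conditioned clinico-genomic instance with both classes present."""
    n, q, p = 80, 2, 6
    D = rng.standard_normal((n, q))
    X = rng.standard_normal((n, p))
    eta = 0.3 + D @ np.array([0.4, -0.3]) + X @ rng.normal(0.0, 0.3, p)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    assert 0 < y.mean() < 1
    return D, X, y


@pytest.fixture
def gaussian_lspls_data(rng):
    """Continuous-response fixture for the Gaussian LS-PLS core."""
    n, q, p = 30, 2, 10
    D = rng.standard_normal((n, q))
    X = rng.standard_normal((n, p))
    y = 0.5 + D @ np.array([1.0, -0.5]) + X[:, 0] * 0.3 + rng.standard_normal(n) * 0.2
    return D, X, y
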