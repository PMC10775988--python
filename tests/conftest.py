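import numpy as np
import pytest

from mrpl import GenoPhenoData, standardize


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_data(rng):
    """120 samples, 25 SNPs, 4 exposures with genuine genetic signal and a
    shared confounder; outcome caused by the first exposure only."""
    n, m, k = 120, 25, 4
    G = standardize(rng.binomial(2, 0.3, size=(n, m)).astype(float))
    u = rng.normal(size=n)
    loads = rng.normal(size=(5, k))
    X = G[:, :5] @ loads + 0.8 * u[:, None] + 0.6 * rng.normal(size=(n, k))
    X = standardize(X)
    Y = standardize(0.5 * X[:, 0] + 0.5 * u + rng.normal(size=n))
    return GenoPhenoData(G=G, X=X, Y=Y)
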