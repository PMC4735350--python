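import numpy as np
import pytest

from grouppca import default_fixture


@pytest.fixture(scope="session")
def tiny_bundle():
    return default_fixture("tiny")


@pytest.fixture(scope="session")
def small_bundle():
    return default_fixture("small")


@pytest.fixture(scope="session")
def small_oracle(small_bundle):
    """Independent dense SVD of the explicitly stacked group matrix."""
    Y = small_bundle.provider.stacked_matrix()
    U, s, _ = np.linalg.svd(Y, full_matrices=False)
    lam = s**2 / (small_bundle.provider.v - 1)
    return U, lam


@pytest.fixture(scope="session")
def tiny_oracle(tiny_bundle):
    Y = tiny_bundle.provider.stacked_matrix()
    U, s, _ = np.linalg.svd(Y, full_matrices=False)
    lam = s**2 / (tiny_bundle.provider.v - 1)
    return U, lam


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
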