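import numpy as np
import pytest

from gismma import SimilarityMatrix, enumerate_isomers


def random_similarity(n: int, seed: int, zero_fraction: float = 0.0) -> SimilarityMatrix:
    """A random symmetric similarity matrix in [0, 1] with unit diagonal."""
    rng = np.random.default_rng(seed)
    w = rng.uniform(0.0, 1.0, size=(n, n))
    if zero_fraction:
        w[rng.uniform(size=(n, n)) < zero_fraction] = 0.0
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 1.0)
    return SimilarityMatrix(tuple(f"n{i}" for i in range(n)), w)


@pytest.fixture(scope="session")
def catalog():
    return enumerate_isomers()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
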