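import numpy as np
import pytest

from mirlink.data_model import AssociationDataset, SimilarityMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    A = np.array(
        [
            [1, 0, 1, 0],
            [0, 1, 0, 0],
            [1, 1, 0, 1],
            [0, 0, 1, 1],
            [1, 0, 0, 0],
        ],
        dtype=float,
    )
    return AssociationDataset([f"m{i}" for i in range(5)], [f"d{j}" for j in range(4)], A)


def random_similarity(n, rng, ids=None):
    M = rng.random((n, n))
    S = (M + M.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(ids or [f"x{i}" for i in range(n)], S)


@pytest.fixture
def similarity_factory(rng):
    def make(n, ids=None):
        return random_similarity(n, rng, ids)

    return make
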