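import numpy as np
import pytest

from cassacore import DistanceMatrix, GenotypeMatrix


@pytest.fixture
def toy_distance():
    """3-accession matrix with d(1,2)=0.2, d(1,3)=0.4, d(2,3)=0.6."""
    d = np.array([[0.0, 0.2, 0.4], [0.2, 0.0, 0.6], [0.4, 0.6, 0.0]])
    return DistanceMatrix(("1", "2", "3"), d, "gower")


@pytest.fixture
def random_distance():
    """Factory: random euclidean-based distance matrix in [0, 1]."""

    def make(n: int, seed: int = 0) -> DistanceMatrix:
        rng = np.random.default_rng(seed)
        x = rng.random((n, 3))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1)) / np.sqrt(3)
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix(tuple(f"A{i}" for i in range(n)), d, "gower")

    return make


@pytest.fixture
def random_genotypes():
    """Factory: random complete genotype matrix."""

    def make(n: int, l: int, seed: int = 0) -> GenotypeMatrix:
        rng = np.random.default_rng(seed)
        dos = rng.integers(0, 3, size=(n, l)).astype(np.int8)
        return GenotypeMatrix(
            tuple(f"A{i}" for i in range(n)),
            tuple(f"chr1:{j + 1}" for j in range(l)),
            dos,
        )

    return make
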