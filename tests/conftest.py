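import numpy as np
import pytest

from ships.genotypes import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_block_similarity():
    """Ideal similarity: two groups, within-similarity 2, across 0."""
    n1, n2 = 5, 7
    S = np.zeros((n1 + n2, n1 + n2))
    S[:n1, :n1] = 2.0
    S[n1:, n1:] = 2.0
    labels = np.array([0] * n1 + [1] * n2)
    return S, labels


@pytest.fixture
def three_block_similarity():
    """Three mutually dissimilar groups of 3 samples each."""
    S = np.zeros((9, 9))
    for start in (0, 3, 6):
        S[start : start + 3, start : start + 3] = 2.0
    labels = np.repeat([1, 2, 3], 3)
    return S, labels


@pytest.fixture
def small_genotypes(rng):
    values = rng.integers(0, 3, size=(12, 40))
    return GenotypeMatrix(values)


def random_partition_labels(rng, n, k):
    """k non-empty clusters over n samples, labels 1..k."""
    labels = np.concatenate([np.arange(1, k + 1), rng.integers(1, k + 1, size=n - k)])
    rng.shuffle(labels)
    # relabel contiguously by first appearance order of sorted uniques
    uniq = np.unique(labels)
    remap = {u: i + 1 for i, u in enumerate(uniq)}
    return np.array([remap[x] for x in labels])
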