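import numpy as np
import pytest
from hypothesis import settings

from mesoresolve import BinaryGraph, Partition, WeightedNetwork

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def two_clique_graph() -> BinaryGraph:
    """Two 4-cliques joined by a single bridge edge (8 nodes, 13 edges)."""
    a = np.zeros((8, 8))
    for block in (range(4), range(4, 8)):
        for i in block:
            for j in block:
                if i != j:
                    a[i, j] = 1.0
    a[3, 4] = a[4, 3] = 1.0
    return BinaryGraph(a)


@pytest.fixture
def two_clique_partition() -> Partition:
    return Partition(np.array([0, 0, 0, 0, 1, 1, 1, 1]))


@pytest.fixture
def small_weighted() -> WeightedNetwork:
    """3-node path with weights 1 and 2 (M=2, m=3)."""
    return WeightedNetwork(np.array([[0.0, 1.0, 0.0],
                                     [1.0, 0.0, 2.0],
                                     [0.0, 2.0, 0.0]]))


def random_binary_graph(n: int, p: float, rng) -> BinaryGraph:
    """Random symmetric 0/1 graph guaranteed to have at least one edge."""
    while True:
        upper = rng.random((n, n)) < p
        a = np.triu(upper, k=1).astype(float)
        a = a + a.T
        if a.sum() > 0:
            return BinaryGraph(a)
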