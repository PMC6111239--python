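import numpy as np
import pytest

from symkron import (
    AdjacencyMatrix,
    AssociationTable,
    DiseaseHierarchy,
    SimilarityMatrix,
    build_adjacency,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_node_hierarchy():
    """B is a child of A."""
    return DiseaseHierarchy.from_edges([("B", "A")])


@pytest.fixture
def small_adjacency():
    """2x2 identity adjacency: A-m1, B-m2."""
    return build_adjacency(
        AssociationTable.from_pairs([("A", "m1"), ("B", "m2")])
    )


def random_psd(n, rng, scale=1.0):
    q = rng.random((n, n)) * scale
    return q @ q.T


def random_adjacency(nd, nm, rng, density=0.4, prefix=("d", "m")):
    v = (rng.random((nd, nm)) < density).astype(float)
    return AdjacencyMatrix(
        tuple(f"{prefix[0]}{i}" for i in range(nd)),
        tuple(f"{prefix[1]}{j}" for j in range(nm)),
        v,
    )


def psd_similarity(ids, rng, scale=0.5):
    n = len(ids)
    return SimilarityMatrix(tuple(ids), random_psd(n, rng, scale))
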