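"""Semantic, functional, kernel and integrated similarity computations."""

import math

import numpy as np
import pytest

from symkron import (
    AdjacencyMatrix,
    AssociationTable,
    DiseaseHierarchy,
    KernelParams,
    SemanticParams,
    SimilarityMatrix,
    ValidationError,
    build_adjacency,
    combine_semantic,
    compute_dag_counts,
    disease_dag,
    disease_semantic_similarity,
    gaussian_kernel,
    integrate,
    mirna_functional_similarity,
    semantic_similarity,
)

P = SemanticParams(delta=0.5)


class TestDiseaseDAG:
    def test_isolated_node(self):
        h = DiseaseHierarchy.from_edges([], extra_nodes=["X"])
        dag = disease_dag(h, "X", P, {"X": 1}, 1)
        assert dag.nodes == {"X"}
        assert dag.contribution1 == {"X": 1.0}
        assert dag.dv1 == 1.0

    def test_chain_contributions_decay(self):
        # C -> B -> A, rooted at C
        h = DiseaseHierarchy.from_edges([("C", "B"), ("B", "A")])
        counts = compute_dag_counts(h, ["A", "B", "C"])
        dag = disease_dag(h, "C", P, counts, 3)
        assert dag.contribution1 == {"C": 1.0, "B": 0.5, "A": 0.25}
        assert dag.dv1 == pytest.approx(1.75, abs=1e-15)

    def test_information_content_contributions(self):
        h = DiseaseHierarchy.from_edges([("B", "A")])
        counts = compute_dag_counts(h, ["A", "B"])
        assert counts == {"A": 2, "B": 1}
        dag = disease_dag(h, "B", P, counts, 2)
        assert dag.contribution2["A"] == pytest.approx(0.0)
        assert dag.contribution2["B"] == pytest.approx(math.log(2))

    def test_max_over_multiple_paths(self):
        # two paths from D up to A: direct edge and via B; max rule keeps 0.5
        h = DiseaseHierarchy.from_edges([("D", "A"), ("D", "B"), ("B", "A")])
        counts = compute_dag_counts(h, ["A", "B", "D"])
        dag = disease_dag(h, "D", P, counts, 3)
        assert dag.contribution1["A"] == pytest.approx(0.5)

    def test_unknown_disease_raises(self, two_node_hierarchy):
        with pytest.raises(KeyError):
            disease_dag(two_node_hierarchy, "Z", P, {}, 1)


class TestSemanticSimilarity:
    def test_two_node_fixture(self, two_node_hierarchy):
        ss1, ss2, ss = disease_semantic_similarity(
            two_node_hierarchy, ["A", "B"], P
        )
        assert ss1.values[0, 1] == pytest.approx(0.6, abs=1e-12)
        assert np.array_equal(np.diag(ss1.values), [1.0, 1.0])
        # A appears in both DAGs so its information content is zero
        assert ss2.values[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert ss.values[0, 1] == pytest.approx(0.3, abs=1e-12)

    def test_degenerate_denominator_defined(self, two_node_hierarchy):
        # DV2(A) = 0 (A is in every DAG): SS2(A,A) is 0/0, defined as 1
        _, ss2, _ = disease_semantic_similarity(two_node_hierarchy, ["A", "B"], P)
        assert ss2.values[0, 0] == 1.0

    def test_log_base_invariance(self, two_node_hierarchy):
        _, e, _ = disease_semantic_similarity(
            two_node_hierarchy, ["A", "B"], SemanticParams(delta=0.5)
        )
        _, b2, _ = disease_semantic_similarity(
            two_node_hierarchy, ["A", "B"], SemanticParams(delta=0.5, log_base=2)
        )
        assert np.abs(e.values - b2.values).max() < 1e-10

    def test_edge_insertion_order_invariance(self):
        edges = [("C", "B"), ("B", "A"), ("D", "B"), ("E", "A")]
        ids = ["A", "B", "C", "D", "E"]
        a = disease_semantic_similarity(DiseaseHierarchy.from_edges(edges), ids, P)
        b = disease_semantic_similarity(
            DiseaseHierarchy.from_edges(edges[::-1]), ids, P
        )
        assert np.array_equal(a[0].values, b[0].values)

    def test_disease_outside_hierarchy_gets_zero_offdiag(self, two_node_hierarchy):
        ss1, _, _ = disease_semantic_similarity(
            two_node_hierarchy, ["A", "B", "Orphan"], P
        )
        assert ss1.values[2, 2] == 1.0
        assert ss1.values[0, 2] == 0.0 and ss1.values[2, 1] == 0.0

    def test_combine_identical_is_identity(self, two_node_hierarchy):
        ss1, _, _ = disease_semantic_similarity(two_node_hierarchy, ["A", "B"], P)
        assert np.array_equal(combine_semantic(ss1, ss1).values, ss1.values)

    def test_combine_label_mismatch_raises(self):
        a = SimilarityMatrix(("x",), np.eye(1), "SS1")
        b = SimilarityMatrix(("y",), np.eye(1), "SS2")
        with pytest.raises(KeyError):
            combine_semantic(a, b)

    def test_bad_model_rejected(self):
        with pytest.raises(ValidationError):
            semantic_similarity({}, 3)


class TestFunctionalSimilarity:
    def _ss(self):
        v = np.array([[1.0, 0.6], [0.6, 1.0]])
        return SimilarityMatrix(("A", "B"), v, "SS")

    def test_identical_single_disease_groups(self):
        a = build_adjacency(
            AssociationTable.from_pairs([("A", "m1"), ("A", "m2")]),
            diseases=["A", "B"],
        )
        fs = mirna_functional_similarity(a, self._ss())
        assert fs.values[0, 1] == pytest.approx(1.0)

    def test_group_max_rule(self):
        a = build_adjacency(
            AssociationTable.from_pairs([("A", "m1"), ("B", "m2")])
        )
        fs = mirna_functional_similarity(a, self._ss())
        assert fs.values[0, 1] == pytest.approx(0.6, abs=1e-12)

    def test_disjoint_groups_zero_similarity(self):
        ss = SimilarityMatrix(("A", "B"), np.eye(2), "SS")
        a = build_adjacency(
            AssociationTable.from_pairs([("A", "m1"), ("B", "m2")])
        )
        assert mirna_functional_similarity(a, ss).values[0, 1] == 0.0

    def test_empty_group_zero_offdiag_unit_diag(self):
        a = build_adjacency(
            AssociationTable.from_pairs([("A", "m1")]), mirnas=["m1", "m2"]
        )
        fs = mirna_functional_similarity(a, self._ss())
        assert fs.values[1, 1] == 1.0 and fs.values[0, 1] == 0.0


class TestGaussianKernel:
    def test_unit_diagonal(self, rng):
        from .conftest import random_adjacency

        a = random_adjacency(5, 7, rng)
        for axis in ("disease", "mirna"):
            k = gaussian_kernel(a, axis)
            assert np.array_equal(np.diag(k.values), np.ones(k.n))

    def test_identity_adjacency_fixture(self, small_adjacency):
        kd = gaussian_kernel(small_adjacency, "disease")
        assert kd.values[0, 1] == pytest.approx(math.exp(-2), abs=1e-12)

    def test_all_zero_adjacency_rejected(self):
        a = AdjacencyMatrix(("d1",), ("m1",), np.zeros((1, 1)))
        with pytest.raises(ValidationError, match="bandwidth undefined"):
            gaussian_kernel(a, "disease")

    def test_strictly_decreasing_in_hamming_distance(self):
        # profiles at Hamming distance 1, 2, 3 from the first row
        v = np.array(
            [
                [1, 1, 1, 0, 0],
                [1, 1, 0, 0, 0],
                [1, 0, 0, 1, 0],
                [0, 0, 0, 1, 1],
            ],
            dtype=float,
        )
        a = AdjacencyMatrix(tuple("abcd"), tuple(f"m{i}" for i in range(5)), v)
        k = gaussian_kernel(a, "disease").values
        assert k[0, 1] > k[0, 2] > k[0, 3]

    def test_shared_association_monotonicity(self):
        # adding a shared association leaves the profile distance (hence KM)
        # unchanged; adding it to one miRNA only strictly decreases KM
        # third miRNA with a heavy profile keeps the bandwidth from simply
        # rescaling away the distance change
        base = AdjacencyMatrix(
            ("d1", "d2", "d3", "d4", "d5"), ("m1", "m2", "m3"),
            np.array([[1, 0, 1], [0, 1, 1], [0, 0, 1],
                      [0, 0, 1], [0, 0, 0]], dtype=float),
        )
        shared = base.values.copy(); shared[4, 0] = shared[4, 1] = 1.0
        one_sided = base.values.copy(); one_sided[4, 0] = 1.0
        shared_a = AdjacencyMatrix(base.diseases, base.mirnas, shared)
        one_a = AdjacencyMatrix(base.diseases, base.mirnas, one_sided)
        p = KernelParams()

        def exponent_arg(a):
            prof = a.values.T
            return ((prof[0] - prof[1]) ** 2).sum()

        # a shared association leaves the exponent argument unchanged;
        # a one-sided one strictly increases it
        assert exponent_arg(shared_a) == exponent_arg(base)
        assert exponent_arg(one_a) > exponent_arg(base)
        km_base = gaussian_kernel(base, "mirna", p).values[0, 1]
        km_one = gaussian_kernel(one_a, "mirna", p).values[0, 1]
        assert km_one < km_base

    def test_gamma_prime_default_is_one(self):
        assert KernelParams().gamma_prime_d == 1.0
        assert KernelParams().gamma_prime_m == 1.0


class TestIntegrate:
    def test_arithmetic_fixture(self, two_node_hierarchy, small_adjacency):
        _, _, ss = disease_semantic_similarity(two_node_hierarchy, ["A", "B"], P)
        kd = gaussian_kernel(small_adjacency, "disease")
        sd = integrate(ss, kd)
        assert sd.role == "SD"
        assert sd.values[0, 1] == pytest.approx((0.3 + math.exp(-2)) / 2, abs=1e-12)
        assert sd.values[0, 0] == 1.0

    def test_idempotent_on_equal_inputs(self, rng):
        v = rng.random((3, 3))
        m = SimilarityMatrix(("a", "b", "c"), (v + v.T) / 4)
        assert np.array_equal(integrate(m, m).values, m.values)

    def test_label_mismatch_raises(self):
        a = SimilarityMatrix(("x",), np.eye(1))
        b = SimilarityMatrix(("y",), np.eye(1))
        with pytest.raises(KeyError):
            integrate(a, b)


def test_all_similarities_symmetric_bounded(rng):
    """Every produced similarity is symmetric with entries in [0, 1] and a
    unit diagonal."""
    from .conftest import random_adjacency

    h = DiseaseHierarchy.from_edges(
        [("d1", "root"), ("d2", "root"), ("d3", "d1")]
    )
    a = random_adjacency(4, 6, rng, prefix=("d", "m"))
    ss1, ss2, ss = disease_semantic_similarity(h, a.diseases, P)
    mats = [ss1, ss2, ss,
            gaussian_kernel(a, "disease"), gaussian_kernel(a, "mirna"),
            mirna_functional_similarity(a, ss)]
    mats.append(integrate(ss, mats[3]))
    for m in mats:
        assert np.abs(m.values - m.values.T).max() < 1e-10
        assert m.values.min() >= 0.0 and m.values.max() <= 1.0 + 1e-10
        assert np.allclose(np.diag(m.values), 1.0)
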