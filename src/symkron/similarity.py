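"""Disease and miRNA similarity measures.

Four ingredients feed the integrated similarities:

* semantic similarity over the disease hierarchy, in two variants — a
  decay-based contribution model (each ancestor contributes ``delta`` per
  edge of distance from the disease, taking the max over paths) and an
  information-content model (an ancestor shared by many disease DAGs is less
  informative, contributing ``-log(count/n_diseases)``) — averaged into SS;
* miRNA functional similarity FS, computed from the disease groups of each
  miRNA by the group-max rule (or supplied precomputed);
* Gaussian interaction-profile kernels KD/KM over rows/columns of the
  adjacency, with bandwidth normalized by the mean squared profile norm;
* the integrated similarities SD = (SS+KD)/2 and SM = (FS+KM)/2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .datatypes import (
    AdjacencyMatrix,
    DiseaseHierarchy,
    SimilarityMatrix,
    ValidationError,
)

__all__ = [
    "SemanticParams",
    "KernelParams",
    "DiseaseDAG",
    "compute_dag_counts",
    "disease_dag",
    "semantic_similarity",
    "combine_semantic",
    "disease_semantic_similarity",
    "mirna_functional_similarity",
    "gaussian_kernel",
    "integrate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SemanticParams:
    """Parameters of the semantic similarity models.

    delta
        Semantic contribution factor in (0, 1): per-edge decay applied to an
        ancestor's contribution in model 1.  Default 0.5, the value used by
        the similarity method this model family descends from.
    log_base
        Base of the logarithm in the information-content contribution of
        model 2; ``None`` means natural log.  The model-2 similarity is
        invariant to this choice (numerator and denominator scale together).
    """

    delta: float = 0.5
    log_base: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.delta < 1.0:
            raise ValidationError(f"delta must be in (0, 1), got {self.delta}")
        if self.log_base is not None and (self.log_base <= 0 or self.log_base == 1):
            raise ValidationError("log_base must be positive and != 1")

    def _log(self, x: float) -> float:
        return math.log(x) if self.log_base is None else math.log(x, self.log_base)


@dataclass(frozen=True)
class KernelParams:
    """Gaussian interaction-profile kernel bandwidth scale parameters.

    ``gamma_prime_d`` / ``gamma_prime_m`` are the unnormalized bandwidths;
    the effective bandwidth divides them by the mean squared profile norm on
    the corresponding axis.  Both default to 1.
    """

    gamma_prime_d: float = 1.0
    gamma_prime_m: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma_prime_d <= 0 or self.gamma_prime_m <= 0:
            raise ValidationError("kernel bandwidth parameters must be > 0")


@dataclass(frozen=True)
class DiseaseDAG:
    """One disease's ancestor DAG with both contribution models evaluated.

    ``nodes`` is T(D): the disease plus all its ancestors; ``edges`` are the
    hierarchy's child->parent edges restricted to T(D).  ``contribution1``
    maps each node to its decay-model contribution (1 at the root disease),
    ``contribution2`` to its information-content contribution; ``dv1``/``dv2``
    are the respective semantic values (sums over T(D)).
    """

    root: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    contribution1: Mapping[str, float]
    contribution2: Mapping[str, float]
    dv1: float
    dv2: float


def compute_dag_counts(
    hierarchy: DiseaseHierarchy, diseases: Sequence[str]
) -> dict[str, int]:
    """For each hierarchy node, the number of modeled diseases whose ancestor
    DAG contains it.  Counts are over the modeled disease set only; diseases
    absent from the hierarchy contribute nothing."""
    counts: dict[str, int] = {}
    for d in diseases:
        if d not in hierarchy:
            continue
        for t in hierarchy.ancestor_closure(d):
            counts[t] = counts.get(t, 0) + 1
    return counts


def disease_dag(
    hierarchy: DiseaseHierarchy,
    d: str,
    params: SemanticParams,
    dag_counts: Mapping[str, int],
    n_diseases: int,
) -> DiseaseDAG:
    """Build DAG(d) and evaluate both contribution models on it.

    Model 1: the disease itself contributes 1; every other node t in T(d)
    contributes ``max(delta * contribution1[c])`` over its children c within
    T(d).  Model 2: node t contributes ``-log(dag_counts[t] / n_diseases)``.
    """
    if d not in hierarchy:
        raise KeyError(f"disease {d!r} not in hierarchy")
    nodes = hierarchy.ancestor_closure(d)
    edges = frozenset(
        (c, p) for c, p in hierarchy.edges if c in nodes and p in nodes
    )
    sub = nx.DiGraph()
    sub.add_nodes_from(nodes)
    sub.add_edges_from(edges)  # child -> parent
    contribution1: dict[str, float] = {}
    # children of a node are its predecessors in the child->parent digraph;
    # topological order guarantees children are evaluated first
    for t in nx.topological_sort(sub):
        if t == d:
            contribution1[t] = 1.0
        else:
            contribution1[t] = max(
                params.delta * contribution1[c] for c in sub.predecessors(t)
            )
    contribution2: dict[str, float] = {}
    for t in nodes:
        count = dag_counts.get(t, 0)
        if count < 1:
            raise ValidationError(
                f"dag_counts[{t!r}] must be >= 1 for nodes of a modeled DAG"
            )
        contribution2[t] = -params._log(count / n_diseases)
    return DiseaseDAG(
        root=d,
        nodes=nodes,
        edges=edges,
        contribution1=contribution1,
        contribution2=contribution2,
        dv1=float(sum(contribution1.values())),
        dv2=float(sum(contribution2.values())),
    )


def semantic_similarity(
    dags: Mapping[str, DiseaseDAG],
    model: int,
    ids: Sequence[str] | None = None,
) -> SimilarityMatrix:
    """Pairwise semantic similarity from per-disease DAG contributions.

    ``sim(i, j) = sum over shared ancestors t of (contrib_i[t] + contrib_j[t])
    divided by (DV(i) + DV(j))``.  Diseases in ``ids`` without a DAG (absent
    from the hierarchy) get similarity 0 off-diagonal and 1 on the diagonal.
    A degenerate 0/0 (both semantic values zero, possible in model 2 when
    both diseases appear in every DAG) is defined as 1 on the diagonal and 0
    off it; the occurrence is logged.
    """
    if model not in (1, 2):
        raise ValidationError(f"model must be 1 or 2, got {model}")
    order = tuple(ids) if ids is not None else tuple(dags)
    n = len(order)
    v = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = dags.get(order[i]), dags.get(order[j])
            if a is None or b is None:
                continue
            ca = a.contribution1 if model == 1 else a.contribution2
            cb = b.contribution1 if model == 1 else b.contribution2
            dva = a.dv1 if model == 1 else a.dv2
            dvb = b.dv1 if model == 1 else b.dv2
            denom = dva + dvb
            if denom == 0.0:
                logger.info(
                    "degenerate semantic denominator for (%s, %s); defined as 0",
                    order[i], order[j],
                )
                continue
            shared = a.nodes & b.nodes
            v[i, j] = v[j, i] = sum(ca[t] + cb[t] for t in shared) / denom
    return SimilarityMatrix(order, v, f"SS{model}")


def combine_semantic(
    ss1: SimilarityMatrix, ss2: SimilarityMatrix
) -> SimilarityMatrix:
    """Final semantic similarity SS = (SS1 + SS2) / 2, entrywise."""
    if ss1.ids != ss2.ids:
        raise KeyError("semantic similarity matrices have mismatched id lists")
    return SimilarityMatrix(ss1.ids, (ss1.values + ss2.values) / 2.0, "SS")


def disease_semantic_similarity(
    hierarchy: DiseaseHierarchy,
    diseases: Sequence[str],
    params: SemanticParams = SemanticParams(),
) -> tuple[SimilarityMatrix, SimilarityMatrix, SimilarityMatrix]:
    """Convenience: build every DAG and return (SS1, SS2, SS) over
    ``diseases``.  Diseases missing from the hierarchy are retained with
    zero off-diagonal similarity."""
    modeled = [d for d in diseases if d in hierarchy]
    counts = compute_dag_counts(hierarchy, modeled)
    dags = {
        d: disease_dag(hierarchy, d, params, counts, len(diseases))
        for d in modeled
    }
    ss1 = semantic_similarity(dags, 1, ids=diseases)
    ss2 = semantic_similarity(dags, 2, ids=diseases)
    return ss1, ss2, combine_semantic(ss1, ss2)


def mirna_functional_similarity(
    a: AdjacencyMatrix, ss: SimilarityMatrix
) -> SimilarityMatrix:
    """Functional similarity of miRNAs through their disease groups.

    For miRNAs with associated-disease groups D1 and D2::

        FS = (sum_{d in D1} max_{e in D2} ss(d, e)
              + sum_{d in D2} max_{e in D1} ss(d, e)) / (|D1| + |D2|)

    The diagonal is 1; a miRNA with no associated disease gets 0
    off-diagonal.
    """
    ss_sub = ss.reindex(a.diseases)
    nm = len(a.mirnas)
    groups = [np.nonzero(a.values[:, j])[0] for j in range(nm)]
    v = np.eye(nm)
    for i in range(nm):
        gi = groups[i]
        if gi.size == 0:
            continue
        for j in range(i + 1, nm):
            gj = groups[j]
            if gj.size == 0:
                continue
            cross = ss_sub.values[np.ix_(gi, gj)]
            v[i, j] = v[j, i] = (
                cross.max(axis=1).sum() + cross.max(axis=0).sum()
            ) / (gi.size + gj.size)
    return SimilarityMatrix(a.mirnas, v, "FS")


def gaussian_kernel(
    a: AdjacencyMatrix,
    axis: str,
    params: KernelParams = KernelParams(),
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over rows (``axis='disease'``) or
    columns (``axis='mirna'``) of the adjacency.

    The bandwidth is ``gamma = gamma_prime / mean(||profile||^2)`` over all
    profiles on the chosen axis; ``K(i, j) = exp(-gamma ||IP_i - IP_j||^2)``.
    """
    if axis == "disease":
        profiles, ids, gp, role = a.values, a.diseases, params.gamma_prime_d, "KD"
    elif axis == "mirna":
        profiles, ids, gp, role = a.values.T, a.mirnas, params.gamma_prime_m, "KM"
    else:
        raise ValidationError(f"axis must be 'disease' or 'mirna', got {axis!r}")
    sq_norms = (profiles ** 2).sum(axis=1)
    mean_sq = float(sq_norms.mean()) if sq_norms.size else 0.0
    if mean_sq == 0.0:
        raise ValidationError("bandwidth undefined (all-zero adjacency)")
    gamma = gp / mean_sq
    # ||x - y||^2 for binary profiles, via the gram matrix
    gram = profiles @ profiles.T
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * gram
    np.maximum(d2, 0.0, out=d2)
    v = np.exp(-gamma * d2)
    np.fill_diagonal(v, 1.0)
    v = (v + v.T) / 2.0
    return SimilarityMatrix(ids, v, role)


def integrate(
    sem_or_fs: SimilarityMatrix, kernel: SimilarityMatrix, role: str = ""
) -> SimilarityMatrix:
    """Integrated similarity: the entrywise mean of a semantic/functional
    similarity and the corresponding Gaussian kernel."""
    if sem_or_fs.ids != kernel.ids:
        raise KeyError("integrated similarity inputs have mismatched id lists")
    if not role:
        role = {"SS": "SD", "FS": "SM"}.get(sem_or_fs.role, "")
    return SimilarityMatrix(
        sem_or_fs.ids, (sem_or_fs.values + kernel.values) / 2.0, role
    )
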