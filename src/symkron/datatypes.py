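"""Core data containers for bipartite disease-miRNA association modeling.

The containers are deliberately thin: labeled numpy arrays plus validation.
Rows of every disease x miRNA matrix are diseases, columns are miRNAs, and
``vec`` anywhere in this package means column-stacking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "AssociationTable",
    "AdjacencyMatrix",
    "DiseaseHierarchy",
    "SimilarityMatrix",
    "ScoreMatrix",
    "BOUNDED_ROLES",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected text format."""


class ValidationError(ValueError):
    """Raised when a container invariant is violated."""


#: similarity roles whose entries must lie in [0, 1]
BOUNDED_ROLES = frozenset({"SS1", "SS2", "SS", "KD", "KM", "SD", "SM"})


def _unique_in_order(items: Iterable[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for x in items:
        seen.setdefault(x, None)
    return tuple(seen)


@dataclass(frozen=True)
class AssociationTable:
    """Ordered, deduplicated list of (disease_id, mirna_id) pairs."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        for d, m in self.pairs:
            if not d or not m:
                raise ValidationError("association ids must be non-empty strings")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValidationError("duplicate association pair after normalization")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AssociationTable":
        """Build a table, trimming whitespace and dropping duplicate pairs
        while preserving first-appearance order."""
        seen: dict[tuple[str, str], None] = {}
        for d, m in pairs:
            seen.setdefault((d.strip(), m.strip()), None)
        return cls(tuple(seen))

    @property
    def diseases(self) -> tuple[str, ...]:
        return _unique_in_order(d for d, _ in self.pairs)

    @property
    def mirnas(self) -> tuple[str, ...]:
        return _unique_in_order(m for _, m in self.pairs)

    def without(self, removed: Iterable[tuple[str, str]]) -> "AssociationTable":
        gone = set(removed)
        return AssociationTable(tuple(p for p in self.pairs if p not in gone))

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.pairs)

    def __contains__(self, pair: object) -> bool:
        return pair in set(self.pairs)


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Binary disease x miRNA matrix A of verified associations.

    ``values[i, j] == 1`` iff ``(diseases[i], mirnas[j])`` is a known
    association.  Row i of A is the interaction profile IP(d(i)) of disease
    d(i); column j is the interaction profile IP(m(j)) of miRNA m(j).
    """

    diseases: tuple[str, ...]
    mirnas: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.diseases), len(self.mirnas)):
            raise ValidationError(
                f"adjacency shape {v.shape} does not match label lists "
                f"({len(self.diseases)} x {len(self.mirnas)})"
            )
        if len(set(self.diseases)) != len(self.diseases):
            raise ValidationError("duplicate disease ids")
        if len(set(self.mirnas)) != len(self.mirnas):
            raise ValidationError("duplicate miRNA ids")
        if not np.isin(v, (0.0, 1.0)).all():
            raise ValidationError("adjacency entries must be 0 or 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def disease_index(self, d: str) -> int:
        try:
            return self.diseases.index(d)
        except ValueError:
            raise KeyError(f"unknown disease id: {d!r}") from None

    def mirna_index(self, m: str) -> int:
        try:
            return self.mirnas.index(m)
        except ValueError:
            raise KeyError(f"unknown miRNA id: {m!r}") from None

    def mask_pairs(self, pairs: Iterable[tuple[str, str]]) -> "AdjacencyMatrix":
        """Return a copy with the given known pairs set to 0."""
        v = self.values.copy()
        for d, m in pairs:
            v[self.disease_index(d), self.mirna_index(m)] = 0.0
        return AdjacencyMatrix(self.diseases, self.mirnas, v)

    def zero_disease_row(self, d: str) -> "AdjacencyMatrix":
        """Return a copy where disease ``d`` has all associations removed
        (the 'new disease' protocol)."""
        v = self.values.copy()
        v[self.disease_index(d), :] = 0.0
        return AdjacencyMatrix(self.diseases, self.mirnas, v)

    def to_table(self) -> AssociationTable:
        rows, cols = np.nonzero(self.values)
        return AssociationTable(
            tuple((self.diseases[i], self.mirnas[j]) for i, j in zip(rows, cols))
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.diseases),
                            columns=list(self.mirnas))


@dataclass(frozen=True)
class DiseaseHierarchy:
    """Directed acyclic child -> parent edge set over disease terms."""

    edges: frozenset[tuple[str, str]]
    node_ids: frozenset[str]

    def __post_init__(self) -> None:
        for c, p in self.edges:
            if c not in self.node_ids or p not in self.node_ids:
                raise ValidationError(f"edge ({c!r}, {p!r}) references unknown node")
            if c == p:
                raise ValidationError(f"self-edge on node {c!r}")
        g = self.to_graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValidationError(f"hierarchy contains a cycle: {cycle}")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        extra_nodes: Iterable[str] = (),
    ) -> "DiseaseHierarchy":
        e = frozenset((c.strip(), p.strip()) for c, p in edges)
        nodes = frozenset(x for edge in e for x in edge) | frozenset(
            n.strip() for n in extra_nodes
        )
        return cls(e, nodes)

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from(self.edges)  # direction: child -> parent
        return g

    def ancestor_closure(self, d: str) -> frozenset[str]:
        """T(d): the node itself plus every ancestor reachable through
        child -> parent edges."""
        if d not in self.node_ids:
            raise KeyError(f"disease {d!r} not in hierarchy")
        g = self.to_graph()
        return frozenset({d} | nx.descendants(g, d))

    def __contains__(self, d: object) -> bool:
        return d in self.node_ids


def _check_square_symmetric(ids: Sequence[str], v: np.ndarray, tol: float) -> None:
    n = len(ids)
    if v.shape != (n, n):
        raise ValidationError(f"matrix shape {v.shape} does not match {n} ids")
    if len(set(ids)) != n:
        raise ValidationError("duplicate ids in similarity matrix")
    asym = float(np.abs(v - v.T).max()) if n else 0.0
    if asym > tol:
        raise ValidationError(f"matrix asymmetric beyond {tol:g} (max dev {asym:g})")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Labeled symmetric non-negative square matrix.

    ``role`` records which similarity this is (FS, SS1, SS2, SS, KD, KM, SD,
    SM, or the interpolated SD*, SM*); roles in :data:`BOUNDED_ROLES` must
    additionally have entries <= 1.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    role: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        _check_square_symmetric(self.ids, v, tol=1e-8)
        if v.size and float(v.min()) < -1e-10:
            raise ValidationError(f"negative similarity entry ({v.min():g})")
        if self.role in BOUNDED_ROLES and v.size and float(v.max()) > 1.0 + 1e-10:
            raise ValidationError(
                f"role {self.role}: entry {v.max():g} exceeds 1"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    def reindex(self, ids: Sequence[str]) -> "SimilarityMatrix":
        """Return the submatrix over ``ids`` in the given order."""
        pos = {x: i for i, x in enumerate(self.ids)}
        try:
            idx = np.array([pos[x] for x in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"id {e.args[0]!r} missing from similarity matrix") from None
        return SimilarityMatrix(tuple(ids), self.values[np.ix_(idx, idx)], self.role)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


@dataclass(frozen=True)
class ScoreMatrix:
    """Real-valued disease x miRNA score matrix S, labels as the adjacency."""

    diseases: tuple[str, ...]
    mirnas: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.diseases), len(self.mirnas)):
            raise ValidationError("score matrix shape does not match labels")
        if v.size and not np.isfinite(v).all():
            raise ValidationError("non-finite score entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def score(self, d: str, m: str) -> float:
        return float(
            self.values[self.diseases.index(d), self.mirnas.index(m)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.diseases),
                            columns=list(self.mirnas))
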