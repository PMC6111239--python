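"""Readers and writers for the package's tab-separated text formats.

All formats are UTF-8 TSV with ``#`` comment lines.  Ids are matched
case-sensitively after trimming surrounding whitespace (disease names may
contain internal spaces).  Matrix write/read round-trips to better than
1e-12.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    AdjacencyMatrix,
    AssociationTable,
    DiseaseHierarchy,
    FormatError,
    ScoreMatrix,
    SimilarityMatrix,
)

__all__ = [
    "read_associations",
    "build_adjacency",
    "read_hierarchy",
    "read_matrix",
    "write_matrix",
    "write_predictions",
]


def _data_lines(path: str | os.PathLike) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_associations(path: str | os.PathLike) -> AssociationTable:
    """Read a (disease_id, mirna_id) TSV into a deduplicated table.

    Lines with fewer than two tab-separated fields raise :class:`FormatError`
    with the offending line number; extra fields are ignored.
    """
    pairs: list[tuple[str, str]] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(
                f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
            )
        pairs.append((fields[0], fields[1]))
    return AssociationTable.from_pairs(pairs)


def build_adjacency(
    table: AssociationTable,
    diseases: Sequence[str] | None = None,
    mirnas: Sequence[str] | None = None,
) -> AdjacencyMatrix:
    """Build the binary matrix A from an association table.

    Row/column order follows the explicit id lists when given, else the order
    of first appearance in the table.  The entry sum equals the number of
    distinct pairs.
    """
    ds = tuple(diseases) if diseases is not None else table.diseases
    ms = tuple(mirnas) if mirnas is not None else table.mirnas
    di = {d: i for i, d in enumerate(ds)}
    mi = {m: j for j, m in enumerate(ms)}
    v = np.zeros((len(ds), len(ms)))
    for d, m in table:
        if d not in di:
            raise KeyError(f"disease {d!r} not covered by the explicit disease list")
        if m not in mi:
            raise KeyError(f"miRNA {m!r} not covered by the explicit miRNA list")
        v[di[d], mi[m]] = 1.0
    return AdjacencyMatrix(ds, ms, v)


def read_hierarchy(path: str | os.PathLike) -> DiseaseHierarchy:
    """Read a child TAB parent edge list; rejects self-edges and cycles."""
    edges: list[tuple[str, str]] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(
                f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
            )
        edges.append((fields[0], fields[1]))
    return DiseaseHierarchy.from_edges(edges)


def read_matrix(path: str | os.PathLike, role: str = "") -> SimilarityMatrix:
    """Read a labeled square matrix (header row of ids, then one labeled row
    per id).  Non-square, asymmetric (beyond 1e-8) or negative input is
    rejected by :class:`SimilarityMatrix` validation."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    ids = tuple(str(c) for c in df.columns)
    row_ids = tuple(str(r) for r in df.index)
    if ids != row_ids:
        raise FormatError(
            f"{path}: row labels do not match column labels (non-square or reordered)"
        )
    return SimilarityMatrix(ids, df.to_numpy(dtype=float), role)


def _header_comments(metadata: Mapping[str, object] | None) -> list[str]:
    if not metadata:
        return []
    return [f"# {k}={metadata[k]}" for k in metadata]


def write_matrix(
    m: SimilarityMatrix | ScoreMatrix,
    path: str | os.PathLike,
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write a labeled matrix as TSV with full float precision (%.17g), so
    that write followed by read is the identity to 1e-12 (in fact exactly)."""
    if isinstance(m, ScoreMatrix):
        row_ids, col_ids = m.diseases, m.mirnas
    else:
        row_ids = col_ids = m.ids
    with open(path, "w", encoding="utf-8") as fh:
        for line in _header_comments(metadata):
            fh.write(line + "\n")
        fh.write("\t".join(("",) + tuple(col_ids)) + "\n")
        for i, rid in enumerate(row_ids):
            row = "\t".join(f"{x:.17g}" for x in m.values[i])
            fh.write(f"{rid}\t{row}\n")


def write_predictions(
    s: ScoreMatrix,
    path: str | os.PathLike,
    adjacency: AdjacencyMatrix | None = None,
    top_k: int | None = None,
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write per-disease rankings as (disease_id, mirna_id, score, rank, known).

    Rows are sorted by descending score within each disease; ``top_k`` keeps
    the best k miRNAs per disease; ``known`` flags pairs already present in
    the adjacency (0 when no adjacency is supplied).
    """
    known = (
        adjacency.values
        if adjacency is not None
        else np.zeros(s.values.shape)
    )
    if adjacency is not None and (
        adjacency.diseases != s.diseases or adjacency.mirnas != s.mirnas
    ):
        raise KeyError("adjacency labels do not match score matrix labels")
    with open(path, "w", encoding="utf-8") as fh:
        for line in _header_comments(metadata):
            fh.write(line + "\n")
        fh.write("disease_id\tmirna_id\tscore\trank\tknown\n")
        for i, d in enumerate(s.diseases):
            order = np.argsort(-s.values[i], kind="stable")
            if top_k is not None:
                order = order[:top_k]
            for rank, j in enumerate(order, start=1):
                fh.write(
                    f"{d}\t{s.mirnas[j]}\t{s.values[i, j]:.12g}\t{rank}"
                    f"\t{int(known[i, j])}\n"
                )
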