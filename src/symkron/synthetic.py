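"""Synthetic bipartite benchmark with planted block structure.

The generator emulates the statistical structure the predictor assumes:
functionally related miRNAs associate with related diseases.  Diseases and
miRNAs are partitioned into latent blocks; a true association is planted
with ``within_block_prob`` when the blocks match and ``background_prob``
otherwise; a fraction of the planted truth is masked (held out) to form the
observed data.  The disease hierarchy is a rooted forest with one tree per
block whose nodes are the block's diseases, so that semantic similarity is
informative about block membership.  All randomness flows from one seeded
generator; a dataset is bitwise reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datatypes import (
    AdjacencyMatrix,
    AssociationTable,
    DiseaseHierarchy,
    ValidationError,
)
from .io import build_adjacency

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "generate_hierarchy",
    "generate_associations",
    "default_benchmark",
    "null_benchmark",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator configuration.

    ``n_blocks`` latent communities shared by diseases and miRNAs;
    ``within_block_prob`` must exceed ``background_prob`` for a detectable
    planted signal.  ``hierarchy_depth``/``branching`` shape the per-block
    disease trees.  ``mask_fraction`` of the planted truth is withheld.
    When ``allow_empty_profiles`` is False, draws leaving a disease or miRNA
    with zero observed associations are resampled (bounded retries).
    """

    nd: int = 30
    nm: int = 40
    n_blocks: int = 3
    within_block_prob: float = 0.35
    background_prob: float = 0.02
    hierarchy_depth: int = 3
    branching: int = 3
    mask_fraction: float = 0.2
    seed: int = 0
    allow_empty_profiles: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.background_prob < self.within_block_prob <= 1):
            raise ValidationError(
                "need 0 <= background_prob < within_block_prob <= 1"
            )
        if self.nd < self.n_blocks or self.nm < self.n_blocks:
            raise ValidationError("nd and nm must be >= n_blocks")
        if not 0 <= self.mask_fraction < 1:
            raise ValidationError("mask_fraction must be in [0, 1)")
        if self.hierarchy_depth < 1 or self.branching < 1:
            raise ValidationError("hierarchy_depth and branching must be >= 1")


@dataclass(frozen=True)
class SyntheticDataset:
    """Observed data plus the planted ground truth.

    ``observed = truth - masked`` and ``masked`` is disjoint from the
    observed pairs.  Block assignments are kept for diagnostics.
    """

    spec: SyntheticSpec
    diseases: tuple[str, ...]
    mirnas: tuple[str, ...]
    associations: AssociationTable
    hierarchy: DiseaseHierarchy
    truth: AssociationTable
    masked: AssociationTable
    disease_blocks: tuple[int, ...]
    mirna_blocks: tuple[int, ...]

    def to_adjacency(self) -> AdjacencyMatrix:
        """Observed adjacency over the full id lists (diseases or miRNAs
        with no observed association keep their all-zero profile)."""
        return build_adjacency(self.associations, self.diseases, self.mirnas)


def _balanced_blocks(n: int, n_blocks: int, rng: np.random.Generator) -> np.ndarray:
    blocks = np.empty(n, dtype=int)
    order = rng.permutation(n)
    for k, idx in enumerate(order):
        blocks[idx] = k % n_blocks
    return blocks


def generate_hierarchy(
    spec: SyntheticSpec,
    disease_ids: tuple[str, ...] | None = None,
    disease_blocks: np.ndarray | None = None,
) -> DiseaseHierarchy:
    """Rooted forest over the diseases, one tree per block.

    Within a block the diseases fill a ``branching``-ary tree level by
    level down to ``hierarchy_depth``; overflow attaches to the least-loaded
    node.  Diseases of the same block thus share ancestors, making DAG
    semantic similarity informative about the planted blocks.
    """
    rng = np.random.default_rng(spec.seed)
    if disease_ids is None:
        disease_ids = tuple(f"d{i:03d}" for i in range(spec.nd))
    if disease_blocks is None:
        disease_blocks = _balanced_blocks(spec.nd, spec.n_blocks, rng)
    edges: list[tuple[str, str]] = []
    for b in range(spec.n_blocks):
        members = [disease_ids[i] for i in range(len(disease_ids))
                   if disease_blocks[i] == b]
        depth = {members[0]: 0} if members else {}
        children: dict[str, int] = {m: 0 for m in members}
        for node in members[1:]:
            eligible = [
                m for m in depth
                if depth[m] < spec.hierarchy_depth and children[m] < spec.branching
            ]
            if eligible:
                parent = min(eligible, key=lambda m: (depth[m], members.index(m)))
            else:  # capacity exhausted: least-loaded placed node
                parent = min(depth, key=lambda m: (children[m], members.index(m)))
            edges.append((node, parent))
            depth[node] = depth[parent] + 1
            children[parent] += 1
    return DiseaseHierarchy.from_edges(edges, extra_nodes=disease_ids)


def _pairs_from_matrix(
    m: np.ndarray, diseases: tuple[str, ...], mirnas: tuple[str, ...]
) -> AssociationTable:
    rows, cols = np.nonzero(m)
    return AssociationTable(
        tuple((diseases[i], mirnas[j]) for i, j in zip(rows, cols))
    )


def generate_associations(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a planted dataset: blocks, hierarchy, truth, held-out mask."""
    for attempt in range(50):
        seed = spec.seed if attempt == 0 else spec.seed + 1_000_003 * attempt
        rng = np.random.default_rng(seed)
        diseases = tuple(f"d{i:03d}" for i in range(spec.nd))
        mirnas = tuple(f"m{j:03d}" for j in range(spec.nm))
        d_blocks = _balanced_blocks(spec.nd, spec.n_blocks, rng)
        m_blocks = _balanced_blocks(spec.nm, spec.n_blocks, rng)
        match = d_blocks[:, None] == m_blocks[None, :]
        probs = np.where(match, spec.within_block_prob, spec.background_prob)
        truth_m = (rng.random((spec.nd, spec.nm)) < probs).astype(float)
        flat = np.flatnonzero(truth_m)
        n_mask = int(np.floor(spec.mask_fraction * flat.size))
        masked_idx = rng.choice(flat, size=n_mask, replace=False) if n_mask else []
        observed_m = truth_m.copy()
        observed_m.flat[masked_idx] = 0.0
        if not spec.allow_empty_profiles and (
            (observed_m.sum(axis=1) == 0).any()
            or (observed_m.sum(axis=0) == 0).any()
        ):
            continue
        hierarchy = generate_hierarchy(spec, diseases, d_blocks)
        masked_m = truth_m - observed_m
        return SyntheticDataset(
            spec=spec,
            diseases=diseases,
            mirnas=mirnas,
            associations=_pairs_from_matrix(observed_m, diseases, mirnas),
            hierarchy=hierarchy,
            truth=_pairs_from_matrix(truth_m, diseases, mirnas),
            masked=_pairs_from_matrix(masked_m, diseases, mirnas),
            disease_blocks=tuple(d_blocks.tolist()),
            mirna_blocks=tuple(m_blocks.tolist()),
        )
    raise ValidationError(
        "could not draw a dataset without empty profiles in 50 attempts"
    )


def default_benchmark(seed: int = 1) -> SyntheticDataset:
    """The frozen benchmark configuration: 30 diseases x 40 miRNAs, 3
    blocks, within/background probabilities 0.35/0.02, depth-3 branching-3
    hierarchy, 20% of the truth masked."""
    return generate_associations(
        SyntheticSpec(
            nd=30,
            nm=40,
            n_blocks=3,
            within_block_prob=0.35,
            background_prob=0.02,
            hierarchy_depth=3,
            branching=3,
            mask_fraction=0.2,
            seed=seed,
        )
    )


def null_benchmark(seed: int = 1) -> SyntheticDataset:
    """Structure-free null: same hierarchy and observed-association count as
    :func:`default_benchmark`, but the observed pairs are re-drawn uniformly
    at random (no planted blocks; truth = observed, nothing masked)."""
    base = default_benchmark(seed)
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x6E756C])  # sub-stream for the null draw
    n_obs = len(base.associations)
    flat = rng.choice(base.spec.nd * base.spec.nm, size=n_obs, replace=False)
    m = np.zeros((base.spec.nd, base.spec.nm))
    m.flat[flat] = 1.0
    observed = _pairs_from_matrix(m, base.diseases, base.mirnas)
    return replace(
        base,
        associations=observed,
        truth=observed,
        masked=AssociationTable(()),
    )
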