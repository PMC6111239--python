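"""Ranking-based cross-validation of the association predictor.

Protocols:

* **global LOOCV** — each known association is removed in turn, the pipeline
  is re-run, and the held-out pair's score is ranked against all pairs with
  no verified association;
* **local LOOCV** — as global, but the candidate pool is restricted to the
  held-out pair's own disease;
* **repeated k-fold** — the known associations are shuffled and split into k
  near-equal parts, each part masked in turn; repeated with fresh shuffles
  and summarized as mean +/- std of the per-repeat AUC.

Each test sample is converted to its percentile within its fold's candidate
pool (midrank ties); the pooled AUC is the mean percentile, and the ROC
curve is swept over a shared percentile threshold grid.  Pools never contain
the test pair itself nor any training positive.

By default every adjacency-dependent quantity (Gaussian kernels, internally
computed functional similarity, integrated similarities, SymNMF) is
recomputed with the test associations removed in each fold (leakage-free);
``refresh_kernels=False`` / ``refresh_symnmf=False`` freeze those stages at
their full-data values, the cheaper protocol common in this literature.
Semantic similarity never depends on the adjacency values and is always
computed once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.base import clone
from sklearn.metrics import roc_curve

from .datatypes import (
    AdjacencyMatrix,
    DiseaseHierarchy,
    ScoreMatrix,
    SimilarityMatrix,
    ValidationError,
)
from .kronrls import KronRLSParams, kronrls_solve
from .pipeline import AssociationPredictor, compute_similarities
from .similarity import disease_semantic_similarity
from .symnmf import symnmf_interpolate

__all__ = ["CVConfig", "RankingResult", "roc_auc", "global_loocv",
           "local_loocv", "kfold_cv"]


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation protocol configuration."""

    mode: str = "global_loocv"
    folds: int = 5
    repeats: int = 100
    seed: int = 0
    refresh_kernels: bool = True
    refresh_symnmf: bool = True

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValidationError("folds must be >= 2")
        if self.repeats < 1:
            raise ValidationError("repeats must be >= 1")


@dataclass(frozen=True)
class RankingResult:
    """Per-test-sample records plus summary AUC and ROC curve."""

    records: tuple[dict, ...]
    auc: float
    auc_std: float | None
    roc_points: tuple[tuple[float, float], ...]


def roc_auc(positive: Sequence[float], negative: Sequence[float]) -> RankingResult:
    """AUC of positive vs negative scores by the rank (Mann-Whitney)
    statistic, ties counted 1/2; ROC points by threshold sweep."""
    pos = np.asarray(positive, dtype=float)
    neg = np.asarray(negative, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    auc = (ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2) / (
        pos.size * neg.size
    )
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    fpr, tpr, _ = roc_curve(labels, np.concatenate([pos, neg]),
                            drop_intermediate=False)
    points = [(float(f), float(t)) for f, t in zip(fpr, tpr)]
    if points[0] != (0.0, 0.0):
        points.insert(0, (0.0, 0.0))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    records = tuple(
        {"score": float(s), "label": int(l)}
        for s, l in zip(np.concatenate([pos, neg]), labels)
    )
    return RankingResult(records, float(auc), None, tuple(points))


def _percentile(score: float, pool: np.ndarray) -> float:
    """Fraction of the pool strictly below ``score``, ties counted 1/2."""
    if pool.size == 0:
        raise ValidationError("empty candidate pool")
    return float(
        ((pool < score).sum() + 0.5 * (pool == score).sum()) / pool.size
    )


def _roc_from_percentiles(p: np.ndarray) -> tuple[tuple[float, float], ...]:
    """ROC curve over a shared percentile threshold grid: at threshold t the
    expected pool FPR is 1 - t and the TPR is the fraction of test samples
    at or above t."""
    thresholds = np.unique(np.concatenate([[0.0, 1.0], p]))[::-1]
    points = [(0.0, 0.0)]
    for t in thresholds:
        points.append((float(1.0 - t), float((p >= t).mean())))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return tuple(points)


class _FoldScorer:
    """Re-scores the network with a set of positives masked, honoring the
    refresh flags.  Semantic similarity is computed once up front."""

    def __init__(
        self,
        adjacency: AdjacencyMatrix,
        hierarchy: DiseaseHierarchy | None,
        functional_sim: SimilarityMatrix | None,
        config: CVConfig,
        model: AssociationPredictor,
    ) -> None:
        self.adjacency = adjacency
        self.hierarchy = hierarchy
        self.functional_sim = functional_sim
        self.config = config
        self.model = model
        self.semantic_sim = None
        if hierarchy is not None:
            _, _, self.semantic_sim = disease_semantic_similarity(
                hierarchy, adjacency.diseases, model._semantic_params()
            )
        # full-data stages, reused when the refresh flags are off
        self._full_sims = compute_similarities(
            adjacency,
            functional_sim=functional_sim,
            kernel=model._kernel_params(),
            semantic_sim=self.semantic_sim,
        )
        self._full_stars = self._interpolate(self._full_sims)

    def _interpolate(self, sims):
        if not self.model.interpolate:
            return sims.sd, sims.sm
        p = self.model._symnmf_params()
        return (
            symnmf_interpolate(sims.sd, p).interpolated,
            symnmf_interpolate(sims.sm, p).interpolated,
        )

    def score(self, masked_pairs: Sequence[tuple[int, int]]) -> np.ndarray:
        """Score matrix with the given (row, col) positives set to 0."""
        v = self.adjacency.values.copy()
        for i, j in masked_pairs:
            v[i, j] = 0.0
        fold_adj = AdjacencyMatrix(self.adjacency.diseases,
                                   self.adjacency.mirnas, v)
        if self.config.refresh_kernels:
            sims = compute_similarities(
                fold_adj,
                functional_sim=self.functional_sim,
                kernel=self.model._kernel_params(),
                semantic_sim=self.semantic_sim,
            )
        else:
            sims = self._full_sims
        if self.config.refresh_symnmf:
            sd_star, sm_star = self._interpolate(sims)
        else:
            sd_star, sm_star = self._full_stars
        scores = kronrls_solve(
            sd_star,
            sm_star,
            fold_adj,
            KronRLSParams(lam=self.model.lam),
            clip_negative=self.model.interpolate,
        )
        return scores.values


def _pool_mask(adjacency: AdjacencyMatrix) -> np.ndarray:
    """Unverified pairs of the full data: candidates in every fold."""
    return adjacency.values == 0


def _run_folds(
    scorer: _FoldScorer,
    folds: Sequence[Sequence[tuple[int, int]]],
    local: bool,
) -> list[dict]:
    adjacency = scorer.adjacency
    unknown = _pool_mask(adjacency)
    records: list[dict] = []
    for fold in folds:
        s = scorer.score(fold)
        for i, j in fold:
            if local:
                pool = s[i, unknown[i, :]]
            else:
                pool = s[unknown]
            p = _percentile(s[i, j], pool)
            records.append(
                {
                    "disease": adjacency.diseases[i],
                    "mirna": adjacency.mirnas[j],
                    "score": float(s[i, j]),
                    "percentile": p,
                    "rank": int(round((1.0 - p) * pool.size)) + 1,
                    "pool_size": int(pool.size),
                }
            )
    return records


def _positives(adjacency: AdjacencyMatrix) -> list[tuple[int, int]]:
    rows, cols = np.nonzero(adjacency.values)
    return list(zip(rows.tolist(), cols.tolist()))


def _loocv(
    adjacency: AdjacencyMatrix,
    hierarchy: DiseaseHierarchy | None,
    functional_sim: SimilarityMatrix | None,
    config: CVConfig,
    model: AssociationPredictor | None,
    local: bool,
) -> RankingResult:
    model = clone(model) if model is not None else AssociationPredictor()
    positives = _positives(adjacency)
    if len(positives) < 2:
        raise ValidationError("LOOCV requires at least 2 known associations")
    scorer = _FoldScorer(adjacency, hierarchy, functional_sim, config, model)
    records = _run_folds(scorer, [[p] for p in positives], local)
    p = np.array([r["percentile"] for r in records])
    # summation over sorted percentiles keeps the AUC independent of fold
    # enumeration order down to the last bit
    return RankingResult(tuple(records), float(np.sort(p).mean()), None,
                         _roc_from_percentiles(p))


def global_loocv(
    adjacency: AdjacencyMatrix,
    hierarchy: DiseaseHierarchy | None = None,
    functional_sim: SimilarityMatrix | None = None,
    config: CVConfig = CVConfig(mode="global_loocv"),
    model: AssociationPredictor | None = None,
) -> RankingResult:
    """Leave-one-association-out, ranking against all unverified pairs."""
    return _loocv(adjacency, hierarchy, functional_sim, config, model,
                  local=False)


def local_loocv(
    adjacency: AdjacencyMatrix,
    hierarchy: DiseaseHierarchy | None = None,
    functional_sim: SimilarityMatrix | None = None,
    config: CVConfig = CVConfig(mode="local_loocv"),
    model: AssociationPredictor | None = None,
) -> RankingResult:
    """Leave-one-association-out, ranking within the studied disease only."""
    return _loocv(adjacency, hierarchy, functional_sim, config, model,
                  local=True)


def kfold_cv(
    adjacency: AdjacencyMatrix,
    hierarchy: DiseaseHierarchy | None = None,
    functional_sim: SimilarityMatrix | None = None,
    config: CVConfig = CVConfig(mode="kfold"),
    model: AssociationPredictor | None = None,
) -> RankingResult:
    """Repeated k-fold CV over the known associations.

    Per repeat r the positives are shuffled with seed ``config.seed + r``
    and split into ``config.folds`` near-equal parts (sizes differing by at
    most 1); the per-repeat AUC follows the global ranking rule.  Returns
    the pooled records with mean and standard deviation of the per-repeat
    AUCs.
    """
    model = clone(model) if model is not None else AssociationPredictor()
    positives = _positives(adjacency)
    if len(positives) < config.folds:
        raise ValidationError("k-fold CV requires at least `folds` positives")
    scorer = _FoldScorer(adjacency, hierarchy, None if functional_sim is None
                         else functional_sim, config, model)
    aucs: list[float] = []
    all_records: list[dict] = []
    all_p: list[np.ndarray] = []
    for r in range(config.repeats):
        rng = np.random.default_rng(config.seed + r)
        order = rng.permutation(len(positives))
        folds = [
            [positives[k] for k in part]
            for part in np.array_split(order, config.folds)
        ]
        records = _run_folds(scorer, folds, local=False)
        p = np.array([rec["percentile"] for rec in records])
        aucs.append(float(np.sort(p).mean()))
        all_records.extend(records)
        all_p.append(p)
    p_all = np.concatenate(all_p)
    return RankingResult(
        tuple(all_records),
        float(np.mean(aucs)),
        float(np.std(aucs)),
        _roc_from_percentiles(p_all),
    )
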