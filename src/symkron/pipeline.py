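"""The full prediction pipeline as a fit/predict estimator.

Chain: adjacency A -> (SS, KD, KM, FS) -> integrated (SD, SM) -> SymNMF
interpolation -> (SD*, SM*) -> KronRLS -> score matrix S.  Everything is
deterministic given the random seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .datatypes import (
    AdjacencyMatrix,
    AssociationTable,
    DiseaseHierarchy,
    ScoreMatrix,
    SimilarityMatrix,
    ValidationError,
)
from .io import build_adjacency
from .kronrls import KronRLSParams, kronrls_solve
from .similarity import (
    KernelParams,
    SemanticParams,
    disease_semantic_similarity,
    gaussian_kernel,
    integrate,
    mirna_functional_similarity,
)
from .symnmf import SymNMFParams, symnmf_interpolate

__all__ = [
    "SimilarityBundle",
    "compute_similarities",
    "AssociationPredictor",
    "predict_scores",
    "predict_new_disease",
]


@dataclass(frozen=True)
class SimilarityBundle:
    """All similarity matrices derived from one adjacency."""

    ss1: SimilarityMatrix | None
    ss2: SimilarityMatrix | None
    ss: SimilarityMatrix
    fs: SimilarityMatrix
    kd: SimilarityMatrix
    km: SimilarityMatrix
    sd: SimilarityMatrix
    sm: SimilarityMatrix


def compute_similarities(
    adjacency: AdjacencyMatrix,
    hierarchy: DiseaseHierarchy | None = None,
    functional_sim: SimilarityMatrix | None = None,
    semantic: SemanticParams = SemanticParams(),
    kernel: KernelParams = KernelParams(),
    semantic_sim: SimilarityMatrix | None = None,
) -> SimilarityBundle:
    """Compute every similarity matrix the predictor consumes.

    ``semantic_sim`` short-circuits the hierarchy computation (useful when
    SS is precomputed — it does not depend on the adjacency values, only on
    the disease list).  A supplied ``functional_sim`` takes precedence over
    the internally computed group-max functional similarity.
    """
    ss1 = ss2 = None
    if semantic_sim is not None:
        ss = semantic_sim.reindex(adjacency.diseases)
    elif hierarchy is not None:
        ss1, ss2, ss = disease_semantic_similarity(
            hierarchy, adjacency.diseases, semantic
        )
    else:
        # no hierarchy: semantic similarity degenerates to the identity
        ss = SimilarityMatrix(
            adjacency.diseases, np.eye(len(adjacency.diseases)), "SS"
        )
    kd = gaussian_kernel(adjacency, "disease", kernel)
    km = gaussian_kernel(adjacency, "mirna", kernel)
    if functional_sim is not None:
        fs = functional_sim.reindex(adjacency.mirnas)
    else:
        fs = mirna_functional_similarity(adjacency, ss)
    sd = integrate(ss, kd, "SD")
    sm = integrate(fs, km, "SM")
    return SimilarityBundle(ss1=ss1, ss2=ss2, ss=ss, fs=fs, kd=kd, km=km,
                            sd=sd, sm=sm)


class AssociationPredictor(BaseEstimator):
    """Disease-miRNA association scoring by SymNMF-interpolated KronRLS.

    Parameters
    ----------
    delta : float
        Semantic contribution factor of disease similarity model 1.
    log_base : float or None
        Logarithm base of similarity model 2 (None: natural log).
    gamma_prime_d, gamma_prime_m : float
        Gaussian interaction-profile kernel bandwidth scales.
    alpha : float
        SymNMF damping factor.
    rank : int or None
        SymNMF factor rank; None means full rank.
    max_iter, tol : SymNMF stopping rule.
    lam : float
        KronRLS regularization.
    interpolate : bool
        When False the raw integrated similarities feed KronRLS directly
        (negative kernel eigenvalues are then used as-is, with a warning).
    random_state : int
        Seed of the SymNMF initialization.

    Fitted attributes: ``similarity_`` (bundle of SS/FS/KD/KM/SD/SM),
    ``sd_star_``/``sm_star_`` (interpolated kernels), ``symnmf_disease_``/
    ``symnmf_mirna_`` (factorization results) and ``scores_``.
    """

    def __init__(
        self,
        delta: float = 0.5,
        log_base: float | None = None,
        gamma_prime_d: float = 1.0,
        gamma_prime_m: float = 1.0,
        alpha: float = 0.999,
        rank: int | None = None,
        max_iter: int = 500,
        tol: float = 1e-6,
        lam: float = 1.0,
        interpolate: bool = True,
        random_state: int = 0,
    ) -> None:
        self.delta = delta
        self.log_base = log_base
        self.gamma_prime_d = gamma_prime_d
        self.gamma_prime_m = gamma_prime_m
        self.alpha = alpha
        self.rank = rank
        self.max_iter = max_iter
        self.tol = tol
        self.lam = lam
        self.interpolate = interpolate
        self.random_state = random_state

    # -- internal parameter bundles -------------------------------------
    def _semantic_params(self) -> SemanticParams:
        return SemanticParams(delta=self.delta, log_base=self.log_base)

    def _kernel_params(self) -> KernelParams:
        return KernelParams(
            gamma_prime_d=self.gamma_prime_d, gamma_prime_m=self.gamma_prime_m
        )

    def _symnmf_params(self) -> SymNMFParams:
        return SymNMFParams(
            alpha=self.alpha,
            rank=self.rank,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=self.random_state,
        )

    def fit(
        self,
        adjacency: AdjacencyMatrix,
        hierarchy: DiseaseHierarchy | None = None,
        functional_sim: SimilarityMatrix | None = None,
        semantic_sim: SimilarityMatrix | None = None,
    ) -> "AssociationPredictor":
        """Run the full chain on an adjacency matrix and its side data."""
        sims = compute_similarities(
            adjacency,
            hierarchy=hierarchy,
            functional_sim=functional_sim,
            semantic=self._semantic_params(),
            kernel=self._kernel_params(),
            semantic_sim=semantic_sim,
        )
        self.similarity_ = sims
        if self.interpolate:
            self.symnmf_disease_ = symnmf_interpolate(sims.sd, self._symnmf_params())
            self.symnmf_mirna_ = symnmf_interpolate(sims.sm, self._symnmf_params())
            self.sd_star_ = self.symnmf_disease_.interpolated
            self.sm_star_ = self.symnmf_mirna_.interpolated
            clip = True
        else:
            self.symnmf_disease_ = self.symnmf_mirna_ = None
            self.sd_star_, self.sm_star_ = sims.sd, sims.sm
            clip = False
        self.scores_ = kronrls_solve(
            self.sd_star_,
            self.sm_star_,
            adjacency,
            KronRLSParams(lam=self.lam),
            clip_negative=clip,
        )
        return self

    def predict(self) -> ScoreMatrix:
        if not hasattr(self, "scores_"):
            raise ValidationError("AssociationPredictor is not fitted yet")
        return self.scores_

    def rank_mirnas(self, disease: str) -> list[tuple[str, float]]:
        """All miRNAs for ``disease``, sorted by descending fitted score."""
        s = self.predict()
        i = s.diseases.index(disease) if disease in s.diseases else -1
        if i < 0:
            raise KeyError(f"unknown disease id: {disease!r}")
        order = np.argsort(-s.values[i], kind="stable")
        return [(s.mirnas[j], float(s.values[i, j])) for j in order]


def predict_scores(
    associations: AssociationTable,
    hierarchy: DiseaseHierarchy | None = None,
    functional_sim: SimilarityMatrix | None = None,
    diseases=None,
    mirnas=None,
    **params,
) -> ScoreMatrix:
    """Functional wrapper: association table -> fitted score matrix."""
    adjacency = build_adjacency(associations, diseases, mirnas)
    model = AssociationPredictor(**params)
    model.fit(adjacency, hierarchy=hierarchy, functional_sim=functional_sim)
    return model.predict()


def predict_new_disease(
    associations: AssociationTable,
    hierarchy: DiseaseHierarchy | None,
    functional_sim: SimilarityMatrix | None,
    disease: str,
    diseases=None,
    mirnas=None,
    **params,
) -> list[tuple[str, float]]:
    """Rank miRNAs for a disease treated as new (no known associations).

    The disease's row of the adjacency is zeroed and every quantity that
    depends on the adjacency (kernels, internally computed functional
    similarity, SymNMF, KronRLS) is recomputed before ranking.
    """
    adjacency = build_adjacency(associations, diseases, mirnas)
    if disease not in adjacency.diseases:
        raise KeyError(f"unknown disease id: {disease!r}")
    masked = adjacency.zero_disease_row(disease)
    model = AssociationPredictor(**params)
    model.fit(masked, hierarchy=hierarchy, functional_sim=functional_sim)
    return model.rank_mirnas(disease)
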