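"""Kronecker regularized least squares (KronRLS) over disease/miRNA kernels.

The pairwise kernel over disease-miRNA pairs is the Kronecker product of a
disease kernel SD* and a miRNA kernel SM*; kernel ridge regression on the
vectorized adjacency,

    vec(S) = K (K + lambda I)^(-1) vec(A),    K = SD* (x) SM*,

is solved in closed form through the two side eigendecompositions
``SD* = Vd Ld Vd^T`` and ``SM* = Vm Lm Vm^T``: with ``C = Vm^T A^T Vd`` and
the shrinkage table ``W[i, j] = lm_i ld_j / (lm_i ld_j + lambda)``,

    S = Vd (W * C)^T Vm^T.

The Kronecker kernel itself (size nd*nm x nd*nm) is never materialized; a
direct dense solver is provided as a small-problem test oracle only.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator

from .datatypes import (
    AdjacencyMatrix,
    ScoreMatrix,
    SimilarityMatrix,
    ValidationError,
)

__all__ = [
    "KronRLSParams",
    "eigendecompose_sym",
    "kronrls_solve",
    "kronrls_direct",
    "KronRLS",
]

from dataclasses import dataclass


@dataclass(frozen=True)
class KronRLSParams:
    """Regularization strength lambda of the ridge problem; default 1."""

    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValidationError(f"lam must be > 0, got {self.lam}")


def eigendecompose_sym(
    m: SimilarityMatrix | np.ndarray, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a symmetric matrix, eigenvalues descending.

    Returns (V, w) with columns of V the eigenvectors and ``m = V diag(w)
    V.T`` up to rounding.  Raises on asymmetry beyond ``tol``.
    """
    v = m.values if isinstance(m, SimilarityMatrix) else np.asarray(m, dtype=float)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValidationError("eigendecomposition requires a square matrix")
    if v.size and np.abs(v - v.T).max() > tol:
        raise ValidationError(f"matrix asymmetric beyond {tol:g}")
    w, vec = scipy.linalg.eigh((v + v.T) / 2.0)
    order = np.argsort(w)[::-1]
    return vec[:, order], w[order]


def _check_labels(
    sd_star: SimilarityMatrix, sm_star: SimilarityMatrix, a: AdjacencyMatrix
) -> None:
    if sd_star.ids != a.diseases:
        raise KeyError("disease kernel ids do not match adjacency diseases")
    if sm_star.ids != a.mirnas:
        raise KeyError("miRNA kernel ids do not match adjacency miRNAs")


def kronrls_solve(
    sd_star: SimilarityMatrix,
    sm_star: SimilarityMatrix,
    a: AdjacencyMatrix,
    params: KronRLSParams = KronRLSParams(),
    clip_negative: bool = True,
) -> ScoreMatrix:
    """Closed-form KronRLS scores through the side eigendecompositions.

    ``clip_negative`` floors the side-kernel eigenvalues at 0 (SymNMF output
    is positive semidefinite up to rounding); pass ``False`` to use an
    indefinite kernel as-is, in which case negative Kronecker eigenvalues
    are used unchanged and a warning is emitted.
    """
    _check_labels(sd_star, sm_star, a)
    vd, wd = eigendecompose_sym(sd_star)
    vm, wm = eigendecompose_sym(sm_star)
    if clip_negative:
        wd = np.maximum(wd, 0.0)
        wm = np.maximum(wm, 0.0)
    elif (wd < 0).any() or (wm < 0).any():
        warnings.warn(
            "indefinite side kernel: negative Kronecker eigenvalues used as-is",
            RuntimeWarning,
            stacklevel=2,
        )
    c = vm.T @ a.values.T @ vd                      # nm x nd
    kron_eig = wm[:, None] * wd[None, :]            # lm_i * ld_j table
    shrink = kron_eig / (kron_eig + params.lam)
    z = shrink * c
    s = vd @ z.T @ vm.T                             # nd x nm
    return ScoreMatrix(a.diseases, a.mirnas, s)


def kronrls_direct(
    sd_star: SimilarityMatrix,
    sm_star: SimilarityMatrix,
    a: AdjacencyMatrix,
    params: KronRLSParams = KronRLSParams(),
    max_pairs: int = 2000,
) -> ScoreMatrix:
    """Dense reference solver: materializes K = SD* (x) SM* and solves
    ``(K + lambda I) x = vec(A)`` directly.  Test oracle for small problems
    (``nd * nm <= max_pairs``)."""
    _check_labels(sd_star, sm_star, a)
    nd, nm = a.shape
    if nd * nm > max_pairs:
        raise ValidationError(
            f"direct solver limited to {max_pairs} pairs, got {nd * nm}"
        )
    k = np.kron(sd_star.values, sm_star.values)
    # K acts on the column-stacked nm x nd matrix A^T; vec(A^T) == A.ravel()
    y = a.values.ravel()
    x = np.linalg.solve(k + params.lam * np.eye(nd * nm), y)
    s = (k @ x).reshape(nd, nm)
    return ScoreMatrix(a.diseases, a.mirnas, s)


class KronRLS(BaseEstimator):
    """Kronecker kernel ridge regression as an estimator.

    ``fit(adjacency, sd_star, sm_star)`` solves the pairwise ridge problem;
    ``predict()`` returns the fitted :class:`ScoreMatrix`.

    Parameters
    ----------
    lam : float
        Regularization strength (> 0), default 1.
    clip_negative : bool
        Clip negative side-kernel eigenvalues at 0 (default True).
    """

    def __init__(self, lam: float = 1.0, clip_negative: bool = True) -> None:
        self.lam = lam
        self.clip_negative = clip_negative

    def fit(
        self,
        adjacency: AdjacencyMatrix,
        sd_star: SimilarityMatrix,
        sm_star: SimilarityMatrix,
    ) -> "KronRLS":
        self.scores_ = kronrls_solve(
            sd_star,
            sm_star,
            adjacency,
            KronRLSParams(lam=self.lam),
            clip_negative=self.clip_negative,
        )
        return self

    def predict(self) -> ScoreMatrix:
        if not hasattr(self, "scores_"):
            raise ValidationError("KronRLS instance is not fitted yet")
        return self.scores_
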