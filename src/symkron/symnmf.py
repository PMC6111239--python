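"""Symmetric non-negative matrix factorization (SymNMF) interpolation.

An integrated similarity matrix SD is approximated as ``P @ P.T`` with P
entrywise non-negative, by a damped multiplicative update with a cube-root
fallback:

* ratio        ``R = (SD @ P) / (P @ P.T @ P)``   (entrywise division)
* candidate    ``P * (1 - alpha + alpha * R)``    (damping ``alpha`` < 1)
* fallback     ``P * R ** (1/3)``                 (entrywise cube root)

Each iteration keeps the candidate when it lowers the squared Frobenius
residual ``E = ||SD - P P.T||_F^2`` and otherwise takes the fallback, whose
cube-root form is the classical monotone multiplicative update for the
symmetric factorization objective.  The product ``P @ P.T`` — symmetric and
positive semidefinite by construction — replaces SD downstream, which is
what keeps the pairwise Kronecker kernel well-behaved.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import SimilarityMatrix, ValidationError

__all__ = ["SymNMFParams", "SymNMFResult", "SymNMF", "symnmf_step", "symnmf_interpolate"]

_DIV_FLOOR = 1e-12  # denominator floor before entrywise division


@dataclass(frozen=True)
class SymNMFParams:
    """Parameters of the interpolation run.

    alpha
        Damping of the candidate step, in (0, 1) and close to 1; 0.999 by
        default.  As alpha -> 0 the candidate step tends to the identity.
    rank
        Number of columns of P; ``None`` means full rank (square P, the
        default configuration).
    max_iter, tol
        Outer stop: at most ``max_iter`` iterations, or earlier when the
        relative residual change drops below ``tol``.
    seed
        Seed of the positive random initialization.
    """

    alpha: float = 0.999
    rank: int | None = None
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.rank is not None and self.rank < 1:
            raise ValidationError("rank must be a positive integer or None")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValidationError("max_iter must be >= 1 and tol > 0")


@dataclass(frozen=True)
class SymNMFResult:
    """Factor P with its residual trace for one interpolation run.

    ``residual_trace[k]`` is the squared Frobenius residual of the accepted
    iterate at step k (index 0 is the initialization); ``interpolated`` is
    the product ``P @ P.T`` as a labeled similarity matrix.
    """

    factor: np.ndarray
    residual_trace: tuple[float, ...]
    iterations: int
    interpolated: SimilarityMatrix


def symnmf_step(
    sd: np.ndarray, p: np.ndarray, alpha: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One multiplicative update: returns (candidate, fallback, ratio R).

    ``p`` must be entrywise positive; the denominator ``P @ P.T @ P`` is
    floored at 1e-12 before the entrywise division.
    """
    denom = p @ (p.T @ p)
    np.maximum(denom, _DIV_FLOOR, out=denom)
    ratio = (sd @ p) / denom
    candidate = p * (1.0 - alpha + alpha * ratio)
    fallback = p * np.cbrt(ratio)
    return candidate, fallback, ratio


def _residual(sd: np.ndarray, p: np.ndarray) -> float:
    r = sd - p @ p.T
    return float((r * r).sum())


def _row_seed(label: str) -> int:
    return zlib.crc32(label.encode("utf-8"))


def _init_factor(
    sd: np.ndarray, ids: Sequence[str], rank: int, seed: int
) -> np.ndarray:
    """Positive random P0 with entries in (0, sqrt(mean(SD)/rank)].

    Each row's stream is keyed by (seed, crc32(row id)) so that relabeling
    or reordering the input permutes the initialization identically — this
    makes the whole interpolation equivariant under input permutations.
    """
    n = sd.shape[0]
    high = float(np.sqrt(max(sd.mean(), _DIV_FLOOR) / rank))
    p0 = np.empty((n, rank))
    for i in range(n):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, _row_seed(ids[i])])
        p0[i] = high * (1.0 - rng.random(rank))  # uniform on (0, high]
    return p0


def symnmf_interpolate(
    sd: SimilarityMatrix | np.ndarray,
    params: SymNMFParams = SymNMFParams(),
) -> SymNMFResult:
    """Run the damped SymNMF iteration on a symmetric non-negative matrix.

    Deterministic given ``params.seed``.  The returned residual trace is
    non-increasing from its first accepted step onward (the candidate is
    only kept when it lowers the residual; the fallback is the monotone
    multiplicative update).
    """
    if isinstance(sd, SimilarityMatrix):
        ids: tuple[str, ...] = sd.ids
        v = sd.values
        role = sd.role + "*" if sd.role else "interpolated"
    else:
        v = np.asarray(sd, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("input must be a square matrix")
        if np.abs(v - v.T).max() > 1e-8:
            raise ValidationError("input matrix is not symmetric")
        if v.size and v.min() < 0:
            raise ValidationError("input matrix has negative entries")
        ids = tuple(str(i) for i in range(v.shape[0]))
        role = "interpolated"
    n = v.shape[0]
    rank = params.rank if params.rank is not None else n
    p = _init_factor(v, ids, rank, params.seed)
    trace = [_residual(v, p)]
    iterations = 0
    for _ in range(params.max_iter):
        candidate, fallback, _ = symnmf_step(v, p, params.alpha)
        e_candidate = _residual(v, candidate)
        if e_candidate < trace[-1]:
            p, e = candidate, e_candidate
        else:
            p, e = fallback, _residual(v, fallback)
        iterations += 1
        prev = trace[-1]
        trace.append(e)
        if prev == 0.0 or abs(prev - e) / prev < params.tol:
            break
    interpolated = SimilarityMatrix(ids, p @ p.T, role)
    return SymNMFResult(
        factor=p,
        residual_trace=tuple(trace),
        iterations=iterations,
        interpolated=interpolated,
    )


class SymNMF(TransformerMixin, BaseEstimator):
    """Symmetric NMF interpolation as a transformer.

    ``fit(X)`` factorizes the symmetric non-negative matrix X (a labeled
    :class:`SimilarityMatrix` or a plain array); ``transform`` returns the
    interpolated matrix ``P @ P.T``.

    Parameters mirror :class:`SymNMFParams`.  Fitted attributes:

    components_
        The non-negative factor P, shape (n, rank).
    residual_trace_
        Squared Frobenius residuals of the accepted iterates.
    n_iter_
        Iterations performed.
    interpolated_
        The product ``P @ P.T`` as a :class:`SimilarityMatrix`.
    """

    def __init__(
        self,
        alpha: float = 0.999,
        rank: int | None = None,
        max_iter: int = 500,
        tol: float = 1e-6,
        random_state: int = 0,
    ) -> None:
        self.alpha = alpha
        self.rank = rank
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _params(self) -> SymNMFParams:
        return SymNMFParams(
            alpha=self.alpha,
            rank=self.rank,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=self.random_state,
        )

    def fit(self, X, y=None) -> "SymNMF":
        result = symnmf_interpolate(X, self._params())
        self.components_ = result.factor
        self.residual_trace_ = result.residual_trace
        self.n_iter_ = result.iterations
        self.interpolated_ = result.interpolated
        return self

    def transform(self, X):
        if not hasattr(self, "components_"):
            raise ValidationError("SymNMF instance is not fitted yet")
        return self.interpolated_.values

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
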