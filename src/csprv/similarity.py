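"""RV2 matrix correlation, correlation distance, scaled kernel and view fusion.

The modified RV-coefficient (RV2) measures correlation between two matrices
sharing a row count through the off-diagonal parts of their row cross-product
matrices:

    RV2(X, Y) = <vec(XX' - diag), vec(YY' - diag)>
                / sqrt(||vec(XX' - diag)||^2 ||vec(YY' - diag)||^2)

It lies in [-1, 1] and is invariant to rescaling either matrix. Distances are
d = 1 - RV2 in [0, 2]; similarities use the scaled exponential kernel
W = exp(-d^2 / (mu * eps)) where eps is the local three-term mean distance,
removing scale dependence. Gene- and miRNA-view similarity matrices are fused
by a convex combination with weight alpha on the gene view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reduction import SampleFeatureMatrix

#: exponent floor; keeps kernel values strictly positive (no underflow to 0)
_MIN_EXPONENT = -700.0


class DegenerateInputError(ValueError):
    """RV2 is undefined: an off-diagonal cross-product matrix is all zero."""


@dataclass
class DistanceMatrix:
    """Symmetric n x n RV2-correlation distances, zero diagonal, entries in [0, 2]."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        v = self.values
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix diagonal is not zero")
        if v.min(initial=0.0) < -1e-12 or v.max(initial=0.0) > 2 + 1e-12:
            raise ValueError("distances outside [0, 2]")


@dataclass
class SimilarityMatrix:
    """Symmetric n x n similarities in (0, 1] with unit diagonal."""

    values: np.ndarray
    sample_ids: list[str]
    view: str  # "gene" | "mirna" | "combined"

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        v = self.values
        if v.shape != (n, n):
            raise ValueError(f"similarity matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity diagonal must be 1")
        if v.min(initial=1.0) <= 0.0 or v.max(initial=1.0) > 1 + 1e-12:
            raise ValueError("similarities outside (0, 1]")
        if self.view not in ("gene", "mirna", "combined"):
            raise ValueError(f"unknown view {self.view!r}")


def _offdiag_gram_vec(X: np.ndarray) -> np.ndarray:
    g = X @ X.T
    np.fill_diagonal(g, 0.0)
    return g.ravel()


def rv2(X: np.ndarray, Y: np.ndarray) -> float:
    """Modified RV-coefficient between two matrices sharing a row count."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with the same row count")
    if X.shape[0] < 2:
        raise ValueError("RV2 needs at least 2 rows")
    vx = _offdiag_gram_vec(X)
    vy = _offdiag_gram_vec(Y)
    nx = vx @ vx
    ny = vy @ vy
    if nx == 0.0 or ny == 0.0:
        raise DegenerateInputError(
            "off-diagonal cross-product matrix is all zero; RV2 undefined"
        )
    return float(np.clip((vx @ vy) / np.sqrt(nx * ny), -1.0, 1.0))


def pairwise_distance(mats: list[SampleFeatureMatrix]) -> DistanceMatrix:
    """All-pairs RV2 distance d(i, j) = 1 - RV2(X_i, X_j), zero diagonal."""
    if not mats:
        raise ValueError("no sample matrices")
    shape = mats[0].matrix.shape
    if any(m.matrix.shape != shape for m in mats):
        raise ValueError("sample matrices must share a common 4 x d shape")
    vecs = np.stack([_offdiag_gram_vec(m.matrix) for m in mats])
    norms = np.linalg.norm(vecs, axis=1)
    zero = np.nonzero(norms == 0.0)[0]
    if zero.size:
        raise DegenerateInputError(
            f"sample {mats[zero[0]].sample_id!r} has an all-zero off-diagonal "
            "cross-product matrix; RV2 undefined for its pairs"
        )
    rho = (vecs @ vecs.T) / np.outer(norms, norms)
    np.clip(rho, -1.0, 1.0, out=rho)
    d = 1.0 - rho
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, [m.sample_id for m in mats])


def _neighbor_means(D: np.ndarray, K: int | str) -> np.ndarray:
    """mean(d(X_i, N_i)) per sample: K nearest other samples, or all others."""
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    offdiag = D + np.diag(np.full(n, np.inf))
    if K == "all":
        return (D.sum(axis=1)) / (n - 1)
    K = int(K)
    if not 1 <= K <= n - 1:
        raise ValueError(f"K={K} out of range [1, {n - 1}]")
    part = np.partition(offdiag, K - 1, axis=1)[:, :K]
    return part.mean(axis=1)


def epsilon(D: DistanceMatrix, i: int, j: int, K: int | str = "all") -> float:
    """Local scale for pair (i, j): three-term mean of neighbor and pair distances."""
    if i == j:
        raise ValueError("epsilon is defined for distinct samples")
    means = _neighbor_means(D.values, K)
    return float((means[i] + D.values[i, j] + means[j]) / 3.0)


def kernel_similarity(D: DistanceMatrix, mu: float,
                      K: int | str = "all", view: str = "combined") -> SimilarityMatrix:
    """Scaled exponential kernel W(i, j) = exp(-d(i,j)^2 / (mu * eps_ij)).

    The diagonal is set to 1. Identical samples (d = 0) with eps = 0 yield
    W = 1; a positive distance with eps = 0 cannot be scaled and is an error.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    d = D.values
    n = d.shape[0]
    means = _neighbor_means(d, K)
    eps = (means[:, None] + d + means[None, :]) / 3.0
    off = ~np.eye(n, dtype=bool)
    bad = off & (eps == 0.0) & (d > 0.0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"eps = 0 with positive distance for pair ({i}, {j})")
    with np.errstate(divide="ignore", invalid="ignore"):
        expo = np.where((d == 0.0) & (eps == 0.0), 0.0, -(d ** 2) / (mu * eps))
    np.clip(expo, _MIN_EXPONENT, 0.0, out=expo)
    W = np.exp(expo)
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 1.0)
    return SimilarityMatrix(W, list(D.sample_ids), view)


def fuse(Wg: SimilarityMatrix, Wm: SimilarityMatrix, alpha: float) -> SimilarityMatrix:
    """Convex fusion W_c = alpha * W_gene + (1 - alpha) * W_mirna."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if Wg.sample_ids != Wm.sample_ids:
        raise ValueError("sample ids of the two views do not match")
    values = alpha * Wg.values + (1.0 - alpha) * Wm.values
    return SimilarityMatrix(values, list(Wg.sample_ids), "combined")
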