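"""PCA reduction of the feature matrices and per-sample ensemble assembly.

Each of the four feature matrices of a view is reduced to a shared dimension
d chosen as the smallest value at which every matrix exceeds the configured
explained-variance threshold (default 0.9). Samples are the observations and
features the variables, so d is bounded by the sample count. For each sample
the four reduced score rows are stacked into a 4 x d ensemble matrix — the
object whose pairwise RV2 correlations define inter-sample similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .network_features import FeatureMatrixSet

logger = logging.getLogger("csprv")


@dataclass
class ReducedFeatureSet:
    """Four n_samples x d score matrices sharing sample order and dimension."""

    view: str
    sample_ids: list[str]
    scores: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]
    d: int
    ev_rates: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        for s in self.scores:
            if s.shape != (n, self.d):
                raise ValueError(f"score matrix shape {s.shape} != ({n}, {self.d})")


@dataclass
class SampleFeatureMatrix:
    """One sample's 4 x d ensemble matrix, rows ordered (f0, f1, f2, f3)."""

    sample_id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError(f"ensemble matrix must be 4 x d, got {self.matrix.shape}")


def pca_reduce(matrix: np.ndarray, d: int) -> tuple[np.ndarray, float]:
    """Project samples onto the top-d principal components of the feature space.

    ``matrix`` is n_features x n_samples; samples are the observations. Columns
    are mean-centered; no re-scaling (inputs are already z-scores). Returns the
    n_samples x d score matrix and the explained-variance rate of d components.
    Deterministic: full SVD with the largest-magnitude-loading-positive sign
    convention.
    """
    matrix = np.asarray(matrix, dtype=float)
    n_features, n_samples = matrix.shape
    cap = min(n_features, n_samples)
    if not 1 <= d <= cap:
        raise ValueError(f"d={d} out of range [1, {cap}]")
    if not matrix.any():
        raise ValueError("all-zero matrix has no principal components")
    obs = matrix.T  # observations = samples
    pca = PCA(n_components=d, svd_solver="full")
    scores = pca.fit_transform(obs)
    ev_rate = float(pca.explained_variance_ratio_.sum())
    return scores, ev_rate


def _min_components(matrix: np.ndarray, ev_threshold: float) -> int:
    """Smallest component count with explained-variance rate > threshold."""
    obs = np.asarray(matrix, dtype=float).T
    pca = PCA(svd_solver="full")
    pca.fit(obs)
    cum = np.cumsum(pca.explained_variance_ratio_)
    above = np.nonzero(cum > ev_threshold)[0]
    if above.size == 0:  # saturation: even full rank does not exceed
        return min(matrix.shape)
    return int(above[0]) + 1


def choose_common_dimension(fset: FeatureMatrixSet, ev_threshold: float) -> int:
    """Smallest shared d at which all four feature matrices exceed the threshold.

    Equals the max over matrices of the per-matrix minimal component count,
    capped at min(n_samples, n_features).
    """
    if not 0.0 < ev_threshold <= 1.0:
        raise ValueError("ev_threshold must be in (0, 1]")
    shape = fset.f0.shape
    if 0 in shape:
        raise ValueError("empty feature matrices")
    cap = min(shape)
    counts = [_min_components(m, ev_threshold) for m in fset.matrices]
    return min(max(counts), cap)


def reduce_feature_set(fset: FeatureMatrixSet, ev_threshold: float,
                       d: int | None = None) -> ReducedFeatureSet:
    """Reduce all four matrices of a view to a common dimension."""
    if d is None:
        d = choose_common_dimension(fset, ev_threshold)
    scores, rates = [], []
    for m in fset.matrices:
        s, r = pca_reduce(m, d)
        scores.append(s)
        rates.append(r)
    logger.info("%s view: d=%d, explained variance %s", fset.view, d,
                ", ".join(f"{r:.3f}" for r in rates))
    return ReducedFeatureSet(fset.view, list(fset.sample_ids),
                             tuple(scores), d, tuple(rates))


def assemble_sample_matrices(reduced: ReducedFeatureSet) -> list[SampleFeatureMatrix]:
    """Stack, per sample, the four score rows into a 4 x d ensemble matrix."""
    s0, s1, s2, s3 = reduced.scores
    if not (s0.shape == s1.shape == s2.shape == s3.shape):
        raise ValueError("score matrices have inconsistent dimensions")
    return [
        SampleFeatureMatrix(sid, np.vstack([s0[i], s1[i], s2[i], s3[i]]))
        for i, sid in enumerate(reduced.sample_ids)
    ]
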