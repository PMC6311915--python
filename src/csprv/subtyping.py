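"""Spectral clustering of the fused similarity, survival evaluation, alpha
selection and end-to-end pipeline orchestration.

Clustering solves the relaxed normalized-cut problem: the bottom-m
eigenvectors of the normalized Laplacian L = I - D^{-1/2} W D^{-1/2} are
row-normalized and discretized with seeded k-means. Cluster quality is judged
by how well the subtypes separate survival: a multi-group (Mantel-Haenszel)
log-rank test, which coincides with the Cox partial-likelihood score test for
a categorical group factor. The fusion weight alpha is either fixed or chosen
on a grid as the value minimizing the log-rank p-value.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from .io_config import (
    PipelineConfig,
    SurvivalRecord,
    read_clinical_table,
    read_expression_table,
    read_network_table,
    harmonize,
    zscore_standardize,
)
from .network_features import extract_gene_features, extract_mirna_features
from .reduction import assemble_sample_matrices, reduce_feature_set
from .similarity import (
    SimilarityMatrix,
    fuse,
    kernel_similarity,
    pairwise_distance,
)

logger = logging.getLogger("csprv")


@dataclass
class ClusterAssignment:
    """Subtype labels in 1..m for an ordered list of samples."""

    sample_ids: list[str]
    labels: np.ndarray
    m: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.sample_ids),):
            raise ValueError("labels length does not match sample_ids")
        present = set(self.labels.tolist())
        if not present.issubset(range(1, self.m + 1)):
            raise ValueError(f"labels outside 1..{self.m}")
        if present != set(range(1, self.m + 1)):
            raise ValueError("every cluster must be non-empty")


@dataclass
class AlphaSelectionReport:
    """Log-rank p-value per fusion weight and the selected minimizer."""

    grid: list[float]
    p_values: list[float]
    best_alpha: float


def normalized_laplacian(W: np.ndarray) -> np.ndarray:
    """L = I - D^{-1/2} W D^{-1/2} with D the diagonal of row sums."""
    deg = W.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(deg)
    L = -W * np.outer(inv_sqrt, inv_sqrt)
    L[np.diag_indices_from(L)] += 1.0
    return (L + L.T) / 2.0


def spectral_embedding(W: np.ndarray, m: int) -> np.ndarray:
    """Row-normalized bottom-m eigenvectors of the normalized Laplacian."""
    L = normalized_laplacian(W)
    _, vecs = np.linalg.eigh(L)
    U = vecs[:, :m]
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    return U / norms


def spectral_cluster(W: SimilarityMatrix, m: int, seed: int = 0) -> ClusterAssignment:
    """Cluster samples from the fused similarity by normalized spectral clustering.

    Deterministic symmetric eigendecomposition; the seed affects only the
    k-means discretization (10 restarts).
    """
    n = len(W.sample_ids)
    if m < 2:
        raise ValueError("m must be at least 2")
    if m > n:
        raise ValueError(f"m={m} exceeds the sample count {n}")
    A = W.values.copy()
    np.fill_diagonal(A, 0.0)
    n_comp, _ = connected_components(A > 0, directed=False)
    if n_comp > m:
        raise ValueError(
            f"similarity graph has {n_comp} connected components, more than m={m}"
        )
    U = spectral_embedding(W.values, m)
    km = KMeans(n_clusters=m, n_init=10, random_state=seed)
    raw = km.fit_predict(U)
    # canonical label numbering: clusters ordered by first occurrence
    order: dict[int, int] = {}
    for r in raw:
        if r not in order:
            order[r] = len(order) + 1
    labels = np.array([order[r] for r in raw])
    return ClusterAssignment(list(W.sample_ids), labels, m)


def logrank_test(
    assign: ClusterAssignment, surv: list[SurvivalRecord]
) -> tuple[float, float]:
    """Multi-group log-rank test of survival separation across subtypes.

    Samples without a clinical record are dropped with a warning. Returns the
    chi-square statistic (m - 1 degrees of freedom) and its p-value.
    """
    by_id = {r.sample_id: r for r in surv}
    times, events, groups = [], [], []
    dropped = 0
    for sid, lab in zip(assign.sample_ids, assign.labels):
        rec = by_id.get(sid)
        if rec is None:
            dropped += 1
            continue
        if rec.time < 0:
            raise ValueError(f"negative survival time for {sid!r}")
        times.append(rec.time)
        events.append(rec.status)
        groups.append(int(lab))
    if dropped:
        logger.warning("log-rank: ignored %d samples with no clinical record",
                       dropped)
    if len(set(groups)) < 2:
        raise ValueError("fewer than 2 non-empty groups after joining clinical data")
    res = multivariate_logrank_test(np.array(times), np.array(groups),
                                    np.array(events))
    stat = float(max(res.test_statistic, 0.0))
    return stat, float(res.p_value)


def select_alpha(
    Wg: SimilarityMatrix,
    Wm: SimilarityMatrix,
    surv: list[SurvivalRecord],
    m: int,
    grid: tuple[float, ...] | list[float],
    seed: int = 0,
) -> AlphaSelectionReport:
    """Pick the fusion weight minimizing the subtype log-rank p-value.

    Ties break toward the alpha closest to 0.5 (most balanced fusion), then
    the smaller alpha.
    """
    if not grid:
        raise ValueError("alpha grid must be non-empty")
    p_values = []
    for a in grid:
        Wc = fuse(Wg, Wm, a)
        assign = spectral_cluster(Wc, m, seed)
        _, p = logrank_test(assign, surv)
        p_values.append(p)
    best_p = min(p_values)
    ties = [a for a, p in zip(grid, p_values) if p == best_p]
    best_alpha = min(ties, key=lambda a: (abs(a - 0.5), a))
    if len(ties) > 1:
        logger.info("alpha tie among %s broken to %.2f", ties, best_alpha)
    return AlphaSelectionReport(list(grid), p_values, float(best_alpha))


@dataclass
class PipelineResult:
    assignment: ClusterAssignment
    alpha: float
    report: AlphaSelectionReport | None
    Wg: SimilarityMatrix
    Wm: SimilarityMatrix
    Wc: SimilarityMatrix
    logrank_statistic: float | None
    logrank_p: float | None


def run_pipeline(
    config: PipelineConfig,
    gene_expr_path: str | Path,
    mirna_expr_path: str | Path,
    network_path: str | Path,
    clinical_path: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the whole subtyping pipeline from input files to cluster labels.

    Stages: harmonize -> z-score -> network feature extraction (both views)
    -> PCA reduction and ensemble assembly -> RV2 distances -> scaled kernel
    -> fusion (fixed or survival-selected alpha) -> spectral clustering ->
    log-rank evaluation. Fully reproducible given config.seed.
    """
    if config.alpha == "auto" and clinical_path is None:
        raise ValueError("alpha='auto' requires a clinical file to select on")
    gene = read_expression_table(gene_expr_path, "gene")
    mirna = read_expression_table(mirna_expr_path, "mirna")
    net = read_network_table(network_path)
    surv = read_clinical_table(clinical_path) if clinical_path else None

    gene, mirna, net = harmonize(gene, mirna, net)
    gene = zscore_standardize(gene)
    mirna = zscore_standardize(mirna)

    Wg = view_similarity(gene, mirna, net, "gene", config)
    Wm = view_similarity(gene, mirna, net, "mirna", config)

    report = None
    if config.alpha == "auto":
        report = select_alpha(Wg, Wm, surv, config.n_clusters,
                              config.alpha_grid, config.seed)
        alpha = report.best_alpha
    else:
        alpha = float(config.alpha)
    Wc = fuse(Wg, Wm, alpha)
    assign = spectral_cluster(Wc, config.n_clusters, config.seed)

    stat = p = None
    if surv is not None:
        stat, p = logrank_test(assign, surv)
        logger.info("subtype log-rank: chi2=%.4g p=%.4g at alpha=%.2f",
                    stat, p, alpha)

    result = PipelineResult(assign, alpha, report, Wg, Wm, Wc, stat, p)
    if out_dir is not None:
        _write_outputs(result, config, Path(out_dir))
    return result


def view_similarity(gene, mirna, net, view: str,
                    config: PipelineConfig) -> SimilarityMatrix:
    """Feature extraction -> reduction -> RV2 kernel similarity for one view."""
    extract = extract_gene_features if view == "gene" else extract_mirna_features
    fset = extract(gene, mirna, net)
    reduced = reduce_feature_set(fset, config.ev_threshold)
    mats = assemble_sample_matrices(reduced)
    D = pairwise_distance(mats)
    return kernel_similarity(D, config.mu, config.n_neighbors, view)


def _write_similarity(W: SimilarityMatrix, path: Path) -> None:
    pd.DataFrame(W.values, index=W.sample_ids, columns=W.sample_ids).to_csv(
        path, sep="\t", float_format="%.17g", index_label="sample_id")


def _write_outputs(result: PipelineResult, config: PipelineConfig,
                   out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "sample_id": result.assignment.sample_ids,
        "subtype": result.assignment.labels,
    }).to_csv(out_dir / "labels.tsv", sep="\t", index=False)
    _write_similarity(result.Wg, out_dir / "similarity_gene.tsv")
    _write_similarity(result.Wm, out_dir / "similarity_mirna.tsv")
    _write_similarity(result.Wc, out_dir / "similarity_combined.tsv")
    if result.report is not None:
        pd.DataFrame({
            "alpha": result.report.grid,
            "logrank_p": result.report.p_values,
        }).to_csv(out_dir / "alpha_report.tsv", sep="\t", index=False,
                  float_format="%.17g")
    manifest = {
        "config": {**asdict(config), "alpha_grid": list(config.alpha_grid)},
        "alpha_used": result.alpha,
        "logrank_statistic": result.logrank_statistic,
        "logrank_p": result.logrank_p,
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
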