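"""Network-neighborhood expression features (four per gene and per miRNA).

For every gene the features are its own (standardized) expression plus the
mean expression of its regulator mRNAs, regulator TFs and regulator miRNAs.
For every miRNA they are its own expression plus the mean expression of its
target mRNAs, target TFs and regulator TFs. Empty neighborhoods contribute a
feature value of 0, the mean of the z-scored inputs (no information beyond
the prior). TFs live inside the gene expression table but count only toward
the TF-typed neighbor means, never double as mRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_config import ExpressionMatrix, RegulatoryNetwork


@dataclass
class FeatureMatrixSet:
    """The four per-view feature matrices, aligned to the source expression."""

    view: str
    feature_ids: list[str]
    sample_ids: list[str]
    f0: np.ndarray
    f1: np.ndarray
    f2: np.ndarray
    f3: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.feature_ids), len(self.sample_ids))
        for name in ("f0", "f1", "f2", "f3"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} has shape {getattr(self, name).shape}, "
                                 f"expected {shape}")

    @property
    def matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return (self.f0, self.f1, self.f2, self.f3)


def neighbors_by_role(
    net: RegulatoryNetwork, node: str, role: str, type_filter: str
) -> set[str]:
    """Neighbors of ``node`` by regulatory role, restricted to one node type.

    ``regulator`` returns sources of in-edges, ``target`` returns targets of
    out-edges. mRNA-mRNA edges are symmetric, so an mRNA neighbor shows up in
    both roles.
    """
    if node not in net.nodes:
        raise KeyError(f"unknown node {node!r}")
    if role == "regulator":
        pool = net.regulators(node)
    elif role == "target":
        pool = net.targets(node)
    else:
        raise ValueError(f"role must be 'regulator' or 'target', got {role!r}")
    return {n for n in pool if net.nodes[n] == type_filter}


def _mean_rows(expr: ExpressionMatrix, index: dict[str, int],
               ids: set[str]) -> np.ndarray:
    """Mean of the expression rows for ``ids``; zeros when the set is empty."""
    if not ids:
        return np.zeros(expr.n_samples)
    rows = [index[i] for i in sorted(ids)]
    return expr.values[rows].mean(axis=0)


def _check_harmonized(expr: ExpressionMatrix, net: RegulatoryNetwork) -> None:
    missing = [f for f in expr.feature_ids if f not in net.nodes]
    if missing:
        raise ValueError(
            f"{expr.view} expression has {len(missing)} features missing from "
            f"the network (e.g. {missing[0]!r}); harmonize first"
        )
    if not expr.standardized:
        raise ValueError(f"{expr.view} expression must be standardized first")


def extract_gene_features(
    gene_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    net: RegulatoryNetwork,
) -> FeatureMatrixSet:
    """Four feature matrices centered on genes (mRNA and TF rows).

    f0 = own expression; f1/f2/f3 = per-sample mean expression of the gene's
    regulator mRNAs / TFs / miRNAs as resolved by the typed in-edges.
    """
    _check_harmonized(gene_expr, net)
    _check_harmonized(mirna_expr, net)
    gidx = {f: i for i, f in enumerate(gene_expr.feature_ids)}
    midx = {f: i for i, f in enumerate(mirna_expr.feature_ids)}
    n_f, n_s = gene_expr.n_features, gene_expr.n_samples
    f1 = np.zeros((n_f, n_s))
    f2 = np.zeros((n_f, n_s))
    f3 = np.zeros((n_f, n_s))
    for k, gk in enumerate(gene_expr.feature_ids):
        f1[k] = _mean_rows(gene_expr, gidx,
                           neighbors_by_role(net, gk, "regulator", "mRNA"))
        f2[k] = _mean_rows(gene_expr, gidx,
                           neighbors_by_role(net, gk, "regulator", "TF"))
        f3[k] = _mean_rows(mirna_expr, midx,
                           neighbors_by_role(net, gk, "regulator", "miRNA"))
    return FeatureMatrixSet("gene", list(gene_expr.feature_ids),
                            list(gene_expr.sample_ids),
                            gene_expr.values.copy(), f1, f2, f3)


def extract_mirna_features(
    gene_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    net: RegulatoryNetwork,
) -> FeatureMatrixSet:
    """Four feature matrices centered on miRNAs.

    f0 = own expression; f1 = mean over target mRNAs; f2 = mean over target
    TFs; f3 = mean over regulator TFs (TF->miRNA in-edges).
    """
    _check_harmonized(gene_expr, net)
    _check_harmonized(mirna_expr, net)
    gidx = {f: i for i, f in enumerate(gene_expr.feature_ids)}
    n_f, n_s = mirna_expr.n_features, mirna_expr.n_samples
    f1 = np.zeros((n_f, n_s))
    f2 = np.zeros((n_f, n_s))
    f3 = np.zeros((n_f, n_s))
    for k, mk in enumerate(mirna_expr.feature_ids):
        f1[k] = _mean_rows(gene_expr, gidx,
                           neighbors_by_role(net, mk, "target", "mRNA"))
        f2[k] = _mean_rows(gene_expr, gidx,
                           neighbors_by_role(net, mk, "target", "TF"))
        f3[k] = _mean_rows(gene_expr, gidx,
                           neighbors_by_role(net, mk, "regulator", "TF"))
    return FeatureMatrixSet("mirna", list(mirna_expr.feature_ids),
                            list(mirna_expr.sample_ids),
                            mirna_expr.values.copy(), f1, f2, f3)
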