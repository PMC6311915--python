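"""Input tables, harmonization, standardization and pipeline configuration.

Three tab-delimited inputs drive the pipeline:

* expression tables (rows = features, columns = samples, log2-scale values),
  one for the gene view (mRNA + TF) and one for the miRNA view;
* a typed regulatory-network edge list over mRNA, TF and miRNA nodes;
* a clinical table (sample_id, time_days, status).

Feature and sample universes are harmonized against the network before any
feature extraction: expression rows absent from the network are dropped, and
network nodes without an expression row are removed together with their edges.
Expression is then z-score standardized per feature across samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("csprv")

NODE_TYPES = frozenset({"mRNA", "TF", "miRNA"})

#: permitted (source_type, target_type) pairs and the edge type they imply
EDGE_TYPE_BY_PAIR: Mapping[tuple[str, str], str] = {
    ("mRNA", "mRNA"): "mRNA-mRNA",
    ("TF", "mRNA"): "TF-mRNA",
    ("miRNA", "mRNA"): "miRNA-mRNA",
    ("miRNA", "TF"): "miRNA-TF",
    ("TF", "miRNA"): "TF-miRNA",
}


class LoadError(ValueError):
    """Raised when an input table violates the format contract."""


@dataclass
class ExpressionMatrix:
    """A features x samples real matrix with ordered ids and a view tag."""

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    view: str  # "gene" | "mirna"
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.view not in ("gene", "mirna"):
            raise ValueError(f"unknown view {self.view!r}")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, feature_ids: Iterable[str] | None = None,
               sample_ids: Iterable[str] | None = None) -> "ExpressionMatrix":
        """Restrict to the given features / samples, in the given order."""
        fids = list(feature_ids) if feature_ids is not None else self.feature_ids
        sids = list(sample_ids) if sample_ids is not None else self.sample_ids
        fidx = [self.feature_ids.index(f) for f in fids] \
            if fids is not self.feature_ids else slice(None)
        sidx = [self.sample_ids.index(s) for s in sids] \
            if sids is not self.sample_ids else slice(None)
        vals = self.values[fidx][:, sidx] if not (
            isinstance(fidx, slice) and isinstance(sidx, slice)
        ) else self.values
        return ExpressionMatrix(vals.copy(), list(fids), list(sids),
                                self.view, self.standardized)


@dataclass
class RegulatoryNetwork:
    """Typed nodes and typed directed edges with by-role neighbor lookups.

    mRNA-mRNA associations are undirected and stored symmetrically (both
    directions present). The five permitted edge types are mRNA-mRNA, TF-mRNA,
    miRNA-mRNA, miRNA-TF and TF-miRNA.
    """

    nodes: dict[str, str]
    edges: set[tuple[str, str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for node, ntype in self.nodes.items():
            if ntype not in NODE_TYPES:
                raise ValueError(f"node {node!r} has unknown type {ntype!r}")
        for src, tgt, etype in self.edges:
            if src == tgt:
                raise ValueError(f"self-loop on {src!r}")
            pair = (self.nodes.get(src), self.nodes.get(tgt))
            if None in pair:
                missing = src if pair[0] is None else tgt
                raise ValueError(f"edge endpoint {missing!r} not in nodes")
            if EDGE_TYPE_BY_PAIR.get(pair) != etype:
                raise ValueError(
                    f"edge ({src!r}, {tgt!r}) typed {etype!r} inconsistent with "
                    f"node types {pair}"
                )
        for src, tgt, etype in self.edges:
            if etype == "mRNA-mRNA" and (tgt, src, etype) not in self.edges:
                raise ValueError(
                    f"mRNA-mRNA edge ({src!r}, {tgt!r}) missing its reverse"
                )
        # adjacency caches: in-edges (regulators) and out-edges (targets)
        self._in: dict[str, list[str]] = {n: [] for n in self.nodes}
        self._out: dict[str, list[str]] = {n: [] for n in self.nodes}
        for src, tgt, _ in sorted(self.edges):
            self._out[src].append(tgt)
            self._in[tgt].append(src)

    def regulators(self, node: str) -> list[str]:
        if node not in self.nodes:
            raise KeyError(f"unknown node {node!r}")
        return self._in[node]

    def targets(self, node: str) -> list[str]:
        if node not in self.nodes:
            raise KeyError(f"unknown node {node!r}")
        return self._out[node]

    def subnetwork(self, keep: set[str]) -> "RegulatoryNetwork":
        """Restrict to the given node set, dropping dangling edges."""
        nodes = {n: t for n, t in self.nodes.items() if n in keep}
        edges = {(s, t, e) for s, t, e in self.edges if s in keep and t in keep}
        return RegulatoryNetwork(nodes, edges)


@dataclass(frozen=True)
class SurvivalRecord:
    """One sample's follow-up: time in days and event status (1) / censoring (0)."""

    sample_id: str
    time: float
    status: int

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"negative survival time for {self.sample_id!r}")
        if self.status not in (0, 1):
            raise ValueError(f"status must be 0 or 1, got {self.status!r}")


@dataclass
class PipelineConfig:
    """Tunable parameters of the subtyping pipeline.

    mu is the kernel bandwidth multiplier (recommended range 0.3-0.8,
    default 0.3); alpha the gene-view fusion weight in [0, 1] or "auto" to
    select it on the log-rank survival p-value over alpha_grid; ev_threshold
    the PCA explained-variance level every feature matrix must exceed.
    """

    mu: float = 0.3
    alpha: float | str = "auto"
    n_clusters: int = 3
    ev_threshold: float = 0.9
    n_neighbors: int | str = "all"
    seed: int = 0
    alpha_grid: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(11))

    def __post_init__(self) -> None:
        if not 0.3 <= self.mu <= 0.8:
            raise ValueError(f"mu must be in [0.3, 0.8], got {self.mu}")
        if self.alpha != "auto" and not 0.0 <= float(self.alpha) <= 1.0:
            raise ValueError(f"alpha must be in [0, 1] or 'auto', got {self.alpha}")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be positive")
        if not 0.0 < self.ev_threshold <= 1.0:
            raise ValueError("ev_threshold must be in (0, 1]")
        if self.n_neighbors != "all" and int(self.n_neighbors) < 1:
            raise ValueError("n_neighbors must be positive or 'all'")
        if not self.alpha_grid:
            raise ValueError("alpha_grid must be non-empty")
        if any(not 0.0 <= a <= 1.0 for a in self.alpha_grid):
            raise ValueError("alpha_grid values must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "alpha_grid" in raw:
            raw["alpha_grid"] = tuple(raw["alpha_grid"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# readers / writers (UTF-8 TSV, "." decimal, no quoting)
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path, view: str) -> ExpressionMatrix:
    """Read a features x samples expression TSV.

    First column holds feature ids, the header row sample ids; the body must
    be fully numeric with no missing cells. Row/column order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.empty or df.shape[1] == 0:
        raise LoadError(f"{path}: empty expression table")
    feature_ids = [str(f) for f in df.index]
    sample_ids = [str(s) for s in df.columns]
    for ids, kind in ((feature_ids, "feature"), (sample_ids, "sample")):
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise LoadError(f"{path}: duplicate {kind} id {i!r}")
            seen.add(i)
    values = np.empty(df.shape, dtype=float)
    for r, (fid, row) in enumerate(zip(feature_ids, df.itertuples(index=False))):
        for c, cell in enumerate(row):
            try:
                if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                    raise ValueError
                values[r, c] = float(cell)
                if np.isnan(values[r, c]):
                    raise ValueError
            except (TypeError, ValueError):
                raise LoadError(
                    f"{path}: non-numeric or missing value {cell!r} at "
                    f"feature {fid!r}, sample {sample_ids[c]!r}"
                ) from None
    return ExpressionMatrix(values, feature_ids, sample_ids, view=view)


def write_expression_table(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write an ExpressionMatrix as TSV with full float precision (round-trip safe)."""
    df = pd.DataFrame(expr.values, index=expr.feature_ids, columns=expr.sample_ids)
    df.to_csv(path, sep="\t", float_format="%.17g", index_label="feature_id")


def read_network_table(path: str | Path) -> RegulatoryNetwork:
    """Read a typed edge list (source_id, target_id, source_type, target_type).

    The edge type is inferred from the node-type pair; mRNA-mRNA rows expand
    to both directions. A node appearing with two different types, or a type
    pair outside the five permitted kinds, is an error.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["source_id", "target_id", "source_type", "target_type"]
    if list(df.columns[:4]) != required:
        raise LoadError(f"{path}: expected columns {required}, got {list(df.columns)}")
    nodes: dict[str, str] = {}
    edges: set[tuple[str, str, str]] = set()
    for row in df.itertuples(index=False):
        src, tgt, stype, ttype = (str(row.source_id), str(row.target_id),
                                  str(row.source_type), str(row.target_type))
        for node, ntype in ((src, stype), (tgt, ttype)):
            if ntype not in NODE_TYPES:
                raise LoadError(f"{path}: unknown node type {ntype!r} for {node!r}")
            if nodes.setdefault(node, ntype) != ntype:
                raise LoadError(
                    f"{path}: node {node!r} listed as both "
                    f"{nodes[node]!r} and {ntype!r}"
                )
        etype = EDGE_TYPE_BY_PAIR.get((stype, ttype))
        if etype is None:
            raise LoadError(
                f"{path}: edge type {stype}->{ttype} is not in the regulation model"
            )
        if src == tgt:
            raise LoadError(f"{path}: self-loop on {src!r}")
        edges.add((src, tgt, etype))
        if etype == "mRNA-mRNA":
            edges.add((tgt, src, etype))
    return RegulatoryNetwork(nodes, edges)


def write_network_table(net: RegulatoryNetwork, path: str | Path) -> None:
    """Write the network edge list; each mRNA-mRNA pair is emitted once."""
    rows = []
    seen_sym: set[frozenset[str]] = set()
    for src, tgt, etype in sorted(net.edges):
        if etype == "mRNA-mRNA":
            key = frozenset((src, tgt))
            if key in seen_sym:
                continue
            seen_sym.add(key)
        rows.append((src, tgt, net.nodes[src], net.nodes[tgt]))
    pd.DataFrame(rows, columns=["source_id", "target_id",
                                "source_type", "target_type"]).to_csv(
        path, sep="\t", index=False)


def read_clinical_table(path: str | Path) -> list[SurvivalRecord]:
    """Read (sample_id, time_days, status) survival records."""
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "time_days", "status"}
    if not required.issubset(df.columns):
        raise LoadError(f"{path}: expected columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise LoadError(f"{path}: duplicate sample id {dup!r}")
    return [SurvivalRecord(str(r.sample_id), float(r.time_days), int(r.status))
            for r in df.itertuples(index=False)]


def write_clinical_table(records: list[SurvivalRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.sample_id, r.time, r.status) for r in records],
        columns=["sample_id", "time_days", "status"],
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# harmonization & standardization
# ---------------------------------------------------------------------------

def harmonize(
    gene_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    net: RegulatoryNetwork,
) -> tuple[ExpressionMatrix, ExpressionMatrix, RegulatoryNetwork]:
    """Restrict expression and network to their common feature/sample universe.

    Expression features absent from the network are dropped; network nodes
    without an expression row are removed with their edges; both expression
    matrices are restricted to the shared sample set in gene-matrix order.
    """
    gene_keep = [f for f in gene_expr.feature_ids if f in net.nodes]
    mirna_keep = [f for f in mirna_expr.feature_ids if f in net.nodes]
    shared_samples = [s for s in gene_expr.sample_ids
                      if s in set(mirna_expr.sample_ids)]
    if not gene_keep or not mirna_keep:
        raise ValueError("empty feature intersection between expression and network")
    if not shared_samples:
        raise ValueError("gene and miRNA tables share no samples")
    if len(shared_samples) < max(gene_expr.n_samples, mirna_expr.n_samples):
        logger.warning(
            "sample sets differ: keeping %d shared samples", len(shared_samples)
        )
    expressed = set(gene_keep) | set(mirna_keep)
    net_out = net.subnetwork(expressed) if expressed != set(net.nodes) else net
    same_gene = gene_keep == gene_expr.feature_ids and \
        shared_samples == gene_expr.sample_ids
    same_mirna = mirna_keep == mirna_expr.feature_ids and \
        shared_samples == mirna_expr.sample_ids
    gene_out = gene_expr if same_gene else gene_expr.subset(gene_keep, shared_samples)
    mirna_out = mirna_expr if same_mirna else \
        mirna_expr.subset(mirna_keep, shared_samples)
    return gene_out, mirna_out, net_out


def zscore_standardize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale every feature row to mean 0, population sd 1.

    Constant rows (sd = 0) map to all-zeros rather than raising, so that
    degenerate fixtures remain usable.
    """
    if expr.standardized:
        raise ValueError("expression is already standardized")
    mean = expr.values.mean(axis=1, keepdims=True)
    sd = expr.values.std(axis=1, ddof=0, keepdims=True)
    centered = expr.values - mean
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)
    return replace(expr, values=z, standardized=True)
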