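"""Hierarchical clustering of merged samples with multiscale-bootstrap support.

Samples are clustered with 1 - Pearson correlation as distance and average
linkage (UPGMA).  Cluster robustness is assessed by multiscale bootstrap:
genes are resampled with replacement at several dataset sizes r·n
(default r = 0.5 ... 1.4 in steps of 0.1), trees are rebuilt, and each
original node's bootstrap probability BP_r is the fraction of bootstrap
trees containing its exact leaf set.  The approximately-unbiased (AU)
p-value comes from the standard probit-scale curve fit: with
sigma_r = sqrt(1/r) and z_r = Phi^-1(1 - BP_r), fit z(sigma) =
v*sigma + c/sigma by weighted least squares (binomial delta-method
weights) and report AU = 1 - Phi(v - c).  AU corrects the size bias of the
plain bootstrap probability: BP at scale 1 equals 1 - Phi(v + c) under the
same model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import norm

from .errors import DataError, ParameterError
from .crossnorm import MergedDataset

__all__ = [
    "ClusterNode",
    "ClusterTree",
    "correlation_distance",
    "average_linkage",
    "multiscale_bootstrap",
    "au_pvalue",
    "annotate_tree",
    "cut_tree",
    "export_tree",
    "DEFAULT_SCALES",
]

DEFAULT_SCALES: tuple[float, ...] = tuple(np.round(np.arange(0.5, 1.41, 0.1), 1))


@dataclass
class ClusterNode:
    """One internal node: its leaf set, merge height, and support values."""

    leaf_set: frozenset[str]
    height: float
    bp: float | None = None          # bootstrap probability at the scale nearest 1
    au: float | None = None          # approximately-unbiased p-value
    v: float | None = None           # signed-distance parameter of the probit fit
    c: float | None = None           # curvature parameter
    flag: str = ""                   # "", "all_one", "all_zero", "degenerate"
    bp_by_scale: dict[float, float] = field(default_factory=dict)


@dataclass
class ClusterTree:
    """Binary dendrogram over sample labels (scipy linkage matrix + node table)."""

    labels: list[str]
    linkage: np.ndarray  # scipy (n-1) x 4 linkage matrix
    nodes: list[ClusterNode]  # one per linkage row, same order

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def node_by_leaves(self, leaves: Sequence[str]) -> ClusterNode:
        target = frozenset(leaves)
        for node in self.nodes:
            if node.leaf_set == target:
                return node
        raise KeyError(f"no node with leaf set {sorted(target)}")


def _extract_frame(merged: MergedDataset | pd.DataFrame) -> pd.DataFrame:
    return merged.values if isinstance(merged, MergedDataset) else merged


def correlation_distance(merged: MergedDataset | pd.DataFrame) -> pd.DataFrame:
    """Sample-by-sample 1 - Pearson r distance matrix (values in [0, 2])."""
    frame = _extract_frame(merged)
    if frame.shape[0] < 2:
        raise ParameterError("correlation distance needs at least 2 genes")
    arr = frame.to_numpy(dtype=float)
    if np.any(arr.std(axis=0) == 0):
        bad = frame.columns[arr.std(axis=0) == 0].tolist()[:5]
        raise DataError(f"zero-variance sample column(s): {bad}")
    d = 1.0 - np.corrcoef(arr.T)
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return pd.DataFrame(d, index=frame.columns, columns=frame.columns)


def _leafsets_from_linkage(Z: np.ndarray, labels: Sequence[str]) -> list[frozenset[str]]:
    n = len(labels)
    clusters: list[frozenset[str]] = [frozenset((lbl,)) for lbl in labels]
    out: list[frozenset[str]] = []
    for a, b in Z[:, :2].astype(int):
        merged = clusters[a] | clusters[b]
        clusters.append(merged)
        out.append(merged)
    return out


def average_linkage(dist: pd.DataFrame) -> ClusterTree:
    """UPGMA agglomeration of a symmetric distance matrix."""
    labels = list(dist.index)
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ParameterError("distance matrix must be square and symmetric")
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    leafsets = _leafsets_from_linkage(Z, labels)
    nodes = [ClusterNode(leaf_set=ls, height=float(h)) for ls, h in zip(leafsets, Z[:, 2])]
    return ClusterTree(labels=labels, linkage=Z, nodes=nodes)


def cut_tree(tree: ClusterTree, k: int) -> dict[str, int]:
    """Partition the samples into k flat clusters (label -> cluster id)."""
    assign = hierarchy.fcluster(tree.linkage, t=k, criterion="maxclust")
    return {lbl: int(c) for lbl, c in zip(tree.labels, assign)}


def multiscale_bootstrap(
    merged: MergedDataset | pd.DataFrame,
    tree: ClusterTree,
    n_boot: int = 1000,
    scales: Sequence[float] = DEFAULT_SCALES,
    seed: int = 0,
) -> pd.DataFrame:
    """BP table: rows = tree nodes (by index), columns = scales.

    At scale r, each of ``n_boot`` pseudo-datasets resamples round(r*n) genes
    with replacement, is reclustered, and a node counts as supported when its
    exact leaf set reappears in the bootstrap tree.
    """
    frame = _extract_frame(merged)
    arr = frame.to_numpy(dtype=float)
    n_genes = arr.shape[0]
    labels = list(frame.columns)
    if labels != tree.labels:
        raise ParameterError("tree labels do not match merged sample columns")
    targets = [node.leaf_set for node in tree.nodes]
    rng = np.random.default_rng(seed)

    bp = np.zeros((len(targets), len(scales)))
    for si, r in enumerate(scales):
        size = int(round(r * n_genes))
        if size < 2:
            raise ParameterError(f"scale {r} gives a resample of {size} < 2 genes")
        counts = np.zeros(len(targets))
        for _ in range(n_boot):
            idx = rng.integers(0, n_genes, size=size)
            sub = arr[idx]
            if np.any(sub.std(axis=0) == 0):
                continue  # correlation undefined for this resample; counts stay conservative
            d = 1.0 - np.corrcoef(sub.T)
            np.fill_diagonal(d, 0.0)
            d = np.clip(d, 0.0, 2.0)
            Z = hierarchy.linkage(squareform(d, checks=False), method="average")
            found = set(_leafsets_from_linkage(Z, labels))
            for ti, t in enumerate(targets):
                if t in found:
                    counts[ti] += 1
        bp[:, si] = counts / n_boot
    return pd.DataFrame(bp, columns=list(scales))


def au_pvalue(
    bp_by_scale: Sequence[float],
    scales: Sequence[float],
    n_boot: int,
) -> tuple[float, float | None, float | None, str]:
    """Fit the probit support curve for one node; return (AU, v, c, flag).

    Scales where BP is exactly 0 or 1 carry no information about the curve
    and are dropped from the fit.  Fewer than 3 usable scales means the fit
    is degenerate: AU falls back to the BP at the scale closest to 1 and the
    node is flagged.  BP identically 1 (resp. 0) across scales yields AU = 1
    (resp. 0).
    """
    bp = np.asarray(bp_by_scale, dtype=float)
    scales = np.asarray(scales, dtype=float)
    if bp.shape != scales.shape:
        raise ParameterError("bp_by_scale and scales must have the same length")
    if np.all(bp >= 1.0):
        return 1.0, None, None, "all_one"
    if np.all(bp <= 0.0):
        return 0.0, None, None, "all_zero"
    usable = (bp > 0.0) & (bp < 1.0)
    if usable.sum() < 3:
        nearest = int(np.argmin(np.abs(scales - 1.0)))
        return float(bp[nearest]), None, None, "degenerate"

    b = bp[usable]
    sigma = np.sqrt(1.0 / scales[usable])
    z = norm.isf(b)  # Phi^-1(1 - BP)
    # delta method: var(z) = BP(1-BP) / (n_boot * phi(z)^2)
    w = n_boot * norm.pdf(z) ** 2 / (b * (1.0 - b))
    X = np.column_stack([sigma, 1.0 / sigma])
    WX = X * w[:, None]
    coef, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ z, rcond=None)
    v, c = float(coef[0]), float(coef[1])
    au = float(norm.sf(v - c))
    return au, v, c, ""


def annotate_tree(
    tree: ClusterTree,
    merged: MergedDataset | pd.DataFrame,
    n_boot: int = 1000,
    scales: Sequence[float] = DEFAULT_SCALES,
    seed: int = 0,
) -> ClusterTree:
    """Attach BP (scale nearest 1) and AU p-values to every internal node."""
    bp_table = multiscale_bootstrap(merged, tree, n_boot=n_boot, scales=scales, seed=seed)
    scales_arr = np.asarray(scales, dtype=float)
    nearest = int(np.argmin(np.abs(scales_arr - 1.0)))
    for node, (_, row) in zip(tree.nodes, bp_table.iterrows()):
        bp = row.to_numpy(dtype=float)
        node.bp_by_scale = dict(zip(map(float, scales), bp))
        node.bp = float(bp[nearest])
        node.au, node.v, node.c, node.flag = au_pvalue(bp, scales_arr, n_boot)
    return tree


# -- export -----------------------------------------------------------------


def _newick_support(node: ClusterNode | None) -> str:
    if node is None or node.au is None:
        return ""
    au_pct = int(round(node.au * 100))
    bp_pct = int(round((node.bp if node.bp is not None else 0.0) * 100))
    return f"{au_pct}_{bp_pct}"


def to_newick(tree: ClusterTree) -> str:
    """Newick string with internal labels ``AU_BP`` (integer percentages)."""
    n = len(tree.labels)
    heights = {i: 0.0 for i in range(n)}
    for k, h in enumerate(tree.linkage[:, 2]):
        heights[n + k] = float(h)

    def render(i: int, parent_h: float) -> str:
        length = parent_h - heights[i]
        if i < n:
            return f"{tree.labels[i]}:{length:.6f}"
        k = i - n
        a, b = (int(x) for x in tree.linkage[k, :2])
        node = tree.nodes[k]
        inner = ",".join([render(a, heights[i]), render(b, heights[i])])
        return f"({inner}){_newick_support(node)}:{length:.6f}"

    root = n + len(tree.nodes) - 1
    a, b = (int(x) for x in tree.linkage[-1, :2])
    inner = ",".join([render(a, heights[root]), render(b, heights[root])])
    return f"({inner}){_newick_support(tree.nodes[-1])};"


def export_tree(tree: ClusterTree, newick_path: str | Path, support_path: str | Path | None = None) -> str:
    """Write the annotated Newick plus a companion per-node support TSV."""
    nwk = to_newick(tree)
    Path(newick_path).write_text(nwk + "\n")
    if support_path is not None:
        rows = []
        for i, node in enumerate(tree.nodes):
            rows.append(
                {
                    "node": i,
                    "n_leaves": len(node.leaf_set),
                    "leaves": "|".join(sorted(node.leaf_set)),
                    "height": node.height,
                    "BP": node.bp if node.bp is not None else "",
                    "AU": node.au if node.au is not None else "",
                    "v": node.v if node.v is not None else "",
                    "c": node.c if node.c is not None else "",
                    "flag": node.flag,
                }
            )
        pd.DataFrame(rows).to_csv(support_path, sep="\t", index=False)
    return nwk
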