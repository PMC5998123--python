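"""Hierarchical clustering of experimental comparisons by vote agreement.

Two comparisons probing the same biology should call the same genes in
the same direction.  The *affinity distance* between two comparison
columns is one minus the fraction of agreeing nonzero votes among the
co-measured genes where at least one column votes:

    d(x, y) = 1 - |{g: x_g = y_g != 0}| / |{g: x_g != 0 or y_g != 0}|

(both restricted to genes measured in both comparisons; d = 1 when no
gene qualifies).  It is a Jaccard-style agreement distance in [0, 1]:
0 means identical nonzero calls, 1 means no shared call.  The metric is
pluggable so alternatives (e.g. 1 - Pearson correlation of columns) can
be swapped in.

Agglomerative clustering on the pairwise distances with a flat cut at a
height threshold groups redundant or biologically coherent comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

LINKAGES = ("average", "complete", "single")


def affinity_distance(x, y) -> float:
    """Agreement distance in [0, 1] between two affinity columns
    (entries in {+1, -1, 0, NaN}) on the same gene axis."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("affinity columns must share the gene axis")
    both = ~np.isnan(x) & ~np.isnan(y)
    union = both & ((x != 0) | (y != 0))
    denom = int(union.sum())
    if denom == 0:
        return 1.0
    agree = int((both & (x == y) & (x != 0)).sum())
    return 1.0 - agree / denom


def pearson_distance(x, y) -> float:
    """1 - Pearson correlation over co-measured genes (alternative
    metric); rescaled to [0, 1]; 1 when undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    both = ~np.isnan(x) & ~np.isnan(y)
    if both.sum() < 2 or x[both].std() == 0 or y[both].std() == 0:
        return 1.0
    r = float(np.corrcoef(x[both], y[both])[0, 1])
    return (1.0 - r) / 2.0


METRICS: dict[str, Callable] = {
    "affinity": affinity_distance,
    "pearson": pearson_distance,
}


def distance_matrix(am: pd.DataFrame,
                    metric: str | Callable = "affinity") -> pd.DataFrame:
    """Symmetric comparisons x comparisons distance matrix."""
    fn = METRICS[metric] if isinstance(metric, str) else metric
    ids = list(am.columns)
    n = len(ids)
    d = np.zeros((n, n))
    vals = am.to_numpy(float)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(vals[:, i], vals[:, j])
    return pd.DataFrame(d, index=ids, columns=ids)


@dataclass
class ClusterAssignment:
    labels: dict[str, int]      # comparison id -> cluster label (1-based)
    cut_height: float
    linkage: str
    metric: str

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))


def cluster_comparisons(am: pd.DataFrame, linkage: str = "average",
                        cut_height: float = 0.05,
                        metric: str | Callable = "affinity",
                        ) -> ClusterAssignment:
    """Agglomerative clustering of comparison columns with a flat cut.

    Clusters are the connected groups after cutting the dendrogram at
    ``cut_height``; labels are renumbered 1..k in order of first
    appearance along the column order, so the result is deterministic.
    """
    if am.shape[1] < 2:
        raise ValueError("need at least 2 comparisons to cluster")
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    dm = distance_matrix(am, metric)
    z = hierarchy.linkage(squareform(dm.to_numpy(), checks=False),
                          method=linkage)
    flat = hierarchy.fcluster(z, t=cut_height, criterion="distance")
    relabel: dict[int, int] = {}
    labels = {}
    for cid, raw in zip(dm.index, flat):
        if raw not in relabel:
            relabel[raw] = len(relabel) + 1
        labels[str(cid)] = relabel[raw]
    name = metric if isinstance(metric, str) else getattr(
        metric, "__name__", "custom")
    return ClusterAssignment(labels=labels, cut_height=cut_height,
                             linkage=linkage, metric=name)


def dendrogram_newick(am: pd.DataFrame, linkage: str = "average",
                      metric: str | Callable = "affinity") -> str:
    """Newick export of the comparison dendrogram (branch lengths are
    merge-height differences)."""
    dm = distance_matrix(am, metric)
    z = hierarchy.linkage(squareform(dm.to_numpy(), checks=False),
                          method=linkage)
    tree = hierarchy.to_tree(z)
    ids = list(dm.index)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - (node.dist if not node.is_leaf() else 0.0),
                     0.0)
        if node.is_leaf():
            return f"{ids[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def write_distance_matrix(dm: pd.DataFrame, path) -> None:
    dm.to_csv(path, sep="\t", float_format="%.6g")


def write_clusters(ca: ClusterAssignment, path) -> None:
    rows = sorted(ca.labels.items(), key=lambda kv: (kv[1], kv[0]))
    pd.DataFrame(rows, columns=["comparison_id", "cluster"]).to_csv(
        path, sep="\t", index=False)
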