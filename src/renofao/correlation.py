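"""Structure-transcript-metabolite correlation networks ("molecular morphometrics").

Per-animal feature tables mixing histological/ultrastructural parameters,
variance-stabilised gene expression and PQN-normalized NMR peak intensities
are correlated pairwise (Pearson); weak correlations (|r| < 0.5) are removed
and the remainder form a signed network whose nodes are embedded by classical
multidimensional scaling of d = 1 - r and clustered by complete linkage.
Using the signed distance keeps anti-correlated features apart, so clusters
collect features that move together across animals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

MIN_ABS_R = 0.5


@dataclass
class FeatureTable:
    """Animals x features with a type tag per feature column."""

    values: pd.DataFrame
    feature_types: pd.Series  # feature -> 'structure' | 'transcript' | 'metabolite'

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.feature_types.index)
        if missing:
            raise ValueError(f"features without a type tag: {sorted(missing)}")
        if len(self.values) < 3:
            raise ValueError("at least 3 animals required for correlation")


def pearson_matrix(table: FeatureTable | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations; constant columns dropped with a warning."""
    df = table.values if isinstance(table, FeatureTable) else table
    if len(df) < 3:
        raise ValueError("at least 3 rows required")
    sd = df.std(ddof=0)
    constant = sd.index[sd == 0]
    if len(constant):
        warnings.warn(f"dropping constant columns: {list(constant)}")
        df = df.drop(columns=constant)
    corr = df.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def threshold_network(
    corr: pd.DataFrame,
    min_abs_r: float = MIN_ABS_R,
    feature_types: pd.Series | None = None,
) -> nx.Graph:
    """Correlation network keeping edges with |r| >= min_abs_r (inclusive).

    All features remain as nodes; those left without any retained edge carry
    ``isolated=True``. Edge attribute ``r`` stores the signed correlation.
    """
    g = nx.Graph()
    for f in corr.columns:
        ftype = feature_types.get(f) if feature_types is not None else None
        g.add_node(f, type=ftype)
    cols = list(corr.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = float(corr.loc[a, b])
            if abs(r) >= min_abs_r:
                g.add_edge(a, b, r=r)
    for f in g.nodes:
        g.nodes[f]["isolated"] = g.degree(f) == 0
    return g


def classical_mds(dist: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Torgerson classical MDS of a symmetric distance matrix.

    Double-centers the squared distances and embeds on the top eigenvectors;
    dimensions with non-positive eigenvalues collapse to zero.
    """
    d2 = np.asarray(dist, dtype=float) ** 2
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:n_components]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def mds_cluster(
    corr: pd.DataFrame, k_clusters: int, n_components: int = 2
) -> pd.DataFrame:
    """Embed features by classical MDS of d = 1 - r and cluster the embedding.

    Complete-linkage hierarchical clustering on the 2-D coordinates, cut at
    ``k_clusters``. Returns a frame indexed by feature with columns x, y,
    cluster.
    """
    n = corr.shape[0]
    if n < 2:
        raise ValueError("at least 2 features required")
    if k_clusters > n:
        raise ValueError("more clusters requested than features")
    dist = 1.0 - corr.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    coords = classical_mds(dist, n_components=n_components)
    if k_clusters == n:
        labels = np.arange(1, n + 1)
    else:
        Z = linkage(coords, method="complete")
        labels = fcluster(Z, t=k_clusters, criterion="maxclust")
    out = pd.DataFrame(coords[:, :2], index=corr.index, columns=["x", "y"])
    out["cluster"] = labels
    return out


def network_tables(g: nx.Graph, layout: pd.DataFrame | None = None):
    """Edge list (source, target, r) and node table for serialization."""
    edges = pd.DataFrame(
        [(a, b, d["r"]) for a, b, d in g.edges(data=True)],
        columns=["source", "target", "r"],
    )
    nodes = pd.DataFrame(
        [(f, d.get("type"), d.get("isolated", False)) for f, d in g.nodes(data=True)],
        columns=["id", "type", "isolated"],
    ).set_index("id")
    if layout is not None:
        nodes = nodes.join(layout)
    return edges, nodes
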