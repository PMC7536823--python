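"""Regulon-level network structures derived from activity scores.

From a regulon x cell RAS matrix: the pairwise Pearson correlation (PCC)
matrix; its connection-specificity-index (CSI) transform, which is high for
a regulon pair that correlates with each other but with few third parties;
average-linkage modules over CSI rows; an undirected unweighted network over
regulons connected wherever CSI exceeds a threshold (strictly); node
centralities; and the Gini coefficient used to quantify how unequally a
regulon's activity is distributed.

CSI convention: for regulons A, B with correlation p = PCC(A, B),

    CSI(A, B) = 1 - |{C : PCC(C, A) >= p - delta  or  PCC(C, B) >= p - delta}| / n

with delta = 0.05 by default and n the total number of regulons; A and B
count themselves through PCC(X, X) = 1, so CSI < 1 off the diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance

from .activity import RegulonActivityMatrix
from .io_formats import ValidationError


def compute_pcc(ras: RegulonActivityMatrix) -> pd.DataFrame:
    """Pairwise Pearson correlation of regulon activity profiles.

    Zero-variance regulons are excluded with a warning; fewer than three
    cells cannot support a correlation estimate.
    """
    if len(ras.cell_ids) < 3:
        raise ValidationError("PCC needs >= 3 cells")
    V = ras.values
    sd = V.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            "excluding %d zero-variance regulons from PCC" % int((~keep).sum())
        )
    ids = [r for r, k in zip(ras.regulon_ids, keep) if k]
    if len(ids) < 2:
        raise ValidationError("fewer than 2 regulons with non-zero variance")
    P = np.corrcoef(V[keep, :])
    np.fill_diagonal(P, 1.0)
    return pd.DataFrame(P, index=ids, columns=ids)


def compute_csi(pcc: pd.DataFrame, delta: float = 0.05) -> pd.DataFrame:
    """Connection specificity index of every regulon pair (diagonal = 1)."""
    if not 0 <= delta < 2:
        raise ValueError("delta must lie in [0, 2)")
    P = pcc.to_numpy(dtype=float)
    if P.shape[0] != P.shape[1] or not np.allclose(P, P.T, atol=1e-10):
        raise ValidationError("PCC matrix must be symmetric")
    n = P.shape[0]
    csi = np.ones((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            thr = P[a, b] - delta
            count = int(np.sum((P[:, a] >= thr) | (P[:, b] >= thr)))
            csi[a, b] = csi[b, a] = 1.0 - count / n
    return pd.DataFrame(csi, index=pcc.index, columns=pcc.columns)


def cluster_modules(csi: pd.DataFrame, n_modules: int = 5) -> dict[str, int]:
    """Average-linkage agglomerative clustering of CSI rows (Euclidean),
    cut to ``n_modules`` flat clusters."""
    n = csi.shape[0]
    if n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    if n_modules > n:
        raise ValueError("n_modules exceeds the number of regulons")
    dist = scipy.spatial.distance.pdist(csi.to_numpy(), metric="euclidean")
    link = scipy.cluster.hierarchy.linkage(dist, method="average")
    flat = scipy.cluster.hierarchy.fcluster(link, t=n_modules, criterion="maxclust")
    return {r: int(m) for r, m in zip(csi.index, flat)}


@dataclass
class RegulonNetwork:
    """Undirected, unweighted regulon graph with module labels."""

    graph: nx.Graph
    modules: dict[str, int]
    edge_threshold: float

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)


def build_network(
    csi: pd.DataFrame, modules: dict[str, int], edge_threshold: float = 0.7
) -> RegulonNetwork:
    """Connect regulon pairs whose CSI is strictly above the threshold;
    isolated nodes are retained with their module label."""
    if not 0 <= edge_threshold <= 1:
        raise ValueError("edge_threshold must lie in [0, 1]")
    G = nx.Graph()
    ids = list(csi.index)
    for r in ids:
        G.add_node(r, module=modules.get(r))
    M = csi.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if M[i, j] > edge_threshold:
                G.add_edge(ids[i], ids[j])
    return RegulonNetwork(G, dict(modules), edge_threshold)


def network_features(net: RegulonNetwork) -> pd.DataFrame:
    """Degree, closeness (harmonic convention), betweenness and eigenvector
    centrality per node; eigenvector centrality is computed by power
    iteration on the largest connected component, 0 elsewhere."""
    G = net.graph
    n = G.number_of_nodes()
    if n == 0:
        raise ValidationError("network has no nodes")
    degree = dict(G.degree())
    harmonic = nx.harmonic_centrality(G)
    closeness = {v: (harmonic[v] / (n - 1) if n > 1 else 0.0) for v in G}
    betweenness = nx.betweenness_centrality(G, normalized=True)
    eigen = {v: 0.0 for v in G}
    comps = sorted(nx.connected_components(G), key=lambda c: (len(c), sorted(c)))
    if comps:
        largest = comps[-1]
        if len(largest) > 1:
            sub = G.subgraph(largest)
            eigen.update(nx.eigenvector_centrality(sub, max_iter=5000, tol=1e-10))
    rows = [
        {
            "regulon": v,
            "module": net.modules.get(v),
            "degree": degree[v],
            "closeness": closeness[v],
            "betweenness": betweenness[v],
            "eigencentrality": eigen[v],
        }
        for v in sorted(G.nodes)
    ]
    return pd.DataFrame(rows).set_index("regulon")


def gini(values) -> float:
    """Gini coefficient of a non-negative vector:
    G = sum_i (2i - n - 1) x_(i) / (n * sum_i x_i) over the ascending sort."""
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0 or (x < 0).any():
        raise ValidationError("gini needs a non-empty, non-negative vector")
    total = x.sum()
    if total == 0:
        raise ValidationError("gini is undefined for an all-zero vector")
    n = x.size
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * x).sum() / (n * total))
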