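"""Comparison and validation statistics.

Clustering agreement (AMI with max normalisation, completeness), silhouette,
per-point centroid distances in a shared PCA space, Jaccard composition
overlap, validation of the regulon network against an annotated
protein-interaction table and an essentiality list, and — on synthetic data —
recovery of the planted ground truth (per-TF target Jaccard, module ARI,
activity specificity).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import (
    adjusted_mutual_info_score,
    adjusted_rand_score,
    completeness_score,
    silhouette_score,
)

from .activity import RegulonActivityMatrix
from .io_formats import Regulon, ValidationError
from .network import RegulonNetwork
from .synthetic_atlas import SyntheticGroundTruth


def jaccard(a: set, b: set) -> float:
    """|A n B| / |A u B|; undefined when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValidationError("jaccard undefined for two empty sets")
    return len(a & b) / len(union)


def clustering_agreement(pred, truth) -> tuple[float, float]:
    """(AMI, completeness) between a predicted and a reference labelling.

    AMI uses the expected-MI adjustment with max normalisation; completeness
    is 1 - H(pred|truth)/H(pred) (1 when H(pred) = 0)."""
    pred, truth = list(pred), list(truth)
    if len(pred) != len(truth):
        raise ValueError("label vectors differ in length")
    if len(pred) < 2:
        raise ValueError("need >= 2 points")
    ami = float(adjusted_mutual_info_score(truth, pred, average_method="max"))
    comp = float(completeness_score(truth, pred))
    return ami, comp


def kmeans_labels(points: np.ndarray, k: int, seed: int = 0, n_init: int = 10) -> np.ndarray:
    """Seeded k-means with restarts (best inertia kept)."""
    km = KMeans(n_clusters=k, n_init=n_init, random_state=int(seed) % (2**31))
    return km.fit_predict(np.asarray(points, dtype=float))


def silhouette(points: np.ndarray, labels) -> float:
    """Mean silhouette score (Euclidean) of the labelled points."""
    labels = np.asarray(list(labels))
    if len(set(labels.tolist())) < 2:
        raise ValidationError("silhouette needs >= 2 distinct labels")
    return float(silhouette_score(np.asarray(points, dtype=float), labels, metric="euclidean"))


def pca_project(
    fit_points: np.ndarray, project_points: np.ndarray | None = None, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray | None]:
    """PCA fitted on one point set (pseudobulk) with a second set (single
    cells) projected onto the same axes."""
    pca = PCA(n_components=n_components, random_state=0)
    fitted = pca.fit_transform(np.asarray(fit_points, dtype=float))
    projected = None
    if project_points is not None:
        projected = pca.transform(np.asarray(project_points, dtype=float))
    return fitted, projected


def centroid_distances(points: np.ndarray, groups) -> pd.Series:
    """Euclidean distance of every point to the mean of its group."""
    points = np.asarray(points, dtype=float)
    groups = pd.Series(list(groups))
    out = np.empty(len(groups))
    for g, idx in groups.groupby(groups).groups.items():
        idx = np.asarray(idx)
        centroid = points[idx].mean(axis=0)
        out[idx] = np.linalg.norm(points[idx] - centroid, axis=1)
    return pd.Series(out, index=groups.index)


def _percentile_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Right-closed percentile bin index (0..n_bins-1) for every value."""
    edges = np.percentile(values, np.linspace(0, 100, n_bins + 1))
    idx = np.searchsorted(edges[1:-1], values, side="left")
    return np.clip(idx, 0, n_bins - 1)


def validate_network(
    net: RegulonNetwork,
    ppi: pd.DataFrame,
    essentials: set[str],
    csi: pd.DataFrame | None = None,
    confidence_bins: int = 20,
    csi_bins: int = 10,
    tf_of_node=lambda node: node.replace("(+)", ""),
) -> dict:
    """Overlap of the regulon network with annotated protein interactions.

    Reports the fraction of network edges present in the interaction table,
    counts of those validated edges per right-closed confidence percentile
    bin, mean CSI per confidence bin (the CSI-vs-confidence trend) when a
    CSI matrix is supplied, and the fraction of network nodes in the
    essential-gene list.  ``ppi`` needs columns (gene_a, gene_b, confidence).
    """
    edges = net.edges
    if not edges:
        raise ValidationError("network has no edges to validate")
    conf_of = {
        frozenset((str(a), str(b))): float(c)
        for a, b, c in ppi[["gene_a", "gene_b", "confidence"]].itertuples(index=False)
    }
    edge_pairs = [frozenset((tf_of_node(a), tf_of_node(b))) for a, b in edges]
    validated = [p for p in edge_pairs if p in conf_of]
    fraction = len(validated) / len(edges)

    per_bin_counts: dict[str, int] = {}
    if validated:
        all_conf = np.array(sorted(conf_of.values()))
        bins = _percentile_bins(all_conf, confidence_bins)
        edge_conf = np.array([conf_of[p] for p in validated])
        edge_bins = _percentile_bins_against(edge_conf, all_conf, confidence_bins)
        for b in range(confidence_bins):
            per_bin_counts["bin_%02d" % (b + 1)] = int((edge_bins == b).sum())

    csi_trend: dict[str, float] = {}
    if csi is not None:
        node_of_tf = {tf_of_node(v): v for v in net.nodes}
        pair_conf, pair_csi = [], []
        for pair, c in conf_of.items():
            a, b = sorted(pair)
            if a in node_of_tf and b in node_of_tf:
                pair_conf.append(c)
                pair_csi.append(float(csi.loc[node_of_tf[a], node_of_tf[b]]))
        if pair_conf:
            pair_conf = np.array(pair_conf)
            bins = _percentile_bins(pair_conf, csi_bins)
            for b in range(csi_bins):
                mask = bins == b
                if mask.any():
                    csi_trend["bin_%02d" % (b + 1)] = float(np.mean(np.array(pair_csi)[mask]))

    nodes = net.nodes
    essential_fraction = sum(tf_of_node(v) in essentials for v in nodes) / len(nodes)
    return {
        "edge_validation_fraction": fraction,
        "per_bin_counts": per_bin_counts,
        "csi_by_confidence_bin": csi_trend,
        "essential_node_fraction": essential_fraction,
        "n_edges": len(edges),
        "n_validated_edges": len(validated),
    }


def _percentile_bins_against(values: np.ndarray, population: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.percentile(population, np.linspace(0, 100, n_bins + 1))
    idx = np.searchsorted(edges[1:-1], values, side="left")
    return np.clip(idx, 0, n_bins - 1)


def recover_ground_truth(
    regulons: list[Regulon],
    modules: dict[str, int],
    truth: SyntheticGroundTruth,
    ras: RegulonActivityMatrix | None = None,
    cell_types: pd.Series | None = None,
    active_threshold: float = 0.5,
) -> dict:
    """Recovery of the planted structure by the inferred regulons.

    Per planted TF: Jaccard between recovered and planted target sets (0 for
    TFs with no recovered regulon).  Module agreement: ARI between the
    inferred module labels and the planted module partition, over recovered
    TFs.  If RAS plus per-cell types are supplied, per-regulon specificity:
    mean RAS in planted-active cell types minus mean RAS in inactive types.
    """
    recovered = {r.tf: r for r in regulons}
    per_tf = {}
    for tf in truth.tf_ids:
        planted = set(truth.target_weights[tf])
        if tf in recovered:
            per_tf[tf] = jaccard(set(recovered[tf].targets), planted)
        else:
            per_tf[tf] = 0.0

    tf_of_node = {("%s(+)" % tf): tf for tf in recovered}
    common = [node for node in modules if node in tf_of_node]
    if common:
        pred = [modules[node] for node in common]
        true = [truth.module_of_tf[tf_of_node[node]] for node in common]
        ari = float(adjusted_rand_score(true, pred))
    else:
        ari = float("nan")

    specificity = {}
    if ras is not None and cell_types is not None:
        rasf = ras.to_frame()
        types = cell_types.loc[rasf.columns]
        for node in rasf.index:
            tf = node.replace("(+)", "")
            if tf not in truth.activity_profile.columns:
                continue
            act = truth.activity_profile[tf]
            active_types = set(act.index[act >= active_threshold])
            mask = types.isin(active_types).to_numpy()
            if mask.any() and (~mask).any():
                row = rasf.loc[node].to_numpy()
                specificity[node] = float(row[mask].mean() - row[~mask].mean())

    vals = np.array(list(per_tf.values()))
    return {
        "per_tf_jaccard": per_tf,
        "median_jaccard": float(np.median(vals)),
        "n_recovered_regulons": len(recovered),
        "module_ari": ari,
        "ras_specificity": specificity,
        "mean_ras_specificity": float(np.mean(list(specificity.values()))) if specificity else float("nan"),
    }


def harmonisation_accuracy(assigned: pd.Series, truth_types: pd.Series) -> float:
    """Fraction of assigned (non-UNASSIGNED) cells mapped to their true
    reference type."""
    from .io_formats import UNASSIGNED

    common = assigned.index.intersection(truth_types.index)
    a = assigned.loc[common]
    t = truth_types.loc[common]
    mapped = a != UNASSIGNED
    if not mapped.any():
        return 0.0
    return float((a[mapped] == t[mapped]).mean())
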