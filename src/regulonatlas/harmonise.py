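"""Cross-atlas cell-type harmonisation by unsupervised centroid projection.

One atlas is designated the reference: its author labels define the
reference cell types, and per-type centroids (feature-wise medians of
normalised expression) are computed on a dropout-informed feature set.
Every other cell is projected onto those centroids under three similarity
measures — cosine, Pearson and Spearman — each of which votes for its
best-matching type.  A cell is assigned the majority type when at least two
measures agree and the best similarity among the agreeing measures clears a
threshold; otherwise it is left UNASSIGNED and excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .io_formats import UNASSIGNED, CellAnnotation, ExpressionMatrix, ValidationError

MEASURES = ("cosine", "pearson", "spearman")


@dataclass
class ReferenceVocabulary:
    """The shared two-level vocabulary: reference types and their cell groups,
    plus the (atlas, author label) -> reference type map filled in by
    projection."""

    reference_types: list[str]
    group_of: dict[str, str]
    author_map: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.reference_types) - set(self.group_of)
        if missing:
            raise ValidationError("no cell group for types: %s" % sorted(missing)[:5])
        if len(set(self.group_of.values())) < 2:
            raise ValidationError("vocabulary needs >= 2 cell groups")


def select_projection_features(expr: ExpressionMatrix, n_features: int = 500) -> list[str]:
    """Genes most informative for projection: largest positive residuals of a
    linear fit of log dropout rate on log mean expression.

    Genes dropping out *more* than their mean expression predicts are the
    ones whose zeros carry cell-type signal.  Genes with zero dropout cannot
    exceed the trend and rank last; all-zero genes are excluded.
    """
    X = expr.values
    n_cells = expr.n_cells
    dropout = (X == 0).sum(axis=1) / n_cells
    mean = X.mean(axis=1)
    usable = mean > 0
    if not usable.any():
        raise ValidationError("all genes are all-zero; no features to select")
    fit_mask = usable & (dropout > 0)
    if fit_mask.sum() >= 2:
        lx = np.log(mean[fit_mask])
        ly = np.log(dropout[fit_mask])
        slope, intercept = np.polyfit(lx, ly, 1)
    else:  # degenerate: no dropout anywhere
        slope, intercept = 0.0, 0.0
    resid = np.full(expr.n_genes, -np.inf)
    resid[fit_mask] = np.log(dropout[fit_mask]) - (slope * np.log(mean[fit_mask]) + intercept)
    order = np.lexsort((np.array(expr.gene_ids), -resid))
    order = [i for i in order if usable[i]]
    return [expr.gene_ids[i] for i in order[: min(n_features, len(order))]]


def compute_centroids(
    expr: ExpressionMatrix, labels: pd.Series, features: list[str]
) -> pd.DataFrame:
    """Per-type centroid: median of normalised expression over that type's
    cells, restricted to the selected features.  Returns feature x type."""
    missing = set(features) - set(expr.gene_ids)
    if missing:
        raise ValueError("unknown features: %s" % sorted(missing)[:5])
    sub = expr.subset_genes(features)
    labels = labels.loc[sub.cell_ids]
    centroids = {}
    for t in sorted(labels.unique()):
        cols = np.flatnonzero((labels == t).to_numpy())
        centroids[t] = np.median(sub.values[:, cols], axis=1)
    return pd.DataFrame(centroids, index=features)


def _column_ranks(M: np.ndarray) -> np.ndarray:
    return scipy.stats.rankdata(M, axis=0)


def _centred_cosine_sim(X: np.ndarray, C: np.ndarray, centre: bool) -> tuple[np.ndarray, np.ndarray]:
    """Similarity of every column of X (features x cells) to every column of
    C (features x types); returns (cells x types sims, per-cell abstain
    mask where the cell vector has zero norm/variance)."""
    if centre:
        X = X - X.mean(axis=0, keepdims=True)
        C = C - C.mean(axis=0, keepdims=True)
    xn = np.linalg.norm(X, axis=0)
    cn = np.linalg.norm(C, axis=0)
    abstain = xn < 1e-12
    sims = np.zeros((X.shape[1], C.shape[1]))
    ok = ~abstain
    denom = np.outer(xn[ok], np.where(cn < 1e-12, np.inf, cn))
    sims[ok, :] = (X[:, ok].T @ C) / denom
    return sims, abstain


def project_cells(
    expr: ExpressionMatrix, centroids: pd.DataFrame, threshold: float = 0.7
) -> pd.DataFrame:
    """Project every cell onto the centroids under the three measures and
    apply the consensus rule.

    Returns a DataFrame indexed by cell id with, per measure, the
    best-matching type and its similarity, plus ``assigned_type`` (a
    reference type or UNASSIGNED).  A zero-variance cell makes Pearson and
    Spearman abstain (recorded as NaN similarity).
    """
    feats = list(centroids.index)
    sub = expr.subset_genes(feats)
    X = sub.values.astype(float)
    C = centroids.to_numpy(dtype=float)
    types = list(centroids.columns)

    sims = {}
    abstains = {}
    sims["cosine"], abstains["cosine"] = _centred_cosine_sim(X, C, centre=False)
    sims["pearson"], abstains["pearson"] = _centred_cosine_sim(X, C, centre=True)
    sims["spearman"], abstains["spearman"] = _centred_cosine_sim(
        _column_ranks(X), _column_ranks(C), centre=True
    )

    n_cells = sub.n_cells
    out = {"cell_id": sub.cell_ids}
    best_type = {}
    best_sim = {}
    for m in MEASURES:
        arg = sims[m].argmax(axis=1)
        bt = np.array([types[i] for i in arg], dtype=object)
        bs = sims[m][np.arange(n_cells), arg]
        bt[abstains[m]] = ""
        bs = np.where(abstains[m], np.nan, bs)
        best_type[m], best_sim[m] = bt, bs
        out["%s_type" % m] = bt
        out["%s_similarity" % m] = bs

    assigned = []
    for i in range(n_cells):
        votes: dict[str, list[float]] = {}
        for m in MEASURES:
            if best_type[m][i]:
                votes.setdefault(best_type[m][i], []).append(best_sim[m][i])
        winner = UNASSIGNED
        for t, sim_list in votes.items():
            if len(sim_list) >= 2 and max(sim_list) >= threshold:
                winner = t
                break
        assigned.append(winner)
    out["assigned_type"] = assigned
    return pd.DataFrame(out).set_index("cell_id")


def build_integrated_annotation(
    projections: pd.DataFrame,
    vocabulary: ReferenceVocabulary,
    base_annotation: CellAnnotation,
) -> tuple[CellAnnotation, pd.DataFrame]:
    """Fold projection assignments into the annotation and build the
    author-label x reference-type contingency table.

    Assigned cells get their reference type and cell group; UNASSIGNED cells
    keep the UNASSIGNED flag (downstream stages exclude them).  The
    (atlas, author label) -> majority reference type map is recorded on the
    vocabulary.
    """
    missing = set(base_annotation.cell_ids) - set(projections.index)
    if missing:
        raise ValidationError("projections do not cover all cells")
    df = base_annotation.table.copy()
    assigned = projections["assigned_type"].loc[df["cell_id"]].to_numpy(dtype=object)
    df["reference_type"] = assigned
    df["cell_group"] = [
        vocabulary.group_of.get(t, UNASSIGNED) if t != UNASSIGNED else UNASSIGNED
        for t in assigned
    ]
    contingency = pd.crosstab(df["author_label"], df["reference_type"])
    mapped = df[df["reference_type"] != UNASSIGNED]
    for (atlas, label), sub in mapped.groupby(["atlas", "author_label"]):
        vocabulary.author_map[(atlas, label)] = sub["reference_type"].mode().iloc[0]
    return CellAnnotation(df, base_annotation.label_map), contingency


def mapped_cells(annotation: CellAnnotation) -> list[str]:
    """Cells retained after harmonisation (non-mapping cells are excluded)."""
    t = annotation.table
    return t.loc[t["reference_type"] != UNASSIGNED, "cell_id"].tolist()
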