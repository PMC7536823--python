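"""Normalisation, feature filtering, pseudobulk construction, cycle scoring.

Pseudobulk is the workhorse here: within every (atlas, tissue, author label)
stratum, disjoint random samples of ``cells_per_sample`` cells are averaged
gene-wise over their *non-zero* members, which suppresses dropout noise while
keeping the scale of expressed values.  Strata smaller than the sample size
are dropped, which removes very rare author-assigned cell types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CellAnnotation, ExpressionMatrix, ValidationError
from .synthetic_atlas import _stable_seed


@dataclass
class PseudobulkMatrix:
    """Gene x sample matrix with per-sample provenance.

    ``sample_meta`` columns: sample_id, atlas, tissue, author_label,
    reference_type, cell_group, member_cells (semicolon-joined cell ids).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if np.min(self.values) < 0:
            raise ValidationError("pseudobulk matrix contains negative entries")
        if self.values.shape != (len(self.gene_ids), len(self.sample_meta)):
            raise ValidationError("pseudobulk shape does not match metadata")
        members = [set(m.split(";")) for m in self.sample_meta["member_cells"]]
        seen: set[str] = set()
        for s in members:
            if seen & s:
                raise ValidationError("pseudobulk member cell sets overlap")
            seen |= s

    @property
    def sample_ids(self) -> list[str]:
        return self.sample_meta["sample_id"].tolist()

    def to_expression(self) -> ExpressionMatrix:
        return ExpressionMatrix(self.values, self.gene_ids, self.sample_ids, normalised=True)


def normalise(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Scale every cell to the median library size, then log1p."""
    libs = expr.values.sum(axis=0)
    keep = libs > 0
    if not keep.all():
        warnings.warn(
            "excluding %d cells with zero library size" % int((~keep).sum())
        )
    values = expr.values[:, keep].astype(float)
    libs = libs[keep].astype(float)
    median_lib = float(np.median(libs))
    scaled = values * (median_lib / libs)[None, :]
    return ExpressionMatrix(
        np.log1p(scaled),
        list(expr.gene_ids),
        [c for c, k in zip(expr.cell_ids, keep) if k],
        normalised=True,
    )


def regress_and_scale(expr: ExpressionMatrix, covariates: pd.DataFrame) -> ExpressionMatrix:
    """Per gene: residual of a least-squares fit on the covariates (library
    size, mitochondrial fraction), then z-scaled; zero-residual-variance
    genes become 0.  Constant covariates degenerate to centring.

    The output can contain negative values; it is returned as a plain gene x
    cell array flagged normalised (callers that need non-negativity should
    not use this stage)."""
    cov = covariates.loc[expr.cell_ids]
    design = np.column_stack([np.ones(expr.n_cells), cov.to_numpy(dtype=float)])
    Y = expr.values.T.astype(float)  # cells x genes
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    resid = Y - design @ beta
    sd = resid.std(axis=0, ddof=0)
    out = np.zeros_like(resid)
    ok = sd > 1e-12
    out[:, ok] = (resid[:, ok] - resid[:, ok].mean(axis=0)) / sd[ok]
    result = ExpressionMatrix.__new__(ExpressionMatrix)
    # bypass the non-negativity check: scaled residuals are signed by design
    result.values = out.T
    result.gene_ids = list(expr.gene_ids)
    result.cell_ids = list(expr.cell_ids)
    result.normalised = True
    return result


def select_expressed_features(expr: ExpressionMatrix, fraction: float = 0.10) -> list[str]:
    """Genes with a non-zero value in at least ``fraction`` of cells
    (inclusive boundary)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    nonzero = (expr.values != 0).mean(axis=1)
    return [g for g, f in zip(expr.gene_ids, nonzero) if f >= fraction]


def make_pseudobulk(
    expr: ExpressionMatrix,
    annotation: CellAnnotation,
    cells_per_sample: int = 50,
    seed: int = 0,
    nonzero_mean: bool = True,
) -> PseudobulkMatrix:
    """Average disjoint seeded samples of same-stratum cells.

    Within each (atlas, tissue, author_label) stratum of n cells,
    floor(n / cells_per_sample) disjoint samples are drawn without
    replacement; per sample a gene's value is the mean over member cells with
    a non-zero value (0 if all members are zero).  Sampling is keyed to
    sorted cell ids, so the result is invariant to cell order.  Setting
    ``nonzero_mean=False`` switches to a plain mean over all members.
    """
    if cells_per_sample < 1:
        raise ValueError("cells_per_sample must be >= 1")
    ann = annotation.table.set_index("cell_id")
    missing = set(expr.cell_ids) - set(ann.index)
    if missing:
        raise ValidationError("annotation does not cover all cells")
    ann = ann.loc[expr.cell_ids]
    col_of = {c: i for i, c in enumerate(expr.cell_ids)}

    strata = ann.groupby(["atlas", "tissue", "author_label"], sort=True)
    blocks, meta_rows = [], []
    for (atlas, tissue, label), sub in strata:
        cells = sorted(sub.index)
        n_samples = len(cells) // cells_per_sample
        if n_samples == 0:
            continue
        rng = np.random.default_rng(_stable_seed(seed, "pseudobulk", atlas, tissue, label))
        perm = rng.permutation(len(cells))
        for j in range(n_samples):
            member_idx = perm[j * cells_per_sample : (j + 1) * cells_per_sample]
            members = [cells[i] for i in member_idx]
            cols = [col_of[c] for c in members]
            block = expr.values[:, cols]
            if nonzero_mean:
                nz = block != 0
                denom = np.maximum(nz.sum(axis=1), 1)
                vals = block.sum(axis=1) / denom
            else:
                vals = block.mean(axis=1)
            blocks.append(vals)
            ref_types = sub.loc[members, "reference_type"]
            groups = sub.loc[members, "cell_group"]
            meta_rows.append(
                {
                    "sample_id": "%s|%s|%s|s%02d" % (atlas, tissue, label, j + 1),
                    "atlas": atlas,
                    "tissue": tissue,
                    "author_label": label,
                    "reference_type": ref_types.mode().iloc[0],
                    "cell_group": groups.mode().iloc[0],
                    "member_cells": ";".join(members),
                }
            )
    if not blocks:
        raise ValidationError(
            "no stratum has >= %d cells; no pseudobulk sample can be formed"
            % cells_per_sample
        )
    values = np.column_stack(blocks)
    return PseudobulkMatrix(values, list(expr.gene_ids), pd.DataFrame(meta_rows))


def cycle_phase(s_score: float, g2m_score: float) -> str:
    """Phase call: the higher-scoring class when it exceeds 0.5, else G1."""
    if max(s_score, g2m_score) <= 0.5:
        return "G1"
    return "S" if s_score >= g2m_score else "G2M"


def score_cell_cycle(
    expr: ExpressionMatrix,
    s_genes: set[str],
    g2m_genes: set[str],
    seed: int = 0,
    n_bins: int = 25,
    ctrl_size: int = 50,
) -> pd.DataFrame:
    """S/G2M scores per cell plus a phase call.

    Score = mean expression of the marker set minus the mean of a seeded,
    size-matched control set drawn from expression-level bins (25 bins, 50
    controls per marker gene by default).  Phase is the argmax of the two
    scores when the maximum exceeds 0.5, else G1.
    """
    genes = set(expr.gene_ids)
    s_use = sorted(s_genes & genes)
    g2m_use = sorted(g2m_genes & genes)
    if not s_use or not g2m_use:
        raise ValidationError("a cycle gene set has empty intersection with the matrix")

    gidx = expr.gene_index()
    X = expr.values
    gene_means = X.mean(axis=1)
    order = np.argsort(gene_means, kind="stable")
    bin_of = np.empty(expr.n_genes, dtype=int)
    bin_of[order] = np.arange(expr.n_genes) * n_bins // expr.n_genes

    def _score(use: list[str], key: str) -> np.ndarray:
        rng = np.random.default_rng(_stable_seed(seed, "cycle", key))
        ctrl: set[int] = set()
        use_idx = [gidx[g] for g in use]
        for gi in use_idx:
            pool = np.flatnonzero(bin_of == bin_of[gi])
            take = min(ctrl_size, len(pool))
            ctrl.update(rng.choice(pool, size=take, replace=False).tolist())
        ctrl -= set(use_idx)
        if not ctrl:
            ctrl = set(range(expr.n_genes)) - set(use_idx)
        return X[use_idx, :].mean(axis=0) - X[sorted(ctrl), :].mean(axis=0)

    s_score = _score(s_use, "s")
    g2m_score = _score(g2m_use, "g2m")
    phase = [cycle_phase(s, g) for s, g in zip(s_score, g2m_score)]
    return pd.DataFrame(
        {"cell_id": expr.cell_ids, "s_score": s_score, "g2m_score": g2m_score, "phase": phase}
    )
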