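"""Regulon activity scoring: area under the gene-ranking recovery curve.

For one cell, genes are ranked by decreasing expression (ties broken
uniformly at random, keyed to the cell id so the result is independent of
cell order).  A regulon's activity score (RAS) is the area under the step
recovery curve of its gene set — targets plus the TF itself — within the top
``top_fraction`` of the ranking, normalised by the maximal achievable area,
so RAS lies in [0, 1].  The discrete-sum convention is used:

    raw = sum_{k=1..T} |{s in S : rank(s) <= k}|,   max = sum_{k=1..T} min(k, m)

with T = floor(top_fraction * n_genes) and m = |S|.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, Regulon, ValidationError
from .synthetic_atlas import _stable_seed


class RegulonActivityMatrix:
    """Regulon x cell matrix of RAS values in [0, 1]."""

    def __init__(self, values: np.ndarray, regulon_ids: list[str], cell_ids: list[str]):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(regulon_ids), len(cell_ids)):
            raise ValidationError("RAS shape does not match ids")
        if values.size and (values.min() < -1e-12 or values.max() > 1 + 1e-12):
            raise ValidationError("RAS entries must lie in [0, 1]")
        self.values = np.clip(values, 0.0, 1.0)
        self.regulon_ids = list(regulon_ids)
        self.cell_ids = list(cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.regulon_ids, columns=self.cell_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegulonActivityMatrix":
        return cls(df.to_numpy(), df.index.astype(str).tolist(), df.columns.astype(str).tolist())


def rank_genes_per_cell(expr: ExpressionMatrix, seed: int = 0) -> np.ndarray:
    """Gene x cell matrix of ranks (1 = highest expression per cell).

    Ties are broken uniformly at random with an RNG keyed to (seed, cell id),
    so each cell's permutation is reproducible and independent of the order
    or presence of other cells.
    """
    n_genes, n_cells = expr.values.shape
    ranks = np.empty((n_genes, n_cells), dtype=np.int32)
    for j, cell_id in enumerate(expr.cell_ids):
        rng = np.random.default_rng(_stable_seed(seed, "rank", cell_id))
        tiebreak = rng.permutation(n_genes)
        order = np.lexsort((tiebreak, -expr.values[:, j]))
        ranks[order, j] = np.arange(1, n_genes + 1)
    return ranks


def _max_recovery(T: int, m: int) -> int:
    """sum_{k=1..T} min(k, m) in closed form."""
    if m >= T:
        return T * (T + 1) // 2
    return m * (m + 1) // 2 + (T - m) * m


def aucell_score(
    ranking: "Mapping[str, int] | pd.Series",
    regulon: Regulon,
    top_fraction: float = 0.05,
) -> float:
    """RAS of one regulon for one cell, from that cell's gene ranking."""
    if isinstance(ranking, pd.Series):
        ranking = ranking.to_dict()
    n = len(ranking)
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    T = int(np.floor(top_fraction * n))
    if T == 0:
        raise ValueError("top_fraction * n_genes < 1: empty scoring window")
    gene_set = regulon.gene_set
    missing = gene_set - set(ranking)
    if missing:
        raise ValidationError(
            "regulon genes absent from ranking: %s" % sorted(missing)[:5]
        )
    m = len(gene_set)
    raw = sum(T - ranking[g] + 1 for g in gene_set if ranking[g] <= T)
    return raw / _max_recovery(T, m)


def score_all(
    expr: ExpressionMatrix,
    regulons: Iterable[Regulon],
    top_fraction: float = 0.05,
    repeats: int = 1,
    seed: int = 0,
) -> RegulonActivityMatrix:
    """RAS for every (regulon, cell); with ``repeats`` > 1 the mean over
    repeated rankings with distinct tie-breaking seeds (tie-free matrices are
    unaffected by repeats)."""
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    regulons = sorted(regulons, key=lambda r: r.tf)
    gidx = expr.gene_index()
    n = expr.n_genes
    T = int(np.floor(top_fraction * n))
    if T == 0:
        raise ValueError("top_fraction * n_genes < 1: empty scoring window")
    sets = []
    for reg in regulons:
        missing = reg.gene_set - set(gidx)
        if missing:
            raise ValidationError(
                "regulon '%s' genes absent from matrix: %s" % (reg.tf, sorted(missing)[:5])
            )
        sets.append(np.array([gidx[g] for g in sorted(reg.gene_set)]))

    total = np.zeros((len(regulons), expr.n_cells))
    for rep in range(repeats):
        ranks = rank_genes_per_cell(expr, seed=int(seed) + rep * 100003)
        for i, idx in enumerate(sets):
            r = ranks[idx, :]
            contrib = np.clip(T - r + 1, 0, None).sum(axis=0)
            total[i, :] += contrib / _max_recovery(T, len(idx))
    return RegulonActivityMatrix(
        total / repeats, [reg.name for reg in regulons], list(expr.cell_ids)
    )
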