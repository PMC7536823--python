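"""Regulon inference: co-expression importances, modules, motif pruning.

The three classic steps:

1. For every gene, a seeded gradient-boosted tree ensemble predicts its
   expression from the TF expressions; split-gain importances give a ranked
   TF -> target adjacency.
2. Per TF, a candidate module collects the targets passing any enabled rule
   (top-N by importance; importance above a per-TF percentile).
3. Each candidate module is tested for motif enrichment against a ranking
   database: recovery-curve AUC of the module inside the top fraction of
   each motif's genome-wide gene ranking, z-scored over all motifs (NES).
   Motifs annotated to the module's TF that clear the NES threshold define
   the regulon; its targets are the module genes inside those motifs'
   leading edges, so indirect (merely co-expressed) targets are pruned away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lightgbm import LGBMRegressor

from .activity import _max_recovery
from .io_formats import ExpressionMatrix, MotifRankingDB, Regulon, ValidationError


@dataclass
class AdjacencyList:
    """TF -> target importances from the co-expression step."""

    entries: pd.DataFrame  # columns: tf, target, importance
    tf_universe: list[str]

    def __post_init__(self) -> None:
        df = self.entries
        if list(df.columns) != ["tf", "target", "importance"]:
            raise ValidationError("adjacency columns must be (tf, target, importance)")
        if (df["tf"] == df["target"]).any():
            raise ValidationError("adjacency contains self edges")
        imp = df["importance"].to_numpy(dtype=float)
        if not np.isfinite(imp).all() or (imp < 0).any():
            raise ValidationError("importances must be finite and non-negative")

    def for_tf(self, tf: str) -> pd.DataFrame:
        return self.entries[self.entries["tf"] == tf]


@dataclass(frozen=True)
class MotifEnrichment:
    motif_id: str
    tf: str | None
    auc: float
    nes: float
    leading_edge: frozenset[str]


@dataclass(frozen=True)
class ModuleRules:
    """Candidate-module rules; a rule set to None is disabled."""

    top_n: int | None = 50
    importance_percentile: float | None = 90.0


def infer_coexpression(
    expr: ExpressionMatrix,
    tf_list: list[str],
    n_trees: int = 200,
    seed: int = 0,
) -> AdjacencyList:
    """Per-target gradient-boosted regression of expression on TF expression.

    Every gene in the matrix (TFs included, each excluding itself as its own
    predictor) is regressed on the TF expressions with a seeded LightGBM
    ensemble of ``n_trees`` shallow trees; split-gain importances are
    emitted.  Constant target genes yield all-zero importances.
    """
    if expr.n_cells < 2:
        raise ValidationError("co-expression inference needs >= 2 cells")
    genes = set(expr.gene_ids)
    unknown = set(tf_list) - genes
    if unknown:
        raise ValidationError("TFs absent from matrix: %s" % sorted(unknown)[:5])
    tf_list = sorted(tf_list)
    gidx = expr.gene_index()
    X_all = expr.values[[gidx[t] for t in tf_list], :].T.astype(np.float64)  # cells x TFs

    rows = []
    for i, gene in enumerate(expr.gene_ids):
        y = expr.values[i, :].astype(np.float64)
        if np.ptp(y) == 0:
            continue  # constant target: all-zero importances, nothing to emit
        if gene in tf_list:
            keep = [j for j, t in enumerate(tf_list) if t != gene]
            if not keep:
                continue
            X = X_all[:, keep]
            predictors = [tf_list[j] for j in keep]
        else:
            X = X_all
            predictors = tf_list
        model = LGBMRegressor(
            n_estimators=n_trees,
            learning_rate=0.05,
            num_leaves=4,
            min_child_samples=max(2, min(20, expr.n_cells // 10)),
            importance_type="gain",
            random_state=(int(seed) + i) % (2**31),
            n_jobs=1,
            verbose=-1,
            deterministic=True,
            force_row_wise=True,
        )
        model.fit(X, y)
        imp = model.feature_importances_.astype(float)
        for tf, w in zip(predictors, imp):
            if w > 0:
                rows.append((tf, gene, w))
    entries = pd.DataFrame(rows, columns=["tf", "target", "importance"])
    entries = entries.sort_values(["tf", "importance", "target"], ascending=[True, False, True])
    return AdjacencyList(entries.reset_index(drop=True), tf_list)


def build_tf_modules(
    adj: AdjacencyList, rules: ModuleRules = ModuleRules()
) -> dict[str, frozenset[str]]:
    """Per-TF candidate target modules: union of targets passing any rule."""
    modules: dict[str, frozenset[str]] = {}
    for tf, sub in adj.entries.groupby("tf", sort=True):
        sub = sub.sort_values(["importance", "target"], ascending=[False, True])
        selected: set[str] = set()
        if rules.top_n is not None:
            selected |= set(sub["target"].head(rules.top_n))
        if rules.importance_percentile is not None:
            cut = np.percentile(sub["importance"], rules.importance_percentile)
            selected |= set(sub.loc[sub["importance"] > cut, "target"])
        if selected:
            modules[str(tf)] = frozenset(selected)
    return modules


def _module_recovery_auc(ranks: np.ndarray, T: int, m: int) -> float:
    raw = np.clip(T - ranks + 1, 0, None).sum()
    return float(raw) / _max_recovery(T, m)


def motif_enrichment(
    tf: str,
    module_genes: frozenset[str],
    db: MotifRankingDB,
    rank_threshold_fraction: float = 0.05,
) -> list[MotifEnrichment]:
    """Recovery-AUC of the module inside every motif's top-ranked window,
    z-scored across motifs (NES); leading edge = module genes ranked within
    the window."""
    genes = set(db.gene_ids)
    missing = module_genes - genes
    if missing:
        raise ValidationError(
            "module genes absent from motif database: %s" % sorted(missing)[:5]
        )
    n = len(db.gene_ids)
    T = int(np.floor(rank_threshold_fraction * n))
    if T == 0:
        raise ValueError("rank_threshold_fraction * n_genes < 1")
    module = sorted(module_genes)
    m = len(module)
    R = db.rankings[module].to_numpy()  # motifs x module genes
    aucs = np.array([_module_recovery_auc(R[i], T, m) for i in range(R.shape[0])])
    sd = aucs.std(ddof=0)
    nes = (aucs - aucs.mean()) / sd if sd > 1e-15 else np.zeros_like(aucs)
    out = []
    for i, motif in enumerate(db.motif_ids):
        ranks = db.rankings.loc[motif, module].to_numpy()
        leading = frozenset(g for g, r in zip(module, ranks) if r <= T)
        out.append(
            MotifEnrichment(motif, db.annotation.get(motif), float(aucs[i]), float(nes[i]), leading)
        )
    return out


def prune_to_regulons(
    modules: dict[str, frozenset[str]],
    enrichments: dict[str, list[MotifEnrichment]],
    adjacency: AdjacencyList,
    nes_threshold: float = 3.0,
) -> list[Regulon]:
    """Keep, per TF, the motifs annotated to it with NES >= threshold; the
    regulon's targets are the module genes covered by those motifs' leading
    edges, with importances inherited from the adjacency.  TFs with no kept
    motif (or an emptied target set) produce no regulon."""
    regulons = []
    for tf in sorted(modules):
        if tf not in enrichments:
            raise ValidationError("no enrichment computed for module of '%s'" % tf)
        kept = [
            e for e in enrichments[tf] if e.tf == tf and e.nes >= nes_threshold
        ]
        if not kept:
            continue
        leading_union: frozenset[str] = frozenset().union(*(e.leading_edge for e in kept))
        targets = (modules[tf] & leading_union) - {tf}
        if not targets:
            continue
        weights = dict(
            zip(adjacency.for_tf(tf)["target"], adjacency.for_tf(tf)["importance"])
        )
        regulons.append(
            Regulon(
                tf,
                targets,
                {t: float(weights.get(t, 0.0)) for t in targets},
                frozenset(e.motif_id for e in kept),
            )
        )
    return regulons
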