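"""End-to-end workflow: synthesise -> harmonise -> preprocess -> grn ->
score -> network -> evaluate.

Configuration is a flat YAML mapping of stage name to parameter map (plus
top-level ``outdir`` and ``seed``); every random stage takes an explicit
seed defaulting to the global one.  Each stage reads the artifacts earlier
stages wrote under ``outdir`` and writes its own, so stages can be re-run
individually; a stage invoked before its inputs exist raises a
DependencyError naming the missing stage.  Re-running the same config
reproduces identical outputs.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from . import grn_inference as grn
from . import harmonise as hm
from . import network as nw
from . import preprocess as pp
from . import synthetic_atlas as synth
from .activity import RegulonActivityMatrix, score_all
from .io_formats import (
    UNASSIGNED,
    CellAnnotation,
    DependencyError,
    ExpressionMatrix,
    read_annotation,
    read_expression,
    read_json,
    read_motif_db,
    read_regulons,
    write_annotation,
    write_expression,
    write_json,
    write_motif_db,
    write_regulons,
)

log = logging.getLogger("regulonatlas")

STAGES = ["synth", "harmonise", "preprocess", "grn", "score", "network", "evaluate"]

DEFAULT_CONFIG: dict = {
    "outdir": "regulonatlas_run",
    "seed": 0,
    "synth": {
        "enabled": True,
        "low_noise": False,
        "decoy_motifs": 100,
        "ranking_noise": 0.0,
        **synth.DEFAULT_SCALE,
    },
    "harmonise": {"n_features": 500, "threshold": 0.7, "reference_atlas": None},
    "preprocess": {"cells_per_sample": 50, "expressed_fraction": 0.10},
    "grn": {
        "n_trees": 200,
        "top_n": 50,
        "importance_percentile": 90.0,
        "rank_threshold_fraction": 0.05,
        "nes_threshold": 3.0,
    },
    "score": {"top_fraction": 0.05, "repeats": 1},
    "network": {"delta": 0.05, "edge_threshold": 0.7, "n_modules": 5},
    "evaluate": {},
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    for key, value in (overrides or {}).items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _stage_seed(cfg: dict, stage: str) -> int:
    return int(cfg[stage].get("seed", cfg["seed"]))


def _require(outdir: Path, relpath: str, stage: str, produced_by: str) -> Path:
    p = outdir / relpath
    if not p.exists():
        raise DependencyError(
            "stage '%s' requires '%s' produced by stage '%s'; run that stage first"
            % (stage, relpath, produced_by)
        )
    return p


# ---------------------------------------------------------------------------
# artifact helpers
# ---------------------------------------------------------------------------


def _atlas_names(outdir: Path) -> list[str]:
    names = read_json(outdir / "atlases.json")["atlases"]
    return list(names)


def _read_combined_expression(outdir: Path, stage: str) -> tuple[ExpressionMatrix, CellAnnotation]:
    _require(outdir, "atlases.json", stage, "synth")
    names = _atlas_names(outdir)
    mats = [read_expression(outdir / ("expression_%s" % n), "mtx") for n in names]
    genes = mats[0].gene_ids
    values = np.concatenate([m.values for m in mats], axis=1)
    cells = [c for m in mats for c in m.cell_ids]
    annotation = read_annotation(_require(outdir, "annotation.tsv", stage, "synth"))
    return ExpressionMatrix(values, genes, cells), annotation


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_synth(outdir: Path, cfg: dict) -> None:
    p = cfg["synth"]
    seed = _stage_seed(cfg, "synth")
    if not p.get("enabled", True):
        _import_inputs(outdir, p)
        return
    log.info("synth: generating ground truth and %d atlases", p["n_atlases"])
    truth = synth.generate_ground_truth(
        n_tfs=p["n_tfs"],
        n_targets=p["n_targets"],
        n_modules=p["n_modules"],
        n_cell_types=p["n_cell_types"],
        n_groups=p["n_groups"],
        seed=seed,
        n_genes=p["n_genes"],
    )
    profiles = synth.default_profiles(
        p["n_atlases"], p["cells_per_atlas"], low_noise=p.get("low_noise", False)
    )
    tables = []
    for profile in profiles:
        expr, ann = synth.generate_atlas(truth, profile, seed=seed)
        write_expression(expr, outdir / ("expression_%s" % profile.name), "mtx")
        tables.append(ann.table)
    write_annotation(CellAnnotation(pd.concat(tables, ignore_index=True)), outdir / "annotation.tsv")
    db = synth.generate_motif_db(
        truth, decoy_motifs=p.get("decoy_motifs", 100),
        ranking_noise=p.get("ranking_noise", 0.0), seed=seed,
    )
    write_motif_db(db, outdir / "motif_rankings.tsv", outdir / "motif_annotation.tsv")
    write_json(truth.to_json_dict(), outdir / "ground_truth.json")
    write_json({"atlases": [pr.name for pr in profiles],
                "granularity": {pr.name: pr.label_granularity for pr in profiles}},
               outdir / "atlases.json")
    pd.DataFrame(
        sorted(truth.type_to_group.items()), columns=["reference_type", "cell_group"]
    ).to_csv(outdir / "vocabulary.tsv", sep="\t", index=False)


def _import_inputs(outdir: Path, p: dict) -> None:
    """Real-data mode: copy user-supplied inputs into the artifact layout."""
    inputs = p.get("inputs")
    if not inputs:
        raise DependencyError(
            "stage 'synth' disabled but no 'inputs' listed in the synth section"
        )
    names = []
    for item in inputs["expression"]:
        expr = read_expression(item["path"], item.get("format", "mtx"))
        write_expression(expr, outdir / ("expression_%s" % item["atlas"]), "mtx")
        names.append(item["atlas"])
    write_annotation(read_annotation(inputs["annotation"]), outdir / "annotation.tsv")
    db = read_motif_db(inputs["motif_rankings"], inputs["motif_annotation"])
    write_motif_db(db, outdir / "motif_rankings.tsv", outdir / "motif_annotation.tsv")
    write_json({"atlases": names, "granularity": {}}, outdir / "atlases.json")
    vocab = pd.read_csv(inputs["vocabulary"], sep="\t")
    vocab.to_csv(outdir / "vocabulary.tsv", sep="\t", index=False)


def stage_harmonise(outdir: Path, cfg: dict) -> None:
    p = cfg["harmonise"]
    names = _atlas_names(_require(outdir, "atlases.json", "harmonise", "synth").parent)
    annotation = read_annotation(_require(outdir, "annotation.tsv", "harmonise", "synth"))
    vocab_df = pd.read_csv(_require(outdir, "vocabulary.tsv", "harmonise", "synth"), sep="\t")
    vocabulary = hm.ReferenceVocabulary(
        vocab_df["reference_type"].tolist(),
        dict(zip(vocab_df["reference_type"], vocab_df["cell_group"])),
    )
    granularity = read_json(outdir / "atlases.json").get("granularity", {})
    reference = p.get("reference_atlas") or next(
        (n for n in names if granularity.get(n) == "reference"), names[0]
    )
    log.info("harmonise: reference atlas '%s'", reference)

    raw = {n: read_expression(outdir / ("expression_%s" % n), "mtx") for n in names}
    features_per_atlas = [
        hm.select_projection_features(raw[n], p["n_features"]) for n in names
    ]
    common = set(features_per_atlas[0])
    for feats in features_per_atlas[1:]:
        common &= set(feats)
    features = sorted(common)
    if len(features) < 10:
        features = sorted(set().union(*map(set, features_per_atlas)))
    log.info("harmonise: %d common projection features", len(features))

    normed = {n: pp.normalise(raw[n]) for n in names}
    ann = annotation.table.set_index("cell_id")
    ref_labels = ann.loc[normed[reference].cell_ids, "author_label"]
    centroids = hm.compute_centroids(normed[reference], ref_labels, features)

    frames = []
    for n in names:
        proj = hm.project_cells(normed[n], centroids, threshold=p["threshold"])
        if n == reference:
            # the reference atlas keeps its author labels (they define the
            # reference types); projection columns retained for inspection
            proj = proj.copy()
            proj["assigned_type"] = ann.loc[proj.index, "author_label"]
        frames.append(proj)
    projections = pd.concat(frames)
    harmonised, contingency = hm.build_integrated_annotation(
        projections, vocabulary, annotation
    )
    write_annotation(harmonised, outdir / "annotation_harmonised.tsv")
    contingency.to_csv(outdir / "contingency.tsv", sep="\t")
    projections.to_csv(outdir / "projections.tsv", sep="\t")

    summary = {
        "reference_atlas": reference,
        "n_features": len(features),
        "n_cells": len(projections),
        "n_assigned": int((projections["assigned_type"] != UNASSIGNED).sum()),
    }
    truth_file = outdir / "ground_truth.json"
    if truth_file.exists():
        truth = synth.SyntheticGroundTruth.from_json_dict(read_json(truth_file))
        truth_types = annotation.lookup("reference_type")
        non_ref = projections.index.difference(normed[reference].cell_ids)
        summary["accuracy_projected_atlases"] = ev.harmonisation_accuracy(
            projections.loc[non_ref, "assigned_type"], truth_types
        )
        summary["accuracy_all"] = ev.harmonisation_accuracy(
            projections["assigned_type"], truth_types
        )
    write_json(summary, outdir / "harmonise_summary.json")


def stage_preprocess(outdir: Path, cfg: dict) -> None:
    p = cfg["preprocess"]
    seed = _stage_seed(cfg, "preprocess")
    expr, _ = _read_combined_expression(outdir, "preprocess")
    harmonised = read_annotation(
        _require(outdir, "annotation_harmonised.tsv", "preprocess", "harmonise")
    )
    kept = hm.mapped_cells(harmonised)
    log.info("preprocess: %d of %d cells retained after harmonisation", len(kept), expr.n_cells)
    expr = expr.subset_cells(kept)
    normed = pp.normalise(expr)
    pseudo = pp.make_pseudobulk(
        normed, harmonised.subset(normed.cell_ids),
        cells_per_sample=p["cells_per_sample"], seed=seed,
    )
    features = pp.select_expressed_features(
        pseudo.to_expression(), p["expressed_fraction"]
    )
    pseudo.to_expression().to_frame().to_csv(outdir / "pseudobulk.tsv", sep="\t")
    pseudo.sample_meta.to_csv(outdir / "pseudobulk_meta.tsv", sep="\t", index=False)
    pd.Series(features).to_csv(outdir / "features.txt", index=False, header=False)
    write_json(
        {"n_samples": len(pseudo.sample_ids), "n_features": len(features),
         "n_cells_retained": len(kept)},
        outdir / "preprocess_summary.json",
    )


def _read_pseudobulk(outdir: Path, stage: str) -> tuple[ExpressionMatrix, pd.DataFrame]:
    df = pd.read_csv(_require(outdir, "pseudobulk.tsv", stage, "preprocess"), sep="\t", index_col=0)
    meta = pd.read_csv(_require(outdir, "pseudobulk_meta.tsv", stage, "preprocess"), sep="\t")
    expr = ExpressionMatrix(
        df.to_numpy(), df.index.astype(str).tolist(), df.columns.astype(str).tolist(),
        normalised=True,
    )
    return expr, meta


def stage_grn(outdir: Path, cfg: dict) -> None:
    p = cfg["grn"]
    seed = _stage_seed(cfg, "grn")
    pseudo, _ = _read_pseudobulk(outdir, "grn")
    features = pd.read_csv(
        _require(outdir, "features.txt", "grn", "preprocess"), header=None
    )[0].astype(str).tolist()
    db = read_motif_db(
        _require(outdir, "motif_rankings.tsv", "grn", "synth"),
        _require(outdir, "motif_annotation.tsv", "grn", "synth"),
    )
    tf_list = sorted(set(db.annotation.values()) & set(pseudo.gene_ids))
    use_genes = sorted(set(features) | set(tf_list))
    matrix = pseudo.subset_genes(use_genes)
    log.info("grn: %d TFs, %d genes, %d pseudobulk samples",
             len(tf_list), matrix.n_genes, matrix.n_cells)
    adj = grn.infer_coexpression(matrix, tf_list, n_trees=p["n_trees"], seed=seed)
    adj.entries.to_csv(outdir / "adjacency.tsv", sep="\t", index=False, float_format="%.10g")
    modules = grn.build_tf_modules(
        adj, grn.ModuleRules(p["top_n"], p["importance_percentile"])
    )
    enrichments = {
        tf: grn.motif_enrichment(tf, genes, db, p["rank_threshold_fraction"])
        for tf, genes in modules.items()
    }
    regulons = grn.prune_to_regulons(modules, enrichments, adj, p["nes_threshold"])
    log.info("grn: %d regulons", len(regulons))
    write_regulons(regulons, outdir / "regulons.gmt")


def stage_score(outdir: Path, cfg: dict) -> None:
    p = cfg["score"]
    seed = _stage_seed(cfg, "score")
    regulons = read_regulons(_require(outdir, "regulons.gmt", "score", "grn"))
    expr, _ = _read_combined_expression(outdir, "score")
    harmonised = read_annotation(
        _require(outdir, "annotation_harmonised.tsv", "score", "harmonise")
    )
    normed = pp.normalise(expr.subset_cells(hm.mapped_cells(harmonised)))
    ras_sc = score_all(normed, regulons, p["top_fraction"], p["repeats"], seed)
    pseudo, _ = _read_pseudobulk(outdir, "score")
    ras_pb = score_all(pseudo, regulons, p["top_fraction"], p["repeats"], seed)
    header = "# top_fraction=%s repeats=%s seed=%s\n" % (p["top_fraction"], p["repeats"], seed)
    for name, ras in [("ras.tsv", ras_sc), ("ras_pseudobulk.tsv", ras_pb)]:
        with open(outdir / name, "w") as fh:
            fh.write(header)
            ras.to_frame().to_csv(fh, sep="\t", float_format="%.10g")


def read_ras(path: Path) -> RegulonActivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return RegulonActivityMatrix.from_frame(df)


def stage_network(outdir: Path, cfg: dict) -> None:
    p = cfg["network"]
    ras = read_ras(_require(outdir, "ras_pseudobulk.tsv", "network", "score"))
    pcc = nw.compute_pcc(ras)
    csi = nw.compute_csi(pcc, delta=p["delta"])
    n_modules = min(p["n_modules"], csi.shape[0])
    modules = nw.cluster_modules(csi, n_modules=n_modules)
    net = nw.build_network(csi, modules, edge_threshold=p["edge_threshold"])
    feats = nw.network_features(net)
    pcc.to_csv(outdir / "pcc.tsv", sep="\t", float_format="%.10g")
    csi.to_csv(outdir / "csi.tsv", sep="\t", float_format="%.10g")
    pd.DataFrame(net.edges, columns=["source", "target"]).to_csv(
        outdir / "network.tsv", sep="\t", index=False
    )
    feats.to_csv(outdir / "node_features.tsv", sep="\t", float_format="%.10g")


def stage_evaluate(outdir: Path, cfg: dict) -> None:
    seed = _stage_seed(cfg, "evaluate")
    regulons = read_regulons(_require(outdir, "regulons.gmt", "evaluate", "grn"))
    ras_sc = read_ras(_require(outdir, "ras.tsv", "evaluate", "score"))
    ras_pb = read_ras(_require(outdir, "ras_pseudobulk.tsv", "evaluate", "score"))
    csi = pd.read_csv(_require(outdir, "csi.tsv", "evaluate", "network"), sep="\t", index_col=0)
    feats = pd.read_csv(
        _require(outdir, "node_features.tsv", "evaluate", "network"), sep="\t", index_col=0
    )
    modules = dict(zip(feats.index, feats["module"].astype(int)))
    _, meta = _read_pseudobulk(outdir, "evaluate")
    synth_ann = read_annotation(_require(outdir, "annotation.tsv", "evaluate", "synth"))

    # group labels for evaluation come from the generator's planted truth
    truth_group = synth_ann.lookup("cell_group")
    truth_type = synth_ann.lookup("reference_type")
    sc_groups = truth_group.loc[ras_sc.cell_ids]
    member_lists = [m.split(";") for m in meta["member_cells"]]
    pb_groups = pd.Series(
        [truth_group.loc[m].mode().iloc[0] for m in member_lists],
        index=meta["sample_id"].tolist(),
    ).loc[ras_pb.cell_ids]
    k = int(pd.concat([sc_groups, pb_groups]).nunique())

    metrics: dict = {"n_regulons": len(regulons)}

    pred_pb = ev.kmeans_labels(ras_pb.values.T, k, seed=seed)
    pred_sc = ev.kmeans_labels(ras_sc.values.T, k, seed=seed)
    metrics["ami_pseudobulk"], metrics["completeness_pseudobulk"] = ev.clustering_agreement(
        pred_pb, pb_groups
    )
    metrics["ami_single_cell"], metrics["completeness_single_cell"] = ev.clustering_agreement(
        pred_sc, sc_groups
    )
    metrics["silhouette_pseudobulk"] = ev.silhouette(ras_pb.values.T, pb_groups)
    metrics["silhouette_single_cell"] = ev.silhouette(ras_sc.values.T, sc_groups)

    def _gini_median(ras: RegulonActivityMatrix) -> float:
        vals = [
            nw.gini(row) for row in ras.values if row.sum() > 0
        ]
        return float(np.median(vals)) if vals else float("nan")

    metrics["gini_median_pseudobulk"] = _gini_median(ras_pb)
    metrics["gini_median_single_cell"] = _gini_median(ras_sc)

    pb_pts, sc_pts = ev.pca_project(ras_pb.values.T, ras_sc.values.T, n_components=2)
    metrics["mean_centroid_distance_pseudobulk"] = float(
        ev.centroid_distances(pb_pts, pb_groups).mean()
    )
    metrics["mean_centroid_distance_single_cell"] = float(
        ev.centroid_distances(sc_pts, sc_groups).mean()
    )

    truth_file = outdir / "ground_truth.json"
    if truth_file.exists():
        truth = synth.SyntheticGroundTruth.from_json_dict(read_json(truth_file))
        recovery = ev.recover_ground_truth(
            regulons, modules, truth, ras=ras_sc, cell_types=truth_type
        )
        metrics["median_target_jaccard"] = recovery["median_jaccard"]
        metrics["module_ari"] = recovery["module_ari"]
        metrics["mean_ras_specificity"] = recovery["mean_ras_specificity"]
        pd.Series(recovery["per_tf_jaccard"]).rename("jaccard").to_csv(
            outdir / "recovery_per_tf.tsv", sep="\t"
        )
        ppi = pd.DataFrame(
            [[*sorted(pair), conf] for pair, conf in truth.ppi_pairs.items()],
            columns=["gene_a", "gene_b", "confidence"],
        ).sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
        net = nw.build_network(
            csi, modules, edge_threshold=cfg["network"]["edge_threshold"]
        )
        try:
            validation = ev.validate_network(net, ppi, truth.essential_tfs, csi=csi)
            metrics["edge_validation_fraction"] = validation["edge_validation_fraction"]
            metrics["essential_node_fraction"] = validation["essential_node_fraction"]
            metrics["n_network_edges"] = validation["n_edges"]
            pd.Series(validation["per_bin_counts"]).rename("count").to_csv(
                outdir / "validation_bins.tsv", sep="\t"
            )
        except Exception as exc:  # no edges: report and move on
            metrics["edge_validation_fraction"] = float("nan")
            metrics["n_network_edges"] = 0
            log.warning("network validation skipped: %s", exc)

    harm_file = outdir / "harmonise_summary.json"
    if harm_file.exists():
        summary = read_json(harm_file)
        for key in ("accuracy_projected_atlases", "accuracy_all"):
            if key in summary:
                metrics["harmonisation_%s" % key] = summary[key]

    metrics = {
        k: (round(v, 10) if isinstance(v, float) and np.isfinite(v) else v)
        for k, v in metrics.items()
    }
    write_json(metrics, outdir / "metrics.json")


STAGE_FUNCS = {
    "synth": stage_synth,
    "harmonise": stage_harmonise,
    "preprocess": stage_preprocess,
    "grn": stage_grn,
    "score": stage_score,
    "network": stage_network,
    "evaluate": stage_evaluate,
}


def run_stage(stage: str, cfg: dict) -> Path:
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    STAGE_FUNCS[stage](outdir, cfg)
    return outdir


def run_pipeline(config: "str | Path | dict") -> Path:
    """Run every stage in order; returns the artifact directory."""
    cfg = config if isinstance(config, dict) else load_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    write_json({"config": _jsonable(cfg)}, outdir / "run_log.json")
    for stage in STAGES:
        log.info("=== stage %s ===", stage)
        STAGE_FUNCS[stage](outdir, cfg)
    return outdir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
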