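# regulonatlas

Gene-regulatory-network analysis across single-cell transcriptomic atlases.

Large mouse single-cell atlases (droplet 3′, full-length plate, microwell)
profile overlapping cell types under very different technical regimes and
annotate them with incompatible author vocabularies. `regulonatlas`
implements an integrated workflow that turns several such atlases into a
consensus regulatory map:

1. **Harmonisation** — author cell-type labels from every atlas are mapped
   onto one reference vocabulary (reference cell types grouped into broad
   cell groups) by unsupervised centroid projection: per-type median
   centroids on a dropout-informed feature set, with cosine, Pearson and
   Spearman similarity each voting per cell and a consensus/threshold rule
   deciding the assignment (non-mapping cells are excluded).
2. **Pseudobulk** — disjoint random 50-cell samples within each
   (atlas, tissue, author label) stratum, averaged gene-wise over non-zero
   members, to suppress dropout noise.
3. **Regulon inference** — per-gene gradient-boosted tree ensembles rank
   TF → target importances; candidate modules per TF are pruned to *direct*
   targets by motif enrichment against a ranking database (recovery-curve
   AUC, z-scored across motifs into an NES; motifs annotated to the TF with
   NES ≥ 3 define the regulon).
4. **Activity scoring (RAS)** — each regulon is scored per cell as the area
   under the recovery curve of its gene set within the top 5% of that
   cell's expression ranking:
   `RAS = Σ_{k=1..T} |{s ∈ S : rank(s) ≤ k}| / Σ_{k=1..T} min(k, |S|)` ∈ [0, 1].
5. **Regulon network** — from the regulon × regulon Pearson correlation
   (PCC) the connection specificity index
   `CSI(A,B) = 1 − |{C : PCC(C,A) ≥ PCC(A,B) − 0.05 or PCC(C,B) ≥ PCC(A,B) − 0.05}| / n`
   isolates specific partners; average-linkage clustering of CSI rows gives
   regulon modules, and pairs with CSI > 0.7 form an undirected, unweighted
   network with degree / closeness / betweenness / eigenvector features.
6. **Evaluation** — AMI, completeness, silhouette and per-regulon Gini
   coefficients compare pseudobulk against single-cell activity; the network
   is validated against an annotated protein-interaction table and an
   essential-gene list; on synthetic data the planted ground truth is scored
   directly (per-TF target Jaccard, module ARI).

Because the real atlases are hundreds of thousands of cells behind
downloads, the package ships a first-class **synthetic multi-atlas
generator**: ≥3 atlases with different depth/dropout regimes and label
granularities, sharing a planted TF → target structure organised into
co-active modules with cell-type-specific activity, plus a matched motif
ranking database, interaction table and essential-TF list. Every downstream
stage is tested against that planted truth.

## Worked example

The scoring primitives on hand-checkable inputs:

```python
import pandas as pd
import regulonatlas as ra

# RAS of a 2-gene regulon whose genes sit at ranks 1 and 3 of a
# 100-gene ranking, scored in the top-5% window (T = 5)
genes = [f"g{i:03d}" for i in range(100)]
ranking = dict(zip(genes, range(1, 101)))
regulon = ra.Regulon("g000", {"g002"}, {"g002": 1.0})
print("RAS =", round(ra.aucell_score(ranking, regulon, top_fraction=0.05), 4))

# CSI of a correlated pair (PCC 0.9) against an uncorrelated bystander
pcc = pd.DataFrame([[1.0, 0.9, 0.1], [0.9, 1.0, 0.1], [0.1, 0.1, 1.0]],
                   index=list("ABC"), columns=list("ABC"))
print("CSI(A,B) =", round(ra.compute_csi(pcc, delta=0.05).loc["A", "B"], 4))

# Gini of a maximally group-specific activity vector
print("Gini =", ra.gini([0.0, 0.0, 0.0, 1.0]))
```

prints

```
RAS = 0.8889
CSI(A,B) = 0.3333
Gini = 0.75
```

RAS 8/9 is the recovery area of ranks {1, 3} relative to the best possible
curve; CSI 1/3 because only A and B themselves correlate with the pair at
the 0.85 level, so 1 − 2/3; Gini (n−1)/n = 0.75 for a single spike.

The full pipeline at the default study scale (3 atlases × 3,000 cells ×
1,500 genes; 25 TFs in 5 modules; 12 cell types in 6 groups):

```python
import json
from regulonatlas.pipeline import load_config, run_pipeline

cfg = load_config(overrides={"outdir": "run_out", "seed": 1})
out = run_pipeline(cfg)          # ~40 s on one CPU
print(json.load(open(out / "metrics.json")))
```

Key numbers this prints (seed 1): 24 of 25 planted regulons recovered with
`median_target_jaccard: 0.8` and `module_ari: 1.0`; harmonisation maps
97.2% of projected-atlas cells to their true reference type
(`harmonisation_accuracy_projected_atlases: 0.9715`); pseudobulk beats
single cells on cluster agreement (`ami_pseudobulk: 0.6246` vs
`ami_single_cell: 0.6244`) and on median per-regulon Gini (`0.5490` vs
`0.5225`); all 46 CSI > 0.7 network edges fall on planted within-module TF
pairs (`edge_validation_fraction: 1.0`).

The same workflow is available from the shell:

```bash
regulonatlas run --seed 1 --outdir run_out            # full pipeline
regulonatlas synth --config my.yaml                   # one stage at a time
```

Stage parameters live in a flat YAML config (stage → parameter map); see
`regulonatlas.pipeline.DEFAULT_CONFIG` for every knob and its default.

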