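# Methods

This note documents the models, conventions and design choices behind
`regulonatlas`, in the order the pipeline runs. Parameter defaults are in
parentheses; all of them are exposed through the YAML config.

## Synthetic multi-atlas generator

The generator defines the study conditions under which the pipeline is
tested. It plants:

- **TFs and modules.** `n_tfs` (25) transcription factors partitioned
  round-robin into `n_modules` (5) co-active modules.
- **Cell types and groups.** `n_cell_types` (12) reference types, each
  assigned a *distinct* subset of active modules (subsets enumerated by
  size, then lexicographically). Distinct signatures make types separable
  in principle; the module-subset construction caps the number of types at
  `2^K − 1` for K modules. Types are chunked, in signature order, into
  `n_groups` (6) cell groups, so types sharing a primary module tend to
  share a group.
- **Activity profiles.** Per type, module-level activity is drawn high
  (U(0.7, 1.0)) for active modules and low (U(0, 0.15)) otherwise. Each
  TF inherits its module's profile plus Gaussian jitter whose variance is
  calibrated from the realised module-signal variance so that
  within-module activity profiles keep Pearson correlation at or above a
  configured floor (0.8), while between-module profiles are uncorrelated
  in expectation. Every type is guaranteed ≥1 TF with activity ≥ 0.5.
- **Targets.** Each TF regulates `n_targets` (20) genes sampled from the
  non-TF pool with positive (activating) weights U(1, 3). Only activating
  regulons are modelled throughout the package.
- **Interaction truth.** The planted protein-interaction table contains
  exactly the within-module TF pairs (confidence U(0.5, 1)); 40% of TFs
  are marked essential. These drive the network-validation statistics.

**Count model.** A cell of type *c* has expected expression proportional to
`baseline_g · (1 + Σ_t w(t,g) · activity(t,c))` for targets and
`baseline_g · (0.2 + 2 · activity)` for TFs — TFs are expressed genes whose
level tracks their activity, which is what gives the co-expression step its
signal. Per-cell library sizes are log-normal around the atlas's mean
depth (CV 0.3); counts are negative binomial with a shared per-gene
dispersion (0.2), the standard scRNA-seq overdispersion stand-in.

**Dropout.** Excess zeros are injected on top of the NB zero mass with
probability logistic in a gene's log mean expression
(`1/(1 + exp(k(log μ − m)))`): the midpoint *m* is the log-mean at 50%
dropout, the steepness *k* > 0 sharpens the transition. This reproduces the
familiar mean–dropout curves and makes dropout a per-atlas technical
property. The three default profiles emulate a mid-depth droplet reference
atlas (6,000 counts/cell, reference-granularity labels), a deep full-length
atlas (20,000 counts/cell, labels split 2-fold finer) and a shallow
microwell atlas (2,000 counts/cell, coarse group-level labels). Low-noise
mode keeps the label structure but removes injected dropout and equalises
depth; it is used to measure harmonisation accuracy in the regime where the
method's ceiling should be reached.

The reference-granularity atlas always covers **all** planted cell types —
its label set defines the shared vocabulary, and a type absent from the
reference would be unmappable by construction. Non-reference atlases each
drop two types so atlases overlap without coinciding.

What the generator does *not* emulate: UMI duplication, ambient RNA,
doublets, batch effects within an atlas, cell-cycle structure, or realistic
gene–gene correlation beyond the planted regulons. Passing tests therefore
demonstrate correctness of the pipeline's statistics and its ability to
recover a planted signal through realistic depth/dropout differences — not
performance on real tissue.

## Harmonisation

Feature selection fits a linear trend of log dropout rate on log mean
expression and keeps the `n_features` (500) genes with the largest positive
residual — genes dropping out more than their mean predicts, i.e. genes
whose zeros are informative about cell type. Per-atlas selections are
intersected. Zero-dropout genes cannot exceed the trend and rank last;
all-zero genes are excluded.

Centroids are per-type medians of library-size-normalised log1p expression
over the selected features. Every cell is compared to every centroid under
cosine, Pearson and Spearman similarity; each measure votes for its argmax
type, and a cell is assigned when ≥2 measures agree and the best similarity
among the agreeing measures is ≥ `threshold` (0.7) — otherwise UNASSIGNED
and excluded from all later stages. A zero-variance cell makes Pearson and
Spearman abstain, which can never produce the two agreeing votes required.
The agreement rule itself is this package's declared convention (the
projection tool it mirrors does not document one beyond its defaults).

The reference atlas keeps its author labels; harmonisation accuracy is
always reported against the generator's planted types.

## Preprocessing

Normalisation scales every cell to the **median** library size and applies
log1p; zero-library cells are dropped with a warning. A separate
regress-and-scale operation (per-gene least-squares residuals on library
size and mitochondrial fraction, then z-scaling) is provided for
embedding-style analyses; it is not part of the regulon path, which — like
the preprocessing the inference step expects — uses no gene scaling.

Pseudobulk samples: within each (atlas, tissue, author label) stratum of
*n* cells, `floor(n / cells_per_sample)` disjoint samples of
`cells_per_sample` (50) cells are drawn without replacement. Sampling is
keyed to sorted cell ids, so results are independent of cell order.
Per sample, a gene's value is the mean over members with *non-zero*
expression (0 if all members are zero): averaging only detected values
keeps the scale of expressed genes rather than shrinking everything toward
zero with the dropout rate. Strata below the sample size produce nothing,
which silently removes very rare author-assigned types — intended
behaviour. The number of samples per stratum (all disjoint) maximises
independence between samples.

The expressed-gene filter keeps genes non-zero in ≥ `fraction` (10%) of
pseudobulk samples; the boundary is inclusive.

Cell-cycle scores are mean marker expression minus the mean of a seeded
size-matched control set drawn from 25 expression bins (50 controls per
marker); phase is the argmax of the S and G2M scores when the maximum
exceeds 0.5, else G1.

## Regulon inference

Co-expression: for every gene (TFs included, excluding themselves as
predictors), a LightGBM ensemble (`n_trees` = 200, learning rate 0.05,
4 leaves, single-threaded, seeded per target) predicts its expression from
TF expression; split-gain importances form the adjacency. The default
input is the pseudobulk matrix restricted to the expressed-feature set plus
the TFs — pseudobulk is the representation the pipeline argues is the more
robust one, and it is ~60× smaller than the single-cell matrix. Constant
targets contribute no edges.

Candidate modules per TF are the union of two rules (either can be
disabled): top-50 targets by importance, and targets strictly above the
TF's 90th importance percentile.

Motif enrichment scores each candidate module against every motif in the
ranking database with the same discrete recovery-curve AUC used for RAS,
evaluated in the top `rank_threshold_fraction` (5%) of the motif's
genome-wide gene ranking, and z-scores the AUC across all motifs (NES).
The leading edge is the module genes ranked inside that window — a
transparent cutoff in place of the original tool's undocumented heuristic.
Motifs annotated to the module's TF with NES ≥ `nes_threshold` (3.0) are
kept; the regulon's targets are the module ∩ union of kept leading edges,
weights inherited from the adjacency. Raising the threshold can only
remove regulons or targets (tested as a monotonicity property).

## Activity scoring

Genes are ranked per cell by decreasing expression; ties break uniformly
at random with an RNG keyed to (seed, cell id), so a cell's ranking is
reproducible and independent of which other cells are present. The RAS of
a regulon (targets plus the TF, which is part of the regulatory unit) is
the discrete-sum recovery AUC within the top `top_fraction` (5%) of the
ranking, normalised by the best achievable curve — exactly the quantity an
explicit step-by-step enumeration oracle computes in the tests. `repeats`
(1) averages scores over re-rankings with distinct tie-break seeds; on a
tie-free matrix repeats are a no-op.

## Regulon network

PCC is computed over regulon activity profiles (zero-variance regulons
excluded with a warning; ≥3 cells required). CSI counts, for each pair
(A, B), the regulons correlated with A *or* B at PCC ≥ PCC(A,B) − delta
(0.05), including A and B themselves through the unit diagonal, and
divides by the total number of regulons; the diagonal is defined as 1.
Modules come from average-linkage agglomerative clustering of the
Euclidean distances between CSI rows, cut to `n_modules` flat clusters —
the module count is a config parameter (5 at the default scale), since no
principled flat-cut criterion is assumed. Edges connect pairs with CSI
strictly above `edge_threshold` (0.7); isolated nodes are retained.
Closeness centrality uses the harmonic convention (well defined on the
disconnected graphs this construction yields, 0 for isolates); eigenvector
centrality is computed by power iteration on the largest connected
component and set to 0 elsewhere. The Gini coefficient implements
`G = Σ(2i − n − 1)x_(i) / (n Σ x_i)` on the ascending sort, equal to half
the relative mean absolute difference.

## Evaluation

Cluster agreement uses seeded k-means (k = number of cell groups, 10
restarts, best inertia) on RAS vectors, compared to group labels with AMI
(expected-MI adjustment, **max** normalisation) and completeness.
Silhouette is the standard Euclidean mean score. Centroid distances are
measured in a 2-component PCA fitted on pseudobulk RAS with single cells
projected onto the same axes. In the synthetic pipeline, all evaluation
labels come from the generator's planted groups — harmonisation quality is
scored against that same truth rather than being allowed to define it.

Network validation reports the fraction of network edges present in the
interaction table, counts of validated edges per right-closed 20-percentile
confidence bin, mean CSI per 10-percentile confidence bin, and the
fraction of network nodes in the essential list. Ground-truth recovery
reports the per-TF Jaccard between recovered and planted target sets
(TFs with no recovered regulon count as 0), the ARI between CSI modules
and the planted module partition over recovered TFs, and per-regulon
activity specificity (mean RAS in planted-active types minus inactive).

## Numerical and reproducibility choices

- All randomness flows from explicit integer seeds; string-keyed stages
  (per-cell tie-breaks, per-stratum sampling, per-target model seeds)
  derive sub-seeds via CRC32 of the identifier, so results are invariant
  to container ordering and reproducible bit-for-bit — re-running a config
  reproduces identical artifacts, byte for byte.
- Matrices are gene × cell everywhere; MTX with genes.tsv/barcodes.tsv
  sidecars, dense TSV, GMT (+ weight sidecar) and JSON are the only
  formats. Writers and readers are inverse: bit-exact for counts, ≤1e-9
  drift for reals.
- Ties in top-N module selection break by (importance desc, gene id asc);
  feature-selection ties break by gene id. fcluster's maxclust criterion
  may return fewer clusters than requested on degenerate inputs.

## Problem sizes

The default study scale — 3 atlases × 3,000 cells × 1,500 genes, 25 TFs in
5 modules, 12 types in 6 groups, noiseless motif database with 100 decoy
motifs — was chosen as the smallest configuration at which module
structure, harmonisation and network validation are all non-trivial; the
full pipeline completes in well under a minute on one CPU, and the test
suite re-runs it once.

## Known limitations

- Only activating regulons; repression is not modelled anywhere.
- The pseudobulk-vs-single-cell Gini comparison is a directional claim
  whose sign depends on the noise regime: heavy dropout can push
  single-cell RAS toward many exact zeros, which *raises* single-cell
  Gini; at the default conditions the pseudobulk direction holds, but it
  is not a theorem.
- Harmonisation assumes the reference atlas's label set covers the
  biology; cells of types outside the vocabulary are at best UNASSIGNED
  and at worst absorbed by a correlated sibling type.
- The motif database model (one perfect motif per TF plus random decoys)
  makes motif pruning nearly noiseless at `ranking_noise` 0; real motif
  databases are far more ambiguous.
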