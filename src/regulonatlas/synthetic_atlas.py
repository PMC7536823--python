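"""Synthetic multi-atlas single-cell data with a planted regulon structure.

The generator emulates the situation the pipeline is built for: several cell
atlases profiling overlapping cell types under different technical regimes
(sequencing depth, dropout, gene detection), each annotated with its own
author vocabulary, while the underlying biology — a set of TFs organised into
co-active modules driving cell-type-specific target programs — is shared.

The planted structure (:class:`SyntheticGroundTruth`) records everything a
downstream evaluation needs: TF -> target effect sizes, the module partition
of TFs, the per-cell-type activity of every TF, the two-level cell-type /
cell-group vocabulary, a protein-interaction table over TF pairs and an
essential-TF subset.

Count model: negative binomial with a shared per-gene dispersion (default
0.2), the standard overdispersion stand-in for scRNA-seq counts.  Dropout is
injected as excess zeros from a logistic curve in log mean expression, on top
of the count model's own zero mass.  TFs are expressed genes themselves —
their expression tracks their activity — so co-expression inference has
signal to work with.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    CellAnnotation,
    ExpressionMatrix,
    MotifRankingDB,
    ValidationError,
)

GRANULARITIES = ("coarse", "reference", "fine")

#: default study scale: 3 atlases x 3,000 cells x 1,500 genes, 25 TFs in
#: 5 modules, 12 cell types in 6 groups — small enough for a desk run.
DEFAULT_SCALE = dict(
    n_atlases=3,
    cells_per_atlas=3000,
    n_genes=1500,
    n_tfs=25,
    n_targets=20,
    n_modules=5,
    n_cell_types=12,
    n_groups=6,
)

GENE_DISPERSION = 0.2  # shared NB dispersion (1/size)


def _stable_seed(*parts) -> list[int]:
    """Deterministic RNG entropy from a seed plus string keys (order-free of
    any container iteration order)."""
    out = []
    for p in parts:
        if isinstance(p, str):
            out.append(zlib.crc32(p.encode()))
        else:
            out.append(int(p) % (2**31))
    return out


@dataclass
class SyntheticGroundTruth:
    """The planted regulatory structure shared by all generated atlases."""

    tf_ids: list[str]
    target_weights: dict[str, dict[str, float]]
    module_of_tf: dict[str, int]
    activity_profile: pd.DataFrame  # cell type x TF, values in [0, 1]
    type_to_group: dict[str, str]
    ppi_pairs: dict[frozenset, float]
    essential_tfs: set[str]
    gene_ids: list[str]
    baseline_expression: pd.Series  # per-gene relative abundance (arbitrary units)
    tissue_of_type: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        genes = set(self.gene_ids)
        modules = set(self.module_of_tf.values())
        if set(self.module_of_tf) != set(self.tf_ids):
            raise ValidationError("module_of_tf must partition tf_ids")
        if not modules <= set(range(1, len(self.tf_ids) + 1)):
            raise ValidationError("module ids must lie in 1..n_tfs")
        for tf, weights in self.target_weights.items():
            if tf in weights:
                raise ValidationError("TF '%s' is its own target" % tf)
            unknown = set(weights) - genes
            if unknown:
                raise ValidationError(
                    "targets of '%s' outside gene universe: %s" % (tf, sorted(unknown)[:5])
                )
        prof = self.activity_profile
        if ((prof.to_numpy() < 0) | (prof.to_numpy() > 1)).any():
            raise ValidationError("activity_profile values must lie in [0, 1]")
        if not (prof.to_numpy().max(axis=1) >= 0.5).all():
            raise ValidationError("every cell type needs >=1 TF with activity >= 0.5")

    @property
    def cell_types(self) -> list[str]:
        return list(self.activity_profile.index)

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.type_to_group.values()))

    def to_json_dict(self) -> dict:
        return {
            "tf_ids": self.tf_ids,
            "target_weights": self.target_weights,
            "module_of_tf": self.module_of_tf,
            "activity_profile": {
                t: self.activity_profile.loc[t].round(10).to_dict() for t in self.cell_types
            },
            "type_to_group": self.type_to_group,
            "ppi_pairs": [[sorted(p)[0], sorted(p)[1], c] for p, c in sorted(
                self.ppi_pairs.items(), key=lambda kv: sorted(kv[0]))],
            "essential_tfs": sorted(self.essential_tfs),
            "gene_ids": self.gene_ids,
            "baseline_expression": self.baseline_expression.round(12).to_dict(),
            "tissue_of_type": self.tissue_of_type,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SyntheticGroundTruth":
        prof = pd.DataFrame(d["activity_profile"]).T
        prof = prof.loc[list(d["activity_profile"].keys()), d["tf_ids"]]
        return cls(
            tf_ids=list(d["tf_ids"]),
            target_weights={tf: dict(w) for tf, w in d["target_weights"].items()},
            module_of_tf={tf: int(m) for tf, m in d["module_of_tf"].items()},
            activity_profile=prof,
            type_to_group=dict(d["type_to_group"]),
            ppi_pairs={frozenset((a, b)): float(c) for a, b, c in d["ppi_pairs"]},
            essential_tfs=set(d["essential_tfs"]),
            gene_ids=list(d["gene_ids"]),
            baseline_expression=pd.Series(d["baseline_expression"]).loc[d["gene_ids"]],
            tissue_of_type=dict(d.get("tissue_of_type", {})),
        )


@dataclass(frozen=True)
class AtlasProfile:
    """Technical regime of one atlas.

    ``mean_library_size`` is in counts/cell; the dropout curve gives the
    probability of an injected (excess) zero as a logistic function of a
    gene's log mean expression: ``p = 1 / (1 + exp(k * (log_mean - m)))`` is
    *decreasing* in log mean, so ``dropout_midpoint`` m is the log-mean at
    which half the observations of a gene are dropped and
    ``dropout_steepness`` k > 0 controls how sharp the transition is.
    """

    name: str
    mean_library_size: float
    dropout_midpoint: float
    dropout_steepness: float
    label_granularity: str = "reference"
    n_cells: int = 3000

    def __post_init__(self) -> None:
        if self.mean_library_size <= 0:
            raise ValidationError("mean_library_size must be > 0")
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        if self.dropout_steepness <= 0:
            raise ValidationError("dropout_steepness must be > 0")
        if self.label_granularity not in GRANULARITIES:
            raise ValidationError(
                "label_granularity must be one of %s" % (GRANULARITIES,)
            )


def default_profiles(
    n_atlases: int = 3, cells_per_atlas: int = 3000, low_noise: bool = False
) -> list[AtlasProfile]:
    """Three technical regimes loosely emulating a 3' droplet atlas (the
    reference), a deep full-length atlas with fine labels, and a shallow
    microwell atlas with coarse labels.  ``low_noise`` keeps the same label
    structure but removes injected dropout and equalises depth."""
    base = [
        AtlasProfile("droplet_ref", 6000.0, 0.2, 1.2, "reference", cells_per_atlas),
        AtlasProfile("fulllength_fine", 20000.0, -0.3, 1.0, "fine", cells_per_atlas),
        AtlasProfile("microwell_coarse", 2000.0, 0.6, 1.4, "coarse", cells_per_atlas),
    ]
    if low_noise:
        base = [
            AtlasProfile(p.name, 20000.0, -30.0, 5.0, p.label_granularity, p.n_cells)
            for p in base
        ]
    if not 1 <= n_atlases <= len(base):
        raise ValidationError("default_profiles supports 1..%d atlases" % len(base))
    return base[:n_atlases]


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


def _module_combos(n_modules: int, n_cell_types: int) -> list[tuple[int, ...]]:
    """Distinct module subsets (ordered by size then lexicographically) that
    serve as cell-type activity signatures; uniqueness makes types separable."""
    combos: list[tuple[int, ...]] = []
    for size in range(1, n_modules + 1):
        combos.extend(itertools.combinations(range(1, n_modules + 1), size))
        if len(combos) >= n_cell_types:
            break
    if len(combos) < n_cell_types:
        raise ValidationError(
            "%d modules admit only %d distinct type signatures (< %d cell types)"
            % (n_modules, len(combos), n_cell_types)
        )
    return combos[:n_cell_types]


def generate_ground_truth(
    n_tfs: int = DEFAULT_SCALE["n_tfs"],
    n_targets: int = DEFAULT_SCALE["n_targets"],
    n_modules: int = DEFAULT_SCALE["n_modules"],
    n_cell_types: int = DEFAULT_SCALE["n_cell_types"],
    n_groups: int = DEFAULT_SCALE["n_groups"],
    seed: int = 0,
    n_genes: int = DEFAULT_SCALE["n_genes"],
    within_module_floor: float = 0.8,
    n_tissues: int = 2,
    essential_fraction: float = 0.4,
) -> SyntheticGroundTruth:
    """Plant TFs, modules, targets and cell-type activity profiles.

    Each cell type is given a distinct subset of active modules; TFs inherit
    their module's high/low activity pattern plus a small jitter calibrated so
    that within-module activity profiles stay correlated (Pearson around or
    above ``within_module_floor``) while between-module profiles are
    uncorrelated in expectation.
    """
    if min(n_tfs, n_targets, n_modules, n_cell_types, n_groups, n_genes) < 1:
        raise ValueError("all counts must be >= 1")
    if n_modules > n_tfs:
        raise ValueError("n_modules must be <= n_tfs")
    if n_groups > n_cell_types:
        raise ValueError("n_groups must be <= n_cell_types")
    if not 0 < within_module_floor < 1:
        raise ValueError("within_module_floor must lie in (0, 1)")
    if n_tfs + 1 > n_genes:
        raise ValueError("gene universe too small for the requested TF count")

    rng = np.random.default_rng(_stable_seed(seed, "ground_truth"))

    tf_ids = ["Tf%02d" % (i + 1) for i in range(n_tfs)]
    other = ["Gene%04d" % (i + 1) for i in range(n_genes - n_tfs)]
    gene_ids = tf_ids + other

    module_of_tf = {tf: (i % n_modules) + 1 for i, tf in enumerate(tf_ids)}

    cell_types = ["Type%02d" % (i + 1) for i in range(n_cell_types)]
    combos = _module_combos(n_modules, n_cell_types)

    # module-level activity: high where the module is in the type's signature
    M = np.zeros((n_cell_types, n_modules))
    for ti in range(n_cell_types):
        high = rng.uniform(0.7, 1.0, size=n_modules)
        low = rng.uniform(0.0, 0.15, size=n_modules)
        for m in range(1, n_modules + 1):
            M[ti, m - 1] = high[m - 1] if m in combos[ti] else low[m - 1]

    # TF-level jitter sized from each module's realised signal variance so
    # that expected within-module correlation stays above the floor
    A = np.zeros((n_cell_types, n_tfs))
    for j, tf in enumerate(tf_ids):
        col = M[:, module_of_tf[tf] - 1]
        s2 = max(col.var(), 1e-6)
        sigma = np.sqrt(0.5 * s2 * (1.0 - within_module_floor) / within_module_floor)
        A[:, j] = np.clip(col + rng.normal(0.0, sigma, size=n_cell_types), 0.0, 1.0)
    # guarantee at least one strongly active TF per type
    for ti in range(n_cell_types):
        if A[ti].max() < 0.5:
            primary = combos[ti][0]
            j = next(k for k, tf in enumerate(tf_ids) if module_of_tf[tf] == primary)
            A[ti, j] = 0.9
    activity_profile = pd.DataFrame(A, index=cell_types, columns=tf_ids)

    # two-level vocabulary: contiguous chunks of signature-sorted types
    order = sorted(range(n_cell_types), key=lambda ti: combos[ti])
    groups = ["Group%d" % (g + 1) for g in range(n_groups)]
    type_to_group: dict[str, str] = {}
    for g, chunk in enumerate(np.array_split(np.array(order), n_groups)):
        for ti in chunk:
            type_to_group[cell_types[ti]] = groups[g]

    tissues = ["Tissue%d" % (t + 1) for t in range(n_tissues)]
    tissue_of_type = {t: tissues[i % n_tissues] for i, t in enumerate(cell_types)}

    # targets: sampled from the non-TF pool, positive (activating) weights
    target_weights: dict[str, dict[str, float]] = {}
    for tf in tf_ids:
        chosen = rng.choice(len(other), size=min(n_targets, len(other)), replace=False)
        weights = rng.uniform(1.0, 3.0, size=len(chosen))
        target_weights[tf] = {other[i]: float(w) for i, w in zip(chosen, weights)}

    # PPI truth: within-module TF pairs with a confidence score
    ppi_pairs: dict[frozenset, float] = {}
    for a, b in itertools.combinations(tf_ids, 2):
        if module_of_tf[a] == module_of_tf[b]:
            ppi_pairs[frozenset((a, b))] = float(rng.uniform(0.5, 1.0))

    n_ess = max(1, int(round(essential_fraction * n_tfs)))
    essential_tfs = set(rng.choice(tf_ids, size=n_ess, replace=False).tolist())

    baseline = pd.Series(rng.lognormal(0.0, 0.6, size=n_genes), index=gene_ids)

    return SyntheticGroundTruth(
        tf_ids=tf_ids,
        target_weights=target_weights,
        module_of_tf=module_of_tf,
        activity_profile=activity_profile,
        type_to_group=type_to_group,
        ppi_pairs=ppi_pairs,
        essential_tfs=essential_tfs,
        gene_ids=gene_ids,
        baseline_expression=baseline,
        tissue_of_type=tissue_of_type,
    )


# ---------------------------------------------------------------------------
# expression synthesis
# ---------------------------------------------------------------------------


def type_mean_expression(truth: SyntheticGroundTruth, effect_scale: float = 1.0) -> pd.DataFrame:
    """Relative (un-normalised) mean expression per gene for every cell type.

    Non-TF genes: baseline * (1 + effect_scale * sum_t w(t, g) * activity(t)).
    TFs track their own activity: baseline * (0.2 + 2 * activity).
    """
    genes = truth.gene_ids
    gidx = {g: i for i, g in enumerate(genes)}
    types = truth.cell_types
    base = truth.baseline_expression.to_numpy()
    means = np.tile(base[:, None], (1, len(types))).astype(float)
    A = truth.activity_profile  # type x tf
    for tf in truth.tf_ids:
        act = A[tf].to_numpy()  # per type
        means[gidx[tf], :] = base[gidx[tf]] * (0.2 + 2.0 * act)
        for target, w in truth.target_weights[tf].items():
            means[gidx[target], :] += base[gidx[target]] * effect_scale * w * act
    return pd.DataFrame(means, index=genes, columns=types)


def dropout_probability(log_mean: np.ndarray, profile: AtlasProfile) -> np.ndarray:
    """Excess-zero probability for a gene with the given log mean expression."""
    z = profile.dropout_steepness * (np.asarray(log_mean, float) - profile.dropout_midpoint)
    return 1.0 / (1.0 + np.exp(z))


def nb_zero_probability(mean: np.ndarray, dispersion: float = GENE_DISPERSION) -> np.ndarray:
    """Zero mass of the NB count model itself, P(X=0) = (r/(r+mu))^r."""
    r = 1.0 / dispersion
    return (r / (r + np.asarray(mean, float))) ** r


def generate_atlas(
    truth: SyntheticGroundTruth,
    profile: AtlasProfile,
    seed: int = 0,
    dispersion: float = GENE_DISPERSION,
    library_size_cv: float = 0.3,
) -> tuple[ExpressionMatrix, CellAnnotation]:
    """Draw one atlas: cells sampled over the atlas's cell types, NB counts
    around type means, logistic excess-zero dropout, labels at the profile's
    granularity.  Deterministic given (arguments, seed)."""
    rng = np.random.default_rng(_stable_seed(seed, "atlas", profile.name))
    types = truth.cell_types
    n_types = len(types)

    # overlapping coverage: non-reference atlases drop a couple of cell types
    # so atlases sample overlapping but not identical type sets; the
    # reference-granularity atlas covers every type because its label set
    # defines the shared vocabulary
    n_drop = min(2, max(0, n_types - 3)) if n_types > 4 else 0
    if profile.label_granularity == "reference":
        n_drop = 0
    dropped = set(rng.choice(n_types, size=n_drop, replace=False).tolist())
    atlas_types = [t for i, t in enumerate(types) if i not in dropped]

    type_idx = rng.integers(0, len(atlas_types), size=profile.n_cells)
    cell_types = [atlas_types[i] for i in type_idx]

    means = type_mean_expression(truth)[atlas_types].to_numpy()  # gene x atlas-type
    frac = means / means.sum(axis=0, keepdims=True)

    mu_lib = np.log(profile.mean_library_size) - 0.5 * library_size_cv**2
    libs = rng.lognormal(mu_lib, library_size_cv, size=profile.n_cells)

    mu = frac[:, type_idx] * libs[None, :]  # gene x cell expected counts
    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mu)).astype(np.int64)

    # excess zeros: logistic in each gene's log mean expression in this atlas
    gene_mean = mu.mean(axis=1)
    p_drop = dropout_probability(np.log(np.maximum(gene_mean, 1e-12)), profile)
    keep = rng.random(size=counts.shape) >= p_drop[:, None]
    counts = counts * keep

    cell_ids = ["%s_c%05d" % (profile.name, i) for i in range(profile.n_cells)]
    expr = ExpressionMatrix(counts, list(truth.gene_ids), cell_ids, normalised=False)

    table = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "atlas": profile.name,
            "tissue": [truth.tissue_of_type.get(t, "Tissue1") for t in cell_types],
            "author_label": cell_types,
            "reference_type": cell_types,
            "cell_group": [truth.type_to_group[t] for t in cell_types],
            "cycle_phase": "",
        }
    )
    annotation = CellAnnotation(table, label_map={t: t for t in atlas_types})
    if profile.label_granularity != "reference":
        annotation = relabel_cells(annotation, profile.label_granularity, seed=seed, truth=truth)
    return expr, annotation


def relabel_cells(
    annotation: CellAnnotation,
    granularity: str,
    seed: int = 0,
    truth: SyntheticGroundTruth | None = None,
    split: int = 2,
) -> CellAnnotation:
    """Re-emit author labels at a different granularity.

    ``coarse`` merges sibling reference types into their cell group (the
    group mapping comes from ``truth`` or from the annotation itself);
    ``fine`` splits each reference type into ``split`` sublabels (cells
    assigned at random, seeded); ``reference`` is the identity.  The label ->
    reference-type mapping is recorded on the result for evaluation (for
    coarse labels the mapping targets the cell group).
    """
    if granularity not in GRANULARITIES:
        raise ValueError("unknown granularity '%s'" % granularity)
    df = annotation.table.copy()
    if granularity == "reference":
        out = CellAnnotation(df, label_map={t: t for t in df["reference_type"].unique()})
        return out
    if granularity == "coarse":
        if truth is not None:
            group_of = truth.type_to_group
        else:
            group_of = dict(zip(df["reference_type"], df["cell_group"]))
        df["author_label"] = df["reference_type"].map(group_of)
        return CellAnnotation(df, label_map=dict(group_of))
    # fine: deterministic per-cell split keyed on (seed, cell_id)
    if split < 2:
        raise ValueError("fine relabelling needs split >= 2")
    subs = []
    for cell_id, ref in zip(df["cell_id"], df["reference_type"]):
        r = np.random.default_rng(_stable_seed(seed, "fine", cell_id))
        subs.append("%s_sub%d" % (ref, r.integers(1, split + 1)))
    df["author_label"] = subs
    label_map = {}
    for ref in df["reference_type"].unique():
        for k in range(1, split + 1):
            label_map["%s_sub%d" % (ref, k)] = ref
    return CellAnnotation(df, label_map=label_map)


# ---------------------------------------------------------------------------
# motif ranking database
# ---------------------------------------------------------------------------


def generate_motif_db(
    truth: SyntheticGroundTruth,
    decoy_motifs: int = 100,
    ranking_noise: float = 0.0,
    seed: int = 0,
) -> MotifRankingDB:
    """One motif per TF whose gene ranking puts the TF's true targets on top
    (perturbed by Gaussian ``ranking_noise``), plus ``decoy_motifs`` motifs
    with random rankings and no TF annotation."""
    if ranking_noise < 0:
        raise ValueError("ranking_noise must be >= 0")
    rng = np.random.default_rng(_stable_seed(seed, "motif_db"))
    genes = truth.gene_ids
    n = len(genes)
    gidx = {g: i for i, g in enumerate(genes)}

    rows = {}
    annotation = {}
    for tf in truth.tf_ids:
        score = np.zeros(n)
        score[[gidx[t] for t in truth.target_weights[tf]]] = 1.0
        score = score + ranking_noise * rng.normal(size=n)
        tiebreak = rng.permutation(n)
        order = np.lexsort((tiebreak, -score))  # descending score
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(1, n + 1)
        motif = "motif_%s" % tf
        rows[motif] = ranks
        annotation[motif] = tf
    for j in range(decoy_motifs):
        rows["decoy_%03d" % (j + 1)] = rng.permutation(n) + 1

    rankings = pd.DataFrame.from_dict(rows, orient="index", columns=genes)
    return MotifRankingDB(rankings, annotation)
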