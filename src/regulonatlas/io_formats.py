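"""Core data containers and on-disk formats.

Every pipeline stage exchanges data through the validated containers defined
here: :class:`ExpressionMatrix` (gene x cell), :class:`CellAnnotation`,
:class:`Regulon` and :class:`MotifRankingDB`.  Matrices are stored gene x cell
throughout (genes as rows), matching the MatrixMarket sidecar convention of
the deposited mouse atlases.  Regulon sets use a GMT dialect with a TSV weight
sidecar; everything else is plain TSV/JSON so that artifacts stay diffable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

UNASSIGNED = "UNASSIGNED"

CYCLE_PHASES = ("G1", "S", "G2M")

ANNOTATION_COLUMNS = [
    "cell_id",
    "atlas",
    "tissue",
    "author_label",
    "reference_type",
    "cell_group",
    "cycle_phase",
]


class ValidationError(ValueError):
    """An artifact violates one of its declared invariants."""


class FormatError(ValueError):
    """A file on disk cannot be interpreted as the expected format."""


class DependencyError(RuntimeError):
    """A pipeline stage was requested before the stages it depends on."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene x cell matrix of non-negative expression values.

    ``normalised`` flags whether values are raw counts (False) or
    library-size-scaled log1p units (True).
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    normalised: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n_genes, n_cells = self.values.shape
        if n_genes == 0 or n_cells == 0:
            raise ValidationError(
                "expression matrix is empty (%d genes x %d cells)" % (n_genes, n_cells)
            )
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                "gene id count (%d) does not match matrix rows (%d)"
                % (len(self.gene_ids), n_genes)
            )
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                "cell id count (%d) does not match matrix columns (%d)"
                % (len(self.cell_ids), n_cells)
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("gene ids are not unique")
        if len(set(self.cell_ids)) != n_cells:
            raise ValidationError("cell ids are not unique")
        if np.min(self.values) < 0:
            raise ValidationError("expression matrix contains negative entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index()
        missing = [g for g in genes if g not in idx]
        if missing:
            raise ValidationError("unknown genes: %s ..." % ", ".join(missing[:5]))
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(
            self.values[rows, :], list(genes), list(self.cell_ids), self.normalised
        )

    def subset_cells(self, cells: Sequence[str]) -> "ExpressionMatrix":
        idx = {c: i for i, c in enumerate(self.cell_ids)}
        cols = [idx[c] for c in cells]
        return ExpressionMatrix(
            self.values[:, cols], list(self.gene_ids), list(cells), self.normalised
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class CellAnnotation:
    """Per-cell metadata: atlas of origin, tissue, labels at several levels.

    ``reference_type``/``cell_group`` carry the harmonised vocabulary (or
    UNASSIGNED); ``label_map`` optionally records the author-label ->
    reference-type mapping produced by relabelling, for evaluation.
    """

    table: pd.DataFrame
    label_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in ANNOTATION_COLUMNS:
            if col not in df.columns:
                if col == "cycle_phase":
                    df[col] = ""
                else:
                    raise FormatError("annotation missing column '%s'" % col)
        df = df[ANNOTATION_COLUMNS].astype(str)
        df["cycle_phase"] = df["cycle_phase"].replace({"nan": "", "None": ""})
        if df["cell_id"].duplicated().any():
            raise ValidationError("annotation has duplicate cell ids")
        bad = (df["reference_type"] == UNASSIGNED) & (df["cell_group"] != UNASSIGNED)
        if bad.any():
            raise ValidationError(
                "cells with reference_type=UNASSIGNED must have cell_group=UNASSIGNED"
            )
        phases = set(df["cycle_phase"]) - set(CYCLE_PHASES) - {""}
        if phases:
            raise ValidationError("unknown cycle phases: %s" % sorted(phases))
        self.table = df.reset_index(drop=True)

    @property
    def cell_ids(self) -> list[str]:
        return self.table["cell_id"].tolist()

    def subset(self, cells: Sequence[str]) -> "CellAnnotation":
        keep = self.table[self.table["cell_id"].isin(set(cells))]
        return CellAnnotation(keep.copy(), self.label_map)

    def lookup(self, column: str) -> pd.Series:
        return self.table.set_index("cell_id")[column]


@dataclass(frozen=True)
class Regulon:
    """A transcription factor with its motif-supported direct targets."""

    tf: str
    targets: frozenset[str]
    weights: Mapping[str, float]
    motifs: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", frozenset(self.targets))
        object.__setattr__(self, "motifs", frozenset(self.motifs))
        object.__setattr__(self, "weights", dict(self.weights))
        if not self.targets:
            raise ValidationError("regulon '%s' has an empty target set" % self.tf)
        if self.tf in self.targets:
            raise ValidationError("regulon '%s' lists its TF as a target" % self.tf)
        if set(self.weights) != set(self.targets):
            raise ValidationError(
                "regulon '%s': weights must be keyed exactly by targets" % self.tf
            )
        if any(w < 0 for w in self.weights.values()):
            raise ValidationError("regulon '%s' has negative weights" % self.tf)

    @property
    def name(self) -> str:
        return "%s(+)" % self.tf

    @property
    def gene_set(self) -> frozenset[str]:
        """Targets plus the TF itself — the set scored by AUCell."""
        return self.targets | {self.tf}


@dataclass
class MotifRankingDB:
    """Per-motif whole-genome gene rankings plus a motif -> TF annotation.

    ``rankings`` is a motif x gene DataFrame of integer ranks where each row
    is a permutation of 1..n_genes (1 = best / most motif-supported gene).
    """

    rankings: pd.DataFrame
    annotation: dict[str, str]

    def __post_init__(self) -> None:
        self.rankings = self.rankings.astype(int)
        n = self.rankings.shape[1]
        expected = np.arange(1, n + 1)
        for motif, row in self.rankings.iterrows():
            if not np.array_equal(np.sort(row.to_numpy()), expected):
                raise ValidationError(
                    "motif '%s' ranking is not a permutation of 1..%d" % (motif, n)
                )
        genes = set(self.rankings.columns)
        for motif, tf in self.annotation.items():
            if motif not in self.rankings.index:
                raise ValidationError("annotation references unknown motif '%s'" % motif)
            if tf not in genes:
                raise ValidationError(
                    "motif '%s' annotated to TF '%s' absent from gene universe"
                    % (motif, tf)
                )

    @property
    def motif_ids(self) -> list[str]:
        return list(self.rankings.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.rankings.columns)

    def motifs_for_tf(self, tf: str) -> list[str]:
        return [m for m, t in self.annotation.items() if t == tf]


# ---------------------------------------------------------------------------
# expression matrix IO
# ---------------------------------------------------------------------------


def write_expression(expr: ExpressionMatrix, path: str | Path, format: str = "mtx") -> Path:
    """Write an expression matrix as an MTX directory or a dense TSV file."""
    path = Path(path)
    if format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        mat = scipy.sparse.csr_matrix(expr.values)
        scipy.io.mmwrite(str(path / "matrix.mtx"), mat, precision=17)
        pd.Series(expr.gene_ids).to_csv(path / "genes.tsv", sep="\t", index=False, header=False)
        pd.Series(expr.cell_ids).to_csv(path / "barcodes.tsv", sep="\t", index=False, header=False)
        return path
    if format == "tsv":
        path.parent.mkdir(parents=True, exist_ok=True)
        expr.to_frame().to_csv(path, sep="\t", float_format="%.17g")
        return path
    raise FormatError("unknown expression format '%s' (expected mtx or tsv)" % format)


def read_expression(path: str | Path, format: str = "mtx", normalised: bool = False) -> ExpressionMatrix:
    """Read an expression matrix written by :func:`write_expression`."""
    path = Path(path)
    if format == "mtx":
        mtx_file = path / "matrix.mtx"
        if not mtx_file.exists():
            raise FormatError("no matrix.mtx under %s" % path)
        mat = scipy.io.mmread(str(mtx_file))
        values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].astype(str).tolist()
        cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str).tolist()
        if len(genes) != values.shape[0] or len(cells) != values.shape[1]:
            raise FormatError(
                "sidecar ids (%d genes, %d cells) do not match matrix shape %s"
                % (len(genes), len(cells), values.shape)
            )
        if values.size and float(values.max()) == float(int(values.max())) and np.allclose(values, np.round(values)):
            values = np.round(values)
        return ExpressionMatrix(values, genes, cells, normalised=normalised)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return ExpressionMatrix(
            df.to_numpy(), df.index.astype(str).tolist(), df.columns.astype(str).tolist(),
            normalised=normalised,
        )
    raise FormatError("unknown expression format '%s' (expected mtx or tsv)" % format)


# ---------------------------------------------------------------------------
# annotation IO
# ---------------------------------------------------------------------------


def write_annotation(annotation: CellAnnotation, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    annotation.table.to_csv(path, sep="\t", index=False)
    return path


def read_annotation(path: str | Path) -> CellAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return CellAnnotation(df)


# ---------------------------------------------------------------------------
# regulon IO (GMT dialect + weight sidecar)
# ---------------------------------------------------------------------------


def _weights_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".weights.tsv")


def write_regulons(regulons: Iterable[Regulon], path: str | Path) -> Path:
    """Write regulons as GMT: name "TF(+)", description = comma-joined motifs,
    remaining fields = targets; importances go to a ``.weights.tsv`` sidecar."""
    regulons = sorted(regulons, key=lambda r: r.tf)
    names = [r.name for r in regulons]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate regulon names")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for reg in regulons:
            motif_field = ",".join(sorted(reg.motifs)) or "-"
            fh.write("\t".join([reg.name, motif_field, *sorted(reg.targets)]) + "\n")
    rows = [
        (reg.tf, target, reg.weights[target])
        for reg in regulons
        for target in sorted(reg.targets)
    ]
    pd.DataFrame(rows, columns=["tf", "target", "weight"]).to_csv(
        _weights_path(path), sep="\t", index=False, float_format="%.17g"
    )
    return path


def read_regulons(path: str | Path) -> list[Regulon]:
    path = Path(path)
    weights = pd.read_csv(_weights_path(path), sep="\t")
    wmap: dict[str, dict[str, float]] = {}
    for tf, target, w in weights.itertuples(index=False):
        wmap.setdefault(str(tf), {})[str(target)] = float(w)
    regulons = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError("GMT line %d has no targets" % lineno)
            name, motif_field, *targets = fields
            if not name.endswith("(+)"):
                raise FormatError("GMT line %d: regulon name '%s' lacks '(+)'" % (lineno, name))
            tf = name[: -len("(+)")]
            if tf in targets:
                raise ValidationError(
                    "GMT line %d: TF '%s' repeated among its own targets" % (lineno, tf)
                )
            if len(set(targets)) != len(targets):
                raise ValidationError("GMT line %d: duplicate targets" % lineno)
            motifs = frozenset() if motif_field == "-" else frozenset(motif_field.split(","))
            regulons.append(
                Regulon(tf, frozenset(targets), wmap.get(tf, {t: 0.0 for t in targets}), motifs)
            )
    return regulons


# ---------------------------------------------------------------------------
# motif ranking DB IO (long-form TSV + annotation TSV)
# ---------------------------------------------------------------------------


def write_motif_db(db: MotifRankingDB, rankings_path: str | Path, annotation_path: str | Path) -> None:
    rankings_path, annotation_path = Path(rankings_path), Path(annotation_path)
    rankings_path.parent.mkdir(parents=True, exist_ok=True)
    long = db.rankings.stack().rename("rank").reset_index()
    long.columns = ["motif", "gene", "rank"]
    long.to_csv(rankings_path, sep="\t", index=False)
    pd.DataFrame(
        sorted(db.annotation.items()), columns=["motif", "tf"]
    ).to_csv(annotation_path, sep="\t", index=False)


def read_motif_db(rankings_path: str | Path, annotation_path: str | Path) -> MotifRankingDB:
    long = pd.read_csv(rankings_path, sep="\t", dtype={"motif": str, "gene": str, "rank": int})
    rankings = long.pivot(index="motif", columns="gene", values="rank")
    if rankings.isna().any().any():
        raise FormatError("motif ranking table is not a complete motif x gene grid")
    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    return MotifRankingDB(rankings, dict(zip(ann["motif"], ann["tf"])))


# ---------------------------------------------------------------------------
# misc small artifacts
# ---------------------------------------------------------------------------


def write_json(obj: object, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def run_pipeline(config: str | Path) -> Path:
    """Execute the full workflow described by a YAML config; see ``pipeline``."""
    from .pipeline import run_pipeline as _run

    return _run(config)
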