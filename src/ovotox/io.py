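"""Core data model and file I/O.

The pipeline starts from UMI count matrices: bulk matrices are genes x
samples, single-cell matrices are cells x genes. Matrices travel either as
MatrixMarket coordinate files (1-based indices per the standard, converted
to 0-based internally) with one-identifier-per-line row/column files, or as
dense TSV with the identifiers embedded (header row + first column).

Metadata tables (sample and cell level), ortholog maps and GMT gene-set
collections are held in their field-standard containers (pandas DataFrames
and plain dicts) behind validating readers.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sp
import yaml

from .errors import MetadataError, ParseError, ValidationError

logger = logging.getLogger("ovotox")

STAGES = ("PND6", "PND14", "PND22")
COMPOUNDS = ("control", "DES", "KTZ")
DOSE_LEVELS = ("none", "low", "medium", "high")
BROAD_TYPES = (
    "germ",
    "coelomic_surface_epithelial",
    "granulosa",
    "steroidogenic_granulosa",
    "interstitial",
    "theca",
    "endothelial",
    "perivascular",
    "erythrocyte",
    "immune",
)

SAMPLE_META_COLUMNS = ("sample_id", "stage", "compound", "dose_level", "dose_value", "plate")
CELL_META_COLUMNS = (
    "cell_id",
    "subject_id",
    "stage",
    "cluster_id",
    "broad_type",
    "total_umi",
    "n_genes",
    "pct_mito",
)
ORTHOLOG_COLUMNS = ("source_gene", "target_gene", "relationship")
RELATIONSHIPS = ("one2one", "one2many", "many2one", "many2many")


def _check_unique_ids(ids, what: str):
    ids = [str(i) for i in ids]
    if any(i == "" for i in ids):
        raise ValidationError(f"empty {what} identifier")
    if len(set(ids)) != len(ids):
        dupes = pd.Series(ids).value_counts()
        dupes = dupes[dupes > 1].index.tolist()[:5]
        raise ValidationError(f"duplicated {what} identifiers: {dupes}")
    return ids


@dataclass
class CountMatrix:
    """Non-negative integer UMI count matrix with identifiers.

    ``orientation`` is ``genes_by_samples`` for bulk data and
    ``cells_by_genes`` for single-cell data; it is a tag, not a transform.
    """

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    orientation: str = "genes_by_samples"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("count matrix must be 2-dimensional")
        if self.orientation not in ("genes_by_samples", "cells_by_genes"):
            raise ValidationError(f"unknown orientation {self.orientation!r}")
        self.row_ids = _check_unique_ids(self.row_ids, "row")
        self.col_ids = _check_unique_ids(self.col_ids, "column")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match identifier counts "
                f"({len(self.row_ids)}, {len(self.col_ids)})"
            )
        neg = np.argwhere(self.values < 0)
        if neg.size:
            r, c = neg[0]
            raise ValidationError(
                f"negative count at ({self.row_ids[r]}, {self.col_ids[c]})"
            )
        if not np.issubdtype(self.values.dtype, np.integer):
            rounded = np.rint(self.values)
            bad = np.argwhere(np.abs(self.values - rounded) > 1e-9)
            if bad.size:
                r, c = bad[0]
                raise ValidationError(
                    f"non-integral count at ({self.row_ids[r]}, {self.col_ids[c]})"
                )
            self.values = rounded.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, orientation: str = "genes_by_samples") -> "CountMatrix":
        return cls(df.to_numpy(), list(df.index), list(df.columns), orientation)

    def subset_rows(self, ids) -> "CountMatrix":
        idx = pd.Index(self.row_ids).get_indexer(list(ids))
        if (idx < 0).any():
            missing = [g for g, i in zip(ids, idx) if i < 0][:5]
            raise ValidationError(f"row identifiers not present: {missing}")
        return CountMatrix(self.values[idx], list(ids), list(self.col_ids), self.orientation)

    def subset_cols(self, ids) -> "CountMatrix":
        idx = pd.Index(self.col_ids).get_indexer(list(ids))
        if (idx < 0).any():
            missing = [g for g, i in zip(ids, idx) if i < 0][:5]
            raise ValidationError(f"column identifiers not present: {missing}")
        return CountMatrix(self.values[:, idx], list(self.row_ids), list(ids), self.orientation)


def _read_id_file(path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip() != ""]


def read_count_matrix(
    path_matrix,
    path_rows=None,
    path_cols=None,
    orientation: str = "genes_by_samples",
) -> CountMatrix:
    """Read a count matrix from MatrixMarket (.mtx) or dense TSV.

    MatrixMarket requires ``path_rows``/``path_cols`` identifier files; a
    dense TSV carries identifiers in its header row and first column (the
    identifier files, when given, override them).
    """
    path_matrix = Path(path_matrix)
    if path_matrix.suffix == ".mtx":
        if path_rows is None or path_cols is None:
            raise ParseError(f"{path_matrix}: MatrixMarket input needs row and column id files")
        try:
            mat = spio.mmread(path_matrix)
        except Exception as exc:  # noqa: BLE001 - report as structured parse error
            raise ParseError(f"{path_matrix}: not valid MatrixMarket ({exc})") from exc
        values = np.asarray(mat.todense() if sp.issparse(mat) else mat)
        rows = _read_id_file(path_rows)
        cols = _read_id_file(path_cols)
    else:
        try:
            df = pd.read_csv(path_matrix, sep="\t", index_col=0)
        except Exception as exc:  # noqa: BLE001
            raise ParseError(f"{path_matrix}: not valid dense TSV ({exc})") from exc
        values = df.to_numpy()
        rows = _read_id_file(path_rows) if path_rows else [str(i) for i in df.index]
        cols = _read_id_file(path_cols) if path_cols else [str(c) for c in df.columns]
    if values.shape != (len(rows), len(cols)):
        raise ParseError(
            f"{path_matrix}: matrix is {values.shape} but identifier files give "
            f"({len(rows)}, {len(cols)})"
        )
    return CountMatrix(values, rows, cols, orientation)


def write_count_matrix(cm: CountMatrix, path_matrix, path_rows=None, path_cols=None) -> None:
    """Write a CountMatrix as .mtx (+ id files) or dense TSV by extension."""
    path_matrix = Path(path_matrix)
    if path_matrix.suffix == ".mtx":
        if path_rows is None or path_cols is None:
            raise ValidationError("MatrixMarket output needs row and column id paths")
        spio.mmwrite(str(path_matrix), sp.coo_matrix(cm.values))
        Path(path_rows).write_text("".join(f"{r}\n" for r in cm.row_ids))
        Path(path_cols).write_text("".join(f"{c}\n" for c in cm.col_ids))
    else:
        cm.to_frame().to_csv(path_matrix, sep="\t")


def validate_sample_metadata(df: pd.DataFrame, counts: CountMatrix | None = None) -> pd.DataFrame:
    """Validate the bulk sample sheet against its documented invariants."""
    missing = [c for c in SAMPLE_META_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"sample metadata missing columns: {missing}")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    _check_unique_ids(df["sample_id"], "sample_id")
    bad_stage = set(df["stage"]) - set(STAGES)
    if bad_stage:
        raise MetadataError(f"unknown stage labels: {sorted(bad_stage)}")
    bad_cmp = set(df["compound"]) - set(COMPOUNDS)
    if bad_cmp:
        raise MetadataError(f"unknown compound labels: {sorted(bad_cmp)}")
    bad_dose = set(df["dose_level"]) - set(DOSE_LEVELS)
    if bad_dose:
        raise MetadataError(f"unknown dose levels: {sorted(bad_dose)}")
    ctrl = df["compound"] == "control"
    none_dose = df["dose_level"] == "none"
    if not (ctrl == none_dose).all():
        off = df.loc[ctrl != none_dose, "sample_id"].tolist()[:5]
        raise MetadataError(f"compound=control must pair with dose_level=none (violated by {off})")
    if counts is not None:
        absent = set(df["sample_id"]) - set(counts.col_ids)
        if absent:
            raise MetadataError(f"metadata samples absent from count matrix: {sorted(absent)[:5]}")
    return df


def read_sample_metadata(path, counts: CountMatrix | None = None) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"{path}: not a readable TSV ({exc})") from exc
    return validate_sample_metadata(df, counts)


def validate_cell_metadata(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CELL_META_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"cell metadata missing columns: {missing}")
    df = df.copy()
    df["cell_id"] = df["cell_id"].astype(str)
    _check_unique_ids(df["cell_id"], "cell_id")
    # cluster -> broad type must be a function
    mapping = df.groupby("cluster_id")["broad_type"].nunique()
    multi = mapping[mapping > 1].index.tolist()
    if multi:
        raise MetadataError(f"clusters mapped to more than one broad type: {multi}")
    bad_bt = set(df["broad_type"]) - set(BROAD_TYPES)
    if bad_bt:
        raise MetadataError(f"unknown broad types: {sorted(bad_bt)}")
    pm = df["pct_mito"].to_numpy(float)
    if ((pm < 0) | (pm > 100)).any():
        raise MetadataError("pct_mito must lie in [0, 100]")
    return df


def read_cell_metadata(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"{path}: not a readable TSV ({exc})") from exc
    return validate_cell_metadata(df)


def validate_ortholog_map(df: pd.DataFrame) -> pd.DataFrame:
    """Check relationship labels against actual source/target multiplicities."""
    missing = [c for c in ORTHOLOG_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"ortholog map missing columns: {missing}")
    bad = set(df["relationship"]) - set(RELATIONSHIPS)
    if bad:
        raise ValidationError(f"unknown ortholog relationship labels: {sorted(bad)}")
    src_counts = df["source_gene"].value_counts()
    tgt_counts = df["target_gene"].value_counts()
    one2one = df[df["relationship"] == "one2one"]
    bad_rows = one2one[
        (one2one["source_gene"].map(src_counts) != 1)
        | (one2one["target_gene"].map(tgt_counts) != 1)
    ]
    if len(bad_rows):
        g = bad_rows["source_gene"].tolist()[:5]
        raise ValidationError(f"records labeled one2one with non-unique genes: {g}")
    return df.reset_index(drop=True)


def read_ortholog_map(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"{path}: not a readable TSV ({exc})") from exc
    return validate_ortholog_map(df)


def write_ortholog_map(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def one2one_pairs(omap: pd.DataFrame) -> dict[str, str]:
    """source -> target dictionary restricted to one2one records."""
    sub = omap[omap["relationship"] == "one2one"]
    return dict(zip(sub["source_gene"], sub["target_gene"]))


@dataclass
class GeneSetCollection:
    """Named gene sets: term_id -> (description, set of gene ids)."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for term, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {term!r} is empty")

    def __len__(self):
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, term):
        return self.sets[term]

    def items(self):
        return self.sets.items()


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: term <tab> description <tab> gene [<tab> gene ...]."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.strip() == "":
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            term, desc, genes = fields[0], fields[1], fields[2:]
            if term in sets:
                raise ParseError(f"{path}:{lineno}: duplicate term {term!r}")
            sets[term] = {g for g in genes if g != ""}
            descriptions[term] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(gsc: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term in sorted(gsc.sets):
            genes = "\t".join(sorted(gsc.sets[term]))
            fh.write(f"{term}\t{gsc.descriptions.get(term, '')}\t{genes}\n")


@dataclass
class PipelineConfig:
    """All tunable thresholds of the cascade in one reproducible object.

    Defaults follow the study design this package models: a detectability
    cutoff at the global median of the normalized comparison submatrix, a
    1.5 fold-change cutoff, BH-adjusted significance at 0.05, single-cell
    QC at 1000 UMI / 500 genes / 15% mitochondrial content, and per-analysis
    K-means k of 3 (development), 6 (DES), 8 (KTZ) and 4 (shared).
    """

    seed: int = 0
    detectable_quantile: float = 0.5
    fc_cutoff: float = 1.5
    alpha: float = 0.05
    qc_min_umi: int = 1000
    qc_min_genes: int = 500
    qc_max_pct_mito: float = 15.0
    kmeans_k: dict = field(
        default_factory=lambda: {"development": 3, "DES": 6, "KTZ": 8, "shared": 4}
    )
    deconv_nu: float | None = None  # None -> 1e-8 * mean(x^2), set at solve time
    deconv_tol: float = 1e-6
    deconv_max_iter: int = 1000
    enrichment_min_genes: int = 2
    marker_top_n: int = 200
    variable_gene_cap: int = 3000
    mito_prefix: str = "mt-"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.fc_cutoff <= 1:
            raise ValidationError("fc_cutoff must exceed 1")
        for name in ("qc_min_umi", "qc_min_genes", "deconv_max_iter", "enrichment_min_genes"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.qc_max_pct_mito <= 0 or self.deconv_tol <= 0:
            raise ValidationError("qc_max_pct_mito and deconv_tol must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
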