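"""Readers, writers, and validated containers for the pipeline's file formats.

Expression matrices travel as GCT v1.2 (the format GTEx uses for gene read
counts), sample annotations and gene catalogs as tab-separated text.  All
readers validate on ingest: dimension mismatches, duplicate identifiers and
unknown category strings are errors, not warnings.
"""

from __future__ import annotations

import gzip
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleTable",
    "MatrisomeCatalog",
    "FormatError",
    "SchemaError",
    "ValidationError",
    "read_gct",
    "write_gct",
    "read_sample_table",
    "read_catalog",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class SchemaError(ValueError):
    """A table is missing a mandatory column."""


class ValidationError(ValueError):
    """Content-level constraint violated (duplicates, bad categories, ...)."""


EXPRESSION_UNITS = ("raw_counts", "vst", "log_cpm", "tpm", "quantile")

#: Matrisome divisions and the categories inside each.
CORE_CATEGORIES = ("collagens", "proteoglycans", "ECM_glycoproteins")
ASSOCIATED_CATEGORIES = ("ECM_regulators", "ECM_affiliated", "secreted_factors")
ALL_CATEGORIES = CORE_CATEGORIES + ASSOCIATED_CATEGORIES

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def strip_gene_version(gene_id: str) -> str:
    """Remove a trailing Ensembl version suffix (``ENSG...12.5`` -> ``ENSG...12``)."""
    return _VERSION_SUFFIX.sub("", gene_id)


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with a units tag.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with one column per sample.
    units
        One of ``raw_counts``, ``vst``, ``log_cpm``, ``tpm``, ``quantile``.
    gene_descriptions
        Optional free-text per-gene annotations (the GCT Description column).
    """

    data: pd.DataFrame
    units: str = "raw_counts"
    gene_descriptions: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.units not in EXPRESSION_UNITS:
            raise ValidationError(
                f"unknown units {self.units!r}; expected one of {EXPRESSION_UNITS}"
            )
        dup_genes = self.data.index[self.data.index.duplicated()].unique()
        if len(dup_genes):
            raise ValidationError(f"duplicate gene ids: {sorted(dup_genes)}")
        dup_samples = self.data.columns[self.data.columns.duplicated()].unique()
        if len(dup_samples):
            raise ValidationError(f"duplicate sample ids: {sorted(dup_samples)}")
        values = self.data.to_numpy()
        if values.size and np.nanmin(values) < 0:
            raise ValidationError("expression values must be non-negative")
        if self.units == "raw_counts" and values.size:
            if not np.allclose(values, np.round(values), atol=1e-8):
                raise ValidationError("raw counts must be integers")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in self.data.index if g in set(genes)]
        desc = self.gene_descriptions.loc[keep] if self.gene_descriptions is not None else None
        return ExpressionMatrix(self.data.loc[keep], units=self.units, gene_descriptions=desc)

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        keep = [s for s in self.data.columns if s in set(samples)]
        return ExpressionMatrix(
            self.data[keep], units=self.units, gene_descriptions=self.gene_descriptions
        )

    def with_units(self, data: pd.DataFrame, units: str) -> "ExpressionMatrix":
        """A new matrix with fresh values but this matrix's annotations."""
        return ExpressionMatrix(data, units=units, gene_descriptions=self.gene_descriptions)


# Canonical SampleTable columns.  sample_id is the index.
SAMPLE_FIELDS = (
    "subject_id",
    "tissue",
    "age",
    "sex",
    "ischemic_time",
    "hardy_scale",
    "batch",
    "bmi",
    "disease",
)
MANDATORY_SAMPLE_FIELDS = ("subject_id", "tissue")

HARDY_LEVELS = ["0", "1", "2", "3", "4", "missing"]
DISEASE_LEVELS = ("normal", "ventilator_injury", "ALI", "IPF", "cancer", "none")


@dataclass
class SampleTable:
    """Per-sample covariates, indexed by sample id.

    Missing categorical covariates are kept as an explicit ``"missing"``
    level; missing numeric covariates stay NaN and the sample is excluded
    from models that need the field.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique()
            raise ValidationError(f"duplicate sample ids: {sorted(dups)}")
        for col in SAMPLE_FIELDS:
            if col not in self.data.columns:
                self.data[col] = pd.NA
        if "age" in self.data:
            ages = pd.to_numeric(self.data["age"], errors="coerce")
            if (ages.dropna() <= 0).any():
                raise ValidationError("age must be > 0 where present")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def for_samples(self, sample_ids: Iterable[str]) -> "SampleTable":
        sample_ids = list(sample_ids)
        missing = set(sample_ids) - set(self.data.index)
        if missing:
            raise ValidationError(f"samples absent from annotation: {sorted(missing)[:5]}")
        return SampleTable(self.data.loc[sample_ids].copy())

    def tissue_of(self) -> pd.Series:
        return self.data["tissue"]


@dataclass
class MatrisomeCatalog:
    """Gene -> (division, category) matrisome assignments.

    The analysis gene set used throughout the pipeline is the union of the
    core matrisome (collagens, proteoglycans, ECM glycoproteins) with the
    ECM regulators; ECM-affiliated proteins and secreted factors are carried
    in the catalog but excluded from that selector.
    """

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["division", "category"]))

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].unique()
            raise ValidationError(f"duplicate catalog genes: {sorted(dups)}")
        bad = set(self.table["category"]) - set(ALL_CATEGORIES)
        if bad:
            raise ValidationError(f"unknown matrisome categories: {sorted(bad)}")
        bad_div = set(self.table["division"]) - {"core", "associated"}
        if bad_div:
            raise ValidationError(f"unknown divisions: {sorted(bad_div)}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def genes(self) -> set[str]:
        return set(self.table.index)

    def category_of(self, gene_id: str) -> str | None:
        if gene_id in self.table.index:
            return self.table.loc[gene_id, "category"]
        return None

    def genes_in_category(self, category: str) -> set[str]:
        if category not in ALL_CATEGORIES:
            raise ValidationError(f"unknown category {category!r}")
        return set(self.table.index[self.table["category"] == category])

    def core_plus_regulators(self) -> set[str]:
        """The core matrisome plus ECM regulators — the analysis gene set."""
        keep = set(CORE_CATEGORIES) | {"ECM_regulators"}
        return set(self.table.index[self.table["category"].isin(keep)])


# ---------------------------------------------------------------------------
# GCT v1.2
# ---------------------------------------------------------------------------

def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_gct(path: str | Path, units: str = "raw_counts") -> ExpressionMatrix:
    """Read a GCT v1.2 expression file.

    The first line carries the version tag (``#1.2``), the second the
    declared ``n_genes<TAB>n_samples``, the third the column header
    (``Name``, ``Description``, then sample ids).  Ensembl version suffixes
    are stripped from gene ids; a collision after stripping is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with _open_text(path) as fh:
        version = fh.readline().strip()
        if not version.startswith("#1."):
            raise FormatError(f"{path}: missing GCT version tag, got {version!r}")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise FormatError(f"{path}: malformed dimensions line")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        body = pd.read_csv(fh, sep="\t", header=0, dtype={0: str, 1: str})
    if body.shape[0] != n_genes or body.shape[1] - 2 != n_samples:
        raise FormatError(
            f"{path}: header declares {n_genes} genes x {n_samples} samples, "
            f"body has {body.shape[0]} x {body.shape[1] - 2}"
        )
    raw_ids = body.iloc[:, 0].astype(str)
    stripped = raw_ids.map(strip_gene_version)
    collided = stripped[stripped.duplicated(keep=False)]
    if len(collided):
        offenders = sorted(raw_ids[stripped.isin(collided)].tolist())
        raise ValidationError(
            f"gene ids collide after version stripping: {offenders}"
        )
    desc = pd.Series(body.iloc[:, 1].values, index=stripped.values, name="Description")
    data = body.iloc[:, 2:].copy()
    data.index = pd.Index(stripped.values, name="gene_id")
    return ExpressionMatrix(data, units=units, gene_descriptions=desc)


def write_gct(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a GCT v1.2 file (gzip if the path ends in ``.gz``)."""
    desc = matrix.gene_descriptions
    if desc is None:
        desc = pd.Series("na", index=matrix.data.index)
    with _open_text(path, "wt") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
        out = matrix.data.copy()
        out.insert(0, "Description", desc.reindex(matrix.data.index).fillna("na").values)
        out.insert(0, "Name", matrix.data.index.values)
        out.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample annotations
# ---------------------------------------------------------------------------

#: Schema mirroring the GTEx v8 annotation column names.
GTEX_SCHEMA: Mapping[str, str] = {
    "SAMPID": "sample_id",
    "SUBJID": "subject_id",
    "SMTSD": "tissue",
    "AGE": "age",
    "SEX": "sex",
    "SMTSISCH": "ischemic_time",
    "DTHHRDY": "hardy_scale",
    "SMGEBTCH": "batch",
    "BMI": "bmi",
    "DISEASE": "disease",
}

DEFAULT_SEX_CODES = {"1": "M", "2": "F", "M": "M", "F": "F", "male": "M", "female": "F"}


def read_sample_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    sex_codes: Mapping[str, str] | None = None,
) -> SampleTable:
    """Read a tab-separated sample annotation table.

    ``schema`` maps file column names to canonical fields (sample_id,
    subject_id, tissue, age, sex, ischemic_time, hardy_scale, batch, bmi,
    disease).  Rows missing a mandatory field are flagged in a ``flagged``
    column rather than dropped.  A mandatory column absent from the file is
    a :class:`SchemaError`.
    """
    schema = dict(schema or GTEX_SCHEMA)
    sex_codes = dict(sex_codes or DEFAULT_SEX_CODES)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    mapped_targets = set(schema.values())
    for mandatory in ("sample_id",) + MANDATORY_SAMPLE_FIELDS:
        if mandatory not in mapped_targets:
            raise SchemaError(f"schema does not map any column to {mandatory!r}")
    missing_cols = [c for c in schema if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"columns required by schema absent from file: {missing_cols}")
    table = raw[[c for c in schema if c in raw.columns]].rename(columns=schema)
    table = table.set_index("sample_id")

    for col in ("age", "ischemic_time", "bmi"):
        if col in table:
            table[col] = pd.to_numeric(table[col], errors="coerce")
    if "sex" in table:
        table["sex"] = table["sex"].map(lambda v: sex_codes.get(str(v), pd.NA))
    if "hardy_scale" in table:
        hardy = table["hardy_scale"].fillna("missing").astype(str)
        hardy = hardy.where(hardy.isin(HARDY_LEVELS), "missing")
        table["hardy_scale"] = pd.Categorical(hardy, categories=HARDY_LEVELS, ordered=True)
    if "batch" in table:
        table["batch"] = table["batch"].fillna("missing")

    flagged = pd.Series(False, index=table.index)
    for col in MANDATORY_SAMPLE_FIELDS:
        if col in table:
            flagged |= table[col].isna()
    table["flagged"] = flagged
    if flagged.any():
        warnings.warn(
            f"{int(flagged.sum())} rows missing mandatory fields were flagged",
            stacklevel=2,
        )
    return SampleTable(table)


# ---------------------------------------------------------------------------
# Matrisome catalog
# ---------------------------------------------------------------------------

def read_catalog(path: str | Path) -> MatrisomeCatalog:
    """Read a gene -> division/category matrisome catalog (TSV).

    Requires columns ``gene``, ``division``, ``category``.  A gene listed
    twice with conflicting assignments is an error; exact duplicate rows
    are collapsed.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.empty and raw.columns.size == 0:
        return MatrisomeCatalog()
    for col in ("gene", "division", "category"):
        if col not in raw.columns:
            raise SchemaError(f"catalog missing column {col!r}")
    raw = raw.drop_duplicates()
    conflicted = raw["gene"][raw["gene"].duplicated(keep=False)].unique()
    if len(conflicted):
        raise ValidationError(
            f"genes with conflicting catalog assignments: {sorted(conflicted)}"
        )
    table = raw.set_index("gene")[["division", "category"]]
    table.index = table.index.map(strip_gene_version)
    if table.index.duplicated().any():
        dups = sorted(table.index[table.index.duplicated()].unique())
        raise ValidationError(f"catalog genes collide after version stripping: {dups}")
    return MatrisomeCatalog(table)


def write_catalog(catalog: MatrisomeCatalog, path: str | Path) -> None:
    out = catalog.table.copy()
    out.insert(0, "gene", out.index)
    out.to_csv(path, sep="\t", index=False)
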