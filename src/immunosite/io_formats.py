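"""Readers and writers for every external format the pipeline touches.

All downstream modules operate on the in-memory domain types defined here:
:class:`ExpressionMatrix`, :class:`ContigTable` (a validated DataFrame),
:class:`CellTable`, :class:`GeneSet` and :class:`ViralReferenceTable`.
Gzip is supported transparently for all text inputs.

Conventions
-----------
* Gene identity is the symbol string, case-sensitive; no alias resolution.
* Barcode identity is the literal string including any ``-1`` suffix.
* Parsing is order-stable: permuting input rows permutes output rows
  identically.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "concat_cells",
    "TISSUES",
    "LINEAGES",
    "read_mtx_triplet",
    "write_mtx_triplet",
    "read_contig_table",
    "write_contig_table",
    "read_cell_table",
    "write_cell_table",
    "read_gmt",
    "write_gmt",
    "read_viral_reference",
    "write_viral_reference",
]

TISSUES = ("blood", "liver", "tumor")
LINEAGES = ("CD4", "CD8", "NK", "myeloid", "B", "other")

CONTIG_REQUIRED_COLUMNS = ("barcode", "chain", "cdr3", "cdr3_nt", "umis", "productive")
CONTIG_OPTIONAL_DEFAULTS = {
    "reads": 0,
    "v_gene": "",
    "j_gene": "",
    "high_confidence": True,
}

CELL_TABLE_COLUMNS = (
    "barcode",
    "sample_id",
    "patient_id",
    "tissue",
    "replicate",
    "cell_type",
    "lineage",
)

_TRUTHY = {"true", "1", "yes", "t"}

# Default column mapping for VDJdb-style exports; user-overridable.
VDJDB_COLUMN_MAP = {
    "cdr3": "cdr3_aa",
    "CDR3": "cdr3_aa",
    "gene": "chain",
    "Gene": "chain",
    "antigen.epitope": "epitope",
    "Epitope": "epitope",
    "antigen.species": "species",
    "Epitope species": "species",
    "reference.id": "source",
    "Reference": "source",
}


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _coerce_bool(value: object) -> bool:
    """Normalize CellRanger-style boolean-like fields.

    ``"True"/"true"/"TRUE"/1`` map to True; everything else, including
    ``"None"``, maps to False.
    """
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer, float, np.floating)):
        return bool(value) and not (isinstance(value, float) and np.isnan(value))
    return str(value).strip().lower() in _TRUTHY


@dataclass
class ExpressionMatrix:
    """Sparse gene x cell raw count matrix for one sample.

    Attributes
    ----------
    genes : list of str
        Ordered gene symbols (rows).
    barcodes : list of str
        Ordered cell barcodes (columns); unique within the sample.
    counts : scipy.sparse.csc_matrix
        Non-negative integer counts, shape ``(len(genes), len(barcodes))``.
    sample_id : str
    """

    genes: list[str]
    barcodes: list[str]
    counts: sp.csc_matrix
    sample_id: str

    def __post_init__(self) -> None:
        self.counts = sp.csc_matrix(self.counts)
        self.validate()

    def validate(self) -> None:
        if len(self.genes) == 0:
            raise ValidationError(f"sample {self.sample_id!r}: empty gene list")
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise ValidationError(
                f"sample {self.sample_id!r}: counts shape {self.counts.shape} "
                f"inconsistent with {len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            dupes = pd.Series(self.barcodes)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValidationError(
                f"sample {self.sample_id!r}: duplicate barcodes {dupes[:5]}"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError(f"sample {self.sample_id!r}: negative counts")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def cell_n_features(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def subset_cells(self, keep: Sequence[int] | np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep, dtype=int)
        return ExpressionMatrix(
            genes=list(self.genes),
            barcodes=[self.barcodes[i] for i in keep],
            counts=self.counts[:, keep],
            sample_id=self.sample_id,
        )

    def column_of(self, barcode: str) -> np.ndarray:
        j = self.barcodes.index(barcode)
        return np.asarray(self.counts[:, j].todense()).ravel()


def concat_cells(
    matrices: Sequence[ExpressionMatrix],
    sample_id: str = "combined",
    prefix_barcodes: bool = False,
) -> ExpressionMatrix:
    """Horizontally concatenate matrices sharing one gene universe.

    With ``prefix_barcodes`` each barcode becomes ``sample:barcode`` so the
    result stays unique even when raw barcodes collide across samples;
    otherwise raw barcodes are kept and must already be globally unique
    (validated by the constructor).
    """
    if not matrices:
        raise ValidationError("no matrices to concatenate")
    genes = matrices[0].genes
    for m in matrices[1:]:
        if m.genes != genes:
            raise ValidationError("matrices have different gene universes")
    if prefix_barcodes:
        barcodes = [f"{m.sample_id}:{bc}" for m in matrices for bc in m.barcodes]
    else:
        barcodes = [bc for m in matrices for bc in m.barcodes]
    counts = sp.hstack([m.counts for m in matrices], format="csc")
    return ExpressionMatrix(genes=list(genes), barcodes=barcodes, counts=counts, sample_id=sample_id)


@dataclass(frozen=True)
class GeneSet:
    """Named gene list with provenance; symbols deduplicated case-sensitively."""

    name: str
    genes: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("gene set requires a name")
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# Matrix Market triplet
# ---------------------------------------------------------------------------

def _read_lines(path: str | Path) -> list[str]:
    with _open_text(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_mtx_triplet(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    sample_id: str,
) -> ExpressionMatrix:
    """Read a 10x-style triplet (matrix.mtx + features + barcodes).

    Feature files may be one symbol per line or multi-column TSV whose first
    column is the symbol (10x emits id/symbol/type); barcode files are one
    barcode per line. Plain or gzip.
    """
    with _open_text(matrix_path, "rt") as fh:
        try:
            counts = scipy.io.mmread(io.StringIO(fh.read()))
        except Exception as exc:  # noqa: BLE001 - rewrap with file context
            raise FormatError(f"{matrix_path}: not valid Matrix Market ({exc})") from exc
    counts = sp.csc_matrix(counts)
    genes = _read_lines(features_path)
    barcodes = _read_lines(barcodes_path)
    if counts.shape[0] != len(genes):
        raise FormatError(
            f"{features_path}: {len(genes)} features but matrix header declares "
            f"{counts.shape[0]} rows"
        )
    if counts.shape[1] != len(barcodes):
        raise FormatError(
            f"{barcodes_path}: {len(barcodes)} barcodes but matrix header declares "
            f"{counts.shape[1]} columns"
        )
    return ExpressionMatrix(genes=genes, barcodes=barcodes, counts=counts, sample_id=sample_id)


def write_mtx_triplet(
    matrix: ExpressionMatrix,
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    """Write the triplet back out (plain text; paired with read_mtx_triplet)."""
    buf = io.BytesIO()
    scipy.io.mmwrite(buf, sp.coo_matrix(matrix.counts), field="integer")
    Path(matrix_path).write_bytes(buf.getvalue())
    with _open_text(features_path, "wt") as fh:
        fh.write("\n".join(matrix.genes) + "\n")
    with _open_text(barcodes_path, "wt") as fh:
        fh.write("\n".join(matrix.barcodes) + "\n")


# ---------------------------------------------------------------------------
# CellRanger VDJ contig table
# ---------------------------------------------------------------------------

def read_contig_table(path: str | Path) -> pd.DataFrame:
    """Read a filtered-contig annotation CSV into a typed ContigTable.

    Required columns: barcode, chain, cdr3, cdr3_nt, umis, productive.
    Optional columns (reads, v_gene, j_gene, high_confidence) are defaulted
    when absent. Boolean-like strings are normalized; ``"None"`` is False.
    """
    with _open_text(path) as fh:
        df = pd.read_csv(fh, dtype=str, keep_default_na=False)
    missing = [c for c in CONTIG_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    for col, default in CONTIG_OPTIONAL_DEFAULTS.items():
        if col not in df.columns:
            df[col] = default
    df = df.loc[:, list(CONTIG_REQUIRED_COLUMNS) + list(CONTIG_OPTIONAL_DEFAULTS)]
    df["umis"] = pd.to_numeric(df["umis"], errors="raise").astype(int)
    df["reads"] = pd.to_numeric(df["reads"], errors="raise").astype(int)
    df["productive"] = df["productive"].map(_coerce_bool)
    df["high_confidence"] = df["high_confidence"].map(_coerce_bool)
    return validate_contig_table(df, name=str(path))


def validate_contig_table(df: pd.DataFrame, name: str = "contigs") -> pd.DataFrame:
    if (df["umis"] < 0).any():
        raise ValidationError(f"{name}: negative UMI counts")
    productive = df.loc[df["productive"], "cdr3_nt"]
    bad = productive[~productive.str.fullmatch(r"[ACGT]+")]
    if len(bad):
        raise ValidationError(
            f"{name}: productive contigs with invalid cdr3_nt, e.g. {bad.iloc[0]!r}"
        )
    return df.reset_index(drop=True)


def write_contig_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in ("productive", "high_confidence"):
        out[col] = out[col].map({True: "True", False: "False"})
    with _open_text(path, "wt") as fh:
        out.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Per-cell annotation table
# ---------------------------------------------------------------------------

def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read the per-cell annotation TSV (barcode, sample, patient, tissue,
    replicate, cell type, lineage)."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    df = df.loc[:, list(CELL_TABLE_COLUMNS)]
    df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
    return validate_cell_table(df, name=str(path))


def validate_cell_table(df: pd.DataFrame, name: str = "cells") -> pd.DataFrame:
    bad_tissue = sorted(set(df["tissue"]) - set(TISSUES))
    if bad_tissue:
        raise ValidationError(f"{name}: unknown tissue values {bad_tissue}")
    bad_lineage = sorted(set(df["lineage"]) - set(LINEAGES))
    if bad_lineage:
        raise ValidationError(f"{name}: unknown lineage values {bad_lineage}")
    if (df["replicate"] < 1).any():
        raise ValidationError(f"{name}: replicate index must be >= 1")
    if df.duplicated(["barcode", "sample_id"]).any():
        dupes = df.loc[df.duplicated(["barcode", "sample_id"]), "barcode"]
        raise ValidationError(f"{name}: duplicate (barcode, sample_id), e.g. {dupes.iloc[0]!r}")
    return df.reset_index(drop=True)


def write_cell_table(df: pd.DataFrame, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate genes within a line are dropped with a warning.
    """
    sets: list[GeneSet] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, description = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                warnings.warn(
                    f"{path}:{lineno}: gene set {name!r} contains duplicate symbols; deduplicated",
                    stacklevel=2,
                )
            sets.append(GeneSet(name=name, genes=frozenset(unique), source=description))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.source or "na", *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# VDJdb-style viral reference
# ---------------------------------------------------------------------------

def read_viral_reference(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a VDJdb-style TSV of CDR3 -> epitope annotations.

    ``column_map`` maps dialect column names onto the canonical names
    (cdr3_aa, chain, epitope, species, source); the default covers common
    VDJdb exports. Chain values are normalized to TRA/TRB; duplicates of
    (cdr3_aa, chain, epitope) are collapsed to their first occurrence.
    """
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    mapping = dict(VDJDB_COLUMN_MAP)
    if column_map:
        mapping.update(column_map)
    df = df.rename(columns={c: mapping[c] for c in df.columns if c in mapping})
    required = ["cdr3_aa", "chain", "epitope", "species"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if "source" not in df.columns:
        df["source"] = ""
    df = df.loc[:, required + ["source"]]
    chain_norm = {"TRA": "TRA", "TRB": "TRB", "A": "TRA", "B": "TRB", "ALPHA": "TRA", "BETA": "TRB"}
    normalized = df["chain"].str.upper().map(chain_norm)
    if normalized.isna().any():
        bad = sorted(df.loc[normalized.isna(), "chain"].unique())
        raise ValidationError(f"{path}: unmappable chain values {bad}")
    df["chain"] = normalized
    if (df["cdr3_aa"].str.len() == 0).any():
        raise ValidationError(f"{path}: empty cdr3_aa values")
    df = df.drop_duplicates(["cdr3_aa", "chain", "epitope"], keep="first")
    return df.reset_index(drop=True)


def write_viral_reference(df: pd.DataFrame, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False)
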