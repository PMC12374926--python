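"""Paired-chain clonotype assembly, per-sample repertoires and expansion bins.

A clonotype is identified by its paired CDR3 alpha and beta *nucleotide*
sequences; amino-acid sequences are carried as metadata for downstream
annotation. All clonotype-bearing cells of one sample form its "TCR pool",
the denominator for clone frequencies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from .errors import ValidationError

__all__ = [
    "Clonotype",
    "Repertoire",
    "ExpansionBinning",
    "EXPANSION_BINS",
    "assemble_clonotypes",
    "build_repertoire",
    "bin_expansion",
    "expanded_composition",
]

EXPANSION_BINS = ("unique", "rare", "small", "medium", "large", "hyperexpanded")


@dataclass(frozen=True)
class Clonotype:
    """Paired CDR3 clone identity.

    Equality and hashing use the nucleotide pair only; amino-acid fields are
    metadata (used e.g. for viral annotation) and ignored for identity.
    """

    cdr3a_nt: str
    cdr3b_nt: str
    cdr3a_aa: str = ""
    cdr3b_aa: str = ""

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Clonotype):
            return NotImplemented
        return (self.cdr3a_nt, self.cdr3b_nt) == (other.cdr3a_nt, other.cdr3b_nt)

    def __hash__(self) -> int:
        return hash((self.cdr3a_nt, self.cdr3b_nt))

    @property
    def key(self) -> str:
        """Deterministic sort key / serialization id."""
        return f"{self.cdr3a_nt}|{self.cdr3b_nt}"


@dataclass
class Repertoire:
    """Per-sample clone-count multiset ("TCR pool")."""

    sample_id: str
    clone_counts: dict[Clonotype, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for clone, count in self.clone_counts.items():
            if count < 1:
                raise ValidationError(
                    f"repertoire {self.sample_id!r}: clone {clone.key} has count {count} < 1"
                )

    @property
    def pool_size(self) -> int:
        return sum(self.clone_counts.values())

    @property
    def n_clones(self) -> int:
        return len(self.clone_counts)

    def frequency(self, clone: Clonotype) -> float:
        """Clone frequency in the pool; exactly 0.0 when absent."""
        count = self.clone_counts.get(clone, 0)
        return count / self.pool_size if count else 0.0

    def clone_set(self) -> set[Clonotype]:
        return set(self.clone_counts)


@dataclass(frozen=True)
class ExpansionBinning:
    """Frequency boundaries separating rare/small/medium/large/hyperexpanded.

    A clone of absolute count 1 is "unique" regardless of frequency; every
    boundary is half-open on the right except the last, which is closed below
    (f >= hyper boundary -> hyperexpanded).
    """

    rare_max: float = 0.001
    small_max: float = 0.01
    medium_max: float = 0.02
    large_max: float = 0.05

    def __post_init__(self) -> None:
        bounds = (self.rare_max, self.small_max, self.medium_max, self.large_max)
        if not all(b1 < b2 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValidationError(f"bin boundaries must be strictly increasing: {bounds}")

    def bin_of(self, count: int, pool_size: int) -> str:
        if count == 1:
            return "unique"
        f = count / pool_size
        if f < self.rare_max:
            return "rare"
        if f < self.small_max:
            return "small"
        if f < self.medium_max:
            return "medium"
        if f < self.large_max:
            return "large"
        return "hyperexpanded"


def _select_chain(group: pd.DataFrame) -> pd.Series:
    # UMI-dominant chain; ties -> higher read count, then lexicographically
    # smallest cdr3_nt, so assembly is invariant to contig row order.
    ordered = group.sort_values(
        ["umis", "reads", "cdr3_nt"], ascending=[False, False, True], kind="mergesort"
    )
    return ordered.iloc[0]


def assemble_clonotypes(
    contigs: pd.DataFrame,
    beta_only: bool = False,
) -> dict[str, Optional[Clonotype]]:
    """Map each barcode to its paired clonotype, or None when unpaired.

    Only productive, high-confidence TRA/TRB contigs are considered; per
    barcode per locus the UMI-dominant chain wins. Barcodes lacking either
    locus map to None (excluded from repertoires), unless ``beta_only`` is
    set, in which case a TRB alone defines the clonotype (alpha fields empty).
    """
    result: dict[str, Optional[Clonotype]] = {}
    if contigs.empty:
        return result
    usable = contigs[
        contigs["productive"]
        & contigs["high_confidence"]
        & contigs["chain"].isin(["TRA", "TRB"])
    ]
    selected: dict[str, dict[str, pd.Series]] = {}
    for (barcode, chain), group in usable.groupby(["barcode", "chain"], sort=False):
        selected.setdefault(barcode, {})[chain] = _select_chain(group)

    for barcode in contigs["barcode"].unique():
        chains = selected.get(barcode, {})
        tra, trb = chains.get("TRA"), chains.get("TRB")
        if trb is not None and (tra is not None or beta_only):
            result[barcode] = Clonotype(
                cdr3a_nt=tra["cdr3_nt"] if tra is not None else "",
                cdr3b_nt=trb["cdr3_nt"],
                cdr3a_aa=tra["cdr3"] if tra is not None else "",
                cdr3b_aa=trb["cdr3"],
            )
        else:
            result[barcode] = None
    return result


def build_repertoire(
    cell_clonotypes: Mapping[str, Optional[Clonotype]],
    cells: pd.DataFrame,
    sample_id: str,
) -> Repertoire:
    """Tally clonotype-bearing cells of one sample into a Repertoire."""
    if sample_id not in set(cells["sample_id"]):
        raise LookupError(f"sample {sample_id!r} not present in the cell table")
    sample_barcodes = cells.loc[cells["sample_id"] == sample_id, "barcode"]
    counts: Counter[Clonotype] = Counter()
    for barcode in sample_barcodes:
        clone = cell_clonotypes.get(barcode)
        if clone is not None:
            counts[clone] += 1
    return Repertoire(sample_id=sample_id, clone_counts=dict(counts))


def bin_expansion(
    rep: Repertoire,
    binning: ExpansionBinning = ExpansionBinning(),
) -> dict[Clonotype, str]:
    """Assign every clone of the repertoire to exactly one expansion bin."""
    if rep.pool_size == 0:
        raise ValidationError(f"repertoire {rep.sample_id!r} is empty")
    return {
        clone: binning.bin_of(count, rep.pool_size)
        for clone, count in rep.clone_counts.items()
    }


def expanded_composition(
    rep: Repertoire,
    cells: pd.DataFrame,
    cell_clonotypes: Mapping[str, Optional[Clonotype]],
    binning: ExpansionBinning = ExpansionBinning(),
) -> dict[str, float]:
    """Cell-type composition of expanded (non-unique) clones in one sample.

    Returns fractions over cells that belong to expanded clones; empty when
    no clone is expanded.
    """
    if rep.pool_size == 0:
        return {}
    bins = bin_expansion(rep, binning)
    expanded = {clone for clone, b in bins.items() if b != "unique"}
    sample_cells = cells[cells["sample_id"] == rep.sample_id]
    tally: Counter[str] = Counter()
    for barcode, cell_type in zip(sample_cells["barcode"], sample_cells["cell_type"]):
        clone = cell_clonotypes.get(barcode)
        if clone is not None and clone in expanded:
            tally[cell_type] += 1
    total = sum(tally.values())
    return {cell_type: n / total for cell_type, n in tally.items()}
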