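"""Tumor-reactivity nomination: TIL eligibility filtering, per-signature
top-percentile cuts, consensus intersection and cross-site tracking.

Eligible cells are tumor-tissue alpha/beta T cells with an assembled paired
clonotype, minus regulatory T cells, MAIT cells (identified mechanically by
a productive TRAV1-2 alpha contig), gamma-delta T cells and cycling cells —
populations that mimic the reactive transcriptional state or carry
semi-invariant receptors. Every removed cell is logged under exactly one
primary reason.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .repertoire import Clonotype, Repertoire
from .signature_scoring import ScoreTable
from .tracking import track_clones

__all__ = [
    "EligibilityConfig",
    "NominationResult",
    "DEFAULT_PAIRING",
    "filter_tils",
    "nominate",
    "consensus",
    "track_consensus",
]

# Default lineage pairing: two signatures per lineage, consensus = both.
DEFAULT_PAIRING: dict[str, tuple[str, str]] = {
    "CD8": ("NeoTCR8", "TR30"),
    "CD4": ("NeoTCR4", "ExReCD4"),
}

EXCLUSION_REASONS = (
    "non_tumor_tissue",
    "not_t_cell",
    "treg",
    "mait",
    "gamma_delta",
    "cycling",
    "no_paired_tcr",
)


@dataclass(frozen=True)
class EligibilityConfig:
    """Label sets and the MAIT V-gene rule used by :func:`filter_tils`."""

    treg_labels: frozenset[str] = frozenset({"Treg", "Tregs"})
    gd_labels: frozenset[str] = frozenset({"gd T", "gamma delta T", "gdT"})
    cycling_labels: frozenset[str] = frozenset(
        {"cycling T", "proliferating T", "proliferating/cycling T"}
    )
    mait_v_gene_prefix: str = "TRAV1-2"
    top_cell_percent: float = 5.0


@dataclass
class NominationResult:
    """Per-signature nominations plus per-lineage consensus."""

    nominated: dict[str, dict[str, float]] = field(default_factory=dict)
    signature_lineage: dict[str, str] = field(default_factory=dict)
    consensus_barcodes: dict[str, set[str]] = field(default_factory=dict)
    # lineage -> ordered list of (clonotype, n_nominating_signatures, mean score)
    consensus_clonotypes: dict[str, list[tuple[Clonotype, int, float]]] = field(default_factory=dict)
    exclusion_log: dict[str, str] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "nominated": {sig: dict(sorted(d.items())) for sig, d in self.nominated.items()},
            "signature_lineage": dict(self.signature_lineage),
            "consensus_barcodes": {lin: sorted(s) for lin, s in self.consensus_barcodes.items()},
            "consensus_clonotypes": {
                lin: [
                    {"clonotype": c.key, "n_signatures": n, "mean_score": score}
                    for c, n, score in ranked
                ]
                for lin, ranked in self.consensus_clonotypes.items()
            },
            "exclusion_log": dict(self.exclusion_log),
            "notes": list(self.notes),
        }


def filter_tils(
    cells: pd.DataFrame,
    cell_clonotypes: Mapping[str, Optional[Clonotype]],
    contigs: pd.DataFrame,
    config: EligibilityConfig = EligibilityConfig(),
) -> tuple[set[str], dict[str, str]]:
    """Select nomination-eligible TIL barcodes and log every exclusion.

    Returns (eligible barcode set, exclusion log barcode -> primary reason).
    The log partitions removed cells: each barcode appears under exactly the
    first reason that applies, in the order non-tumor tissue, not a T cell,
    Treg, MAIT, gamma-delta, cycling, no paired TCR.
    """
    mait_barcodes: set[str] = set(
        contigs.loc[
            contigs["productive"]
            & (contigs["chain"] == "TRA")
            & contigs["v_gene"].astype(str).str.startswith(config.mait_v_gene_prefix),
            "barcode",
        ]
    )
    t_labels = config.treg_labels | config.gd_labels | config.cycling_labels

    eligible: set[str] = set()
    log: dict[str, str] = {}
    for row in cells.itertuples(index=False):
        barcode = row.barcode
        if row.tissue != "tumor":
            log[barcode] = "non_tumor_tissue"
        elif row.lineage not in ("CD4", "CD8") and row.cell_type not in t_labels:
            log[barcode] = "not_t_cell"
        elif row.cell_type in config.treg_labels:
            log[barcode] = "treg"
        elif barcode in mait_barcodes:
            log[barcode] = "mait"
        elif row.cell_type in config.gd_labels:
            log[barcode] = "gamma_delta"
        elif row.cell_type in config.cycling_labels:
            log[barcode] = "cycling"
        elif cell_clonotypes.get(barcode) is None:
            log[barcode] = "no_paired_tcr"
        else:
            eligible.add(barcode)
    return eligible, log


def _top_cut(scores: pd.Series, percent: float) -> tuple[pd.Series, list[str]]:
    """Take the top ``percent`` of cells by score, threshold ties included."""
    notes: list[str] = []
    n = len(scores)
    if n < 20:
        k = max(1, round(percent / 100.0 * n))
        notes.append(f"only {n} eligible cells: nominating top {k} directly")
    else:
        k = max(1, math.ceil(percent / 100.0 * n))
    threshold = scores.sort_values(ascending=False).iloc[k - 1]
    nominated = scores[scores >= threshold]
    if len(nominated) == n and n > 1:
        notes.append("degenerate scores: every eligible cell reaches the threshold")
    return nominated, notes


def nominate(
    scores: ScoreTable,
    eligible: set[str],
    lineage_map: Mapping[str, str],
    signature_lineage: Mapping[str, str],
    config: EligibilityConfig = EligibilityConfig(),
) -> NominationResult:
    """Per-signature top-percent nomination among eligible cells.

    Each signature is declared CD4- or CD8-targeted via
    ``signature_lineage``; its ranking is restricted to eligible cells of
    that lineage. The cut keeps the top ``top_cell_percent`` of cells; ties
    at the threshold are all included, so the set may exceed the nominal
    fraction.
    """
    result = NominationResult(signature_lineage=dict(signature_lineage))
    frame = scores.to_frame()
    for signature, lineage in signature_lineage.items():
        if signature not in scores.signatures:
            raise ConfigurationError(f"signature {signature!r} missing from the score table")
        pool = [
            bc for bc in frame.index
            if bc in eligible and lineage_map.get(bc) == lineage
        ]
        if not pool:
            result.nominated[signature] = {}
            result.notes.append(f"{signature}: no eligible {lineage} cells")
            continue
        column = frame.loc[pool, signature].dropna()
        if column.empty:
            result.nominated[signature] = {}
            result.notes.append(f"{signature}: all scores missing")
            continue
        if len(column) < 20:
            warnings.warn(
                f"{signature}: fewer than 20 eligible cells ({len(column)})", stacklevel=2
            )
        cut, notes = _top_cut(column, config.top_cell_percent)
        result.nominated[signature] = dict(cut)
        result.notes.extend(f"{signature}: {note}" for note in notes)
    return result


def consensus(
    result: NominationResult,
    cell_clonotypes: Mapping[str, Optional[Clonotype]],
    pairing: Mapping[str, Sequence[str]] = DEFAULT_PAIRING,
) -> NominationResult:
    """Intersect per-signature nominations into per-lineage consensus.

    Consensus barcodes are cells nominated by every signature of the
    lineage; consensus clonotypes are their clonotypes, deduplicated and
    ranked by (number of nominating signatures, mean score) descending,
    ties by clonotype key.
    """
    for lineage, signatures in pairing.items():
        missing = [s for s in signatures if s not in result.nominated]
        if missing:
            raise ConfigurationError(
                f"lineage {lineage}: signatures {missing} absent from nominations"
            )
        sets = [set(result.nominated[s]) for s in signatures]
        barcodes = set.intersection(*sets) if sets else set()
        result.consensus_barcodes[lineage] = barcodes
        if not barcodes:
            result.notes.append(f"{lineage}: empty consensus")

        per_clone: dict[Clonotype, list[str]] = {}
        for barcode in barcodes:
            clone = cell_clonotypes.get(barcode)
            if clone is not None:
                per_clone.setdefault(clone, []).append(barcode)
        ranked: list[tuple[Clonotype, int, float]] = []
        for clone, clone_barcodes in per_clone.items():
            n_sigs = sum(
                1 for s in signatures if any(bc in result.nominated[s] for bc in clone_barcodes)
            )
            all_scores = [
                result.nominated[s][bc]
                for s in signatures
                for bc in clone_barcodes
                if bc in result.nominated[s]
            ]
            ranked.append((clone, n_sigs, float(np.mean(all_scores))))
        ranked.sort(key=lambda t: (-t[1], -t[2], t[0].key))
        result.consensus_clonotypes[lineage] = ranked
    return result


def track_consensus(
    result: NominationResult,
    site_repertoires: Sequence[Repertoire],
) -> dict[str, dict[Clonotype, dict[str, float]]]:
    """Frequencies of every consensus clonotype in each blood/liver sample."""
    presence: dict[str, dict[Clonotype, dict[str, float]]] = {}
    for lineage, ranked in result.consensus_clonotypes.items():
        clones = [clone for clone, _, _ in ranked]
        presence[lineage] = track_clones(clones, site_repertoires) if clones else {}
    return presence
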