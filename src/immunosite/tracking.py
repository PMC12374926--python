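"""Cross-site clone tracking and viral (putative bystander) annotation.

Tracking uses nucleotide clonotype identity (the clone definition); viral
annotation matches on amino-acid CDR3 because public references store amino
acids. No HLA restriction filtering is applied, so matches flag *putative*
bystanders only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import ValidationError
from .repertoire import Clonotype, Repertoire

__all__ = [
    "ViralMatch",
    "TrackedClone",
    "top_expanded",
    "track_clones",
    "annotate_viral",
    "tracking_report",
]

ANNOTATION_MODES = ("beta_aa", "alpha_or_beta_aa", "paired_aa")


@dataclass(frozen=True)
class ViralMatch:
    epitope: str
    species: str


@dataclass
class TrackedClone:
    """One clone's per-site frequencies plus optional viral annotation."""

    clonotype: Clonotype
    source_frequency: float
    site_frequencies: dict[str, float] = field(default_factory=dict)
    viral_match: Optional[ViralMatch] = None
    all_viral_matches: list[ViralMatch] = field(default_factory=list)

    @property
    def putative_bystander(self) -> bool:
        return self.viral_match is not None

    def to_dict(self) -> dict:
        return {
            "clonotype": self.clonotype.key,
            "cdr3a_aa": self.clonotype.cdr3a_aa,
            "cdr3b_aa": self.clonotype.cdr3b_aa,
            "source_frequency": self.source_frequency,
            "site_frequencies": dict(self.site_frequencies),
            "viral_match": (
                {"epitope": self.viral_match.epitope, "species": self.viral_match.species}
                if self.viral_match
                else None
            ),
            "putative_bystander": self.putative_bystander,
        }


def top_expanded(rep: Repertoire, n: int = 20) -> list[Clonotype]:
    """The n most expanded clones, descending count, ties by clonotype key."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if rep.pool_size == 0:
        raise ValidationError(f"repertoire {rep.sample_id!r} is empty")
    ordered = sorted(rep.clone_counts.items(), key=lambda kv: (-kv[1], kv[0].key))
    return [clone for clone, _ in ordered[:n]]


def track_clones(
    clones: Sequence[Clonotype],
    repertoires: Sequence[Repertoire],
) -> dict[Clonotype, dict[str, float]]:
    """Frequency of each clone in each repertoire; exactly 0.0 when absent."""
    if not repertoires:
        raise ValidationError("no repertoires to track against")
    return {
        clone: {rep.sample_id: rep.frequency(clone) for rep in repertoires}
        for clone in clones
    }


def annotate_viral(
    clones: Iterable[Clonotype],
    reference: pd.DataFrame,
    mode: str = "beta_aa",
) -> dict[Clonotype, list[ViralMatch]]:
    """Match clone CDR3 amino-acid sequences against a viral reference table.

    Modes: ``beta_aa`` (default) matches the CDR3beta against TRB entries;
    ``alpha_or_beta_aa`` also accepts a CDR3alpha/TRA match; ``paired_aa``
    requires both chains to match. Multiple reference hits are all returned,
    sorted by (species, epitope) so annotation is independent of reference
    row order.
    """
    if mode not in ANNOTATION_MODES:
        raise ValidationError(f"unknown annotation mode {mode!r}")
    by_chain: dict[str, dict[str, list[ViralMatch]]] = {"TRA": {}, "TRB": {}}
    for row in reference.itertuples(index=False):
        by_chain[row.chain].setdefault(row.cdr3_aa, []).append(
            ViralMatch(epitope=row.epitope, species=row.species)
        )

    def hits(chain: str, aa: str) -> list[ViralMatch]:
        return by_chain[chain].get(aa, []) if aa else []

    result: dict[Clonotype, list[ViralMatch]] = {}
    for clone in clones:
        beta = hits("TRB", clone.cdr3b_aa)
        alpha = hits("TRA", clone.cdr3a_aa)
        if mode == "beta_aa":
            matches = beta
        elif mode == "alpha_or_beta_aa":
            matches = beta + alpha
        else:  # paired_aa
            matches = beta + alpha if (beta and alpha) else []
        result[clone] = sorted(set(matches), key=lambda m: (m.species, m.epitope))
    return result


def tracking_report(
    tumor_rep: Repertoire,
    site_repertoires: Sequence[Repertoire],
    viral_reference: Optional[pd.DataFrame] = None,
    n_top: int = 20,
    annotation_mode: str = "beta_aa",
) -> list[TrackedClone]:
    """Top expanded tumor clones tracked into every site, viral-annotated."""
    clones = top_expanded(tumor_rep, n=n_top)
    frequencies = track_clones(clones, site_repertoires)
    if viral_reference is not None:
        annotations = annotate_viral(clones, viral_reference, mode=annotation_mode)
    else:
        annotations = {clone: [] for clone in clones}
    report = []
    for clone in clones:
        matches = annotations[clone]
        report.append(
            TrackedClone(
                clonotype=clone,
                source_frequency=tumor_rep.frequency(clone),
                site_frequencies=frequencies[clone],
                viral_match=matches[0] if matches else None,
                all_viral_matches=matches,
            )
        )
    return report
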