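"""Replicate / sample concordance: cell-type proportion correlation,
pseudobulk expression correlation, repertoire Jaccard matrix.

Pseudobulk sums counts per gene across a sample's cells, scales to counts
per million and applies log(1 + x), so replicates with different cell
numbers are comparable. Correlation defaults to Pearson; Spearman by flag.
All matrices are computed once per unordered pair, hence exactly symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .errors import ValidationError
from .diversity import jaccard
from .io_formats import ExpressionMatrix
from .repertoire import Repertoire

__all__ = ["ConcordanceReport", "celltype_proportions", "pseudobulk", "concordance_report"]


@dataclass
class ConcordanceReport:
    """Three pairwise sample x sample agreement matrices plus metadata."""

    samples: list[str]
    proportion_corr: pd.DataFrame
    pseudobulk_corr: pd.DataFrame
    repertoire_jaccard: pd.DataFrame
    pair_labels: pd.DataFrame  # "self" / "within_patient" / "cross_patient"
    metadata: dict = field(default_factory=dict)


def celltype_proportions(
    cells: pd.DataFrame,
    sample_id: str,
    vocabulary: Sequence[str] | None = None,
) -> pd.Series:
    """Cell-type proportion vector over the global type vocabulary.

    Types absent from the sample get 0 so vectors are commensurate across
    samples; the vector sums to 1.
    """
    sample = cells[cells["sample_id"] == sample_id]
    if sample.empty:
        raise ValidationError(f"sample {sample_id!r} has no cells")
    if vocabulary is None:
        vocabulary = sorted(cells["cell_type"].unique())
    counts = sample["cell_type"].value_counts()
    vec = pd.Series(0.0, index=list(vocabulary))
    for cell_type, n in counts.items():
        if cell_type not in vec.index:
            raise ValidationError(f"cell type {cell_type!r} missing from vocabulary")
        vec[cell_type] = n
    return vec / vec.sum()


def pseudobulk(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> pd.Series:
    """Per-gene log(1 + CPM) profile of the sample's summed counts."""
    if matrix.n_cells == 0:
        raise ValidationError(f"sample {matrix.sample_id!r} has no cells")
    totals = np.asarray(matrix.counts.sum(axis=1)).ravel().astype(float)
    library = totals.sum()
    if library == 0:
        raise ValidationError(f"sample {matrix.sample_id!r} has zero total counts")
    cpm = totals / library * 1e6
    return pd.Series(np.log1p(cpm), index=matrix.genes)


def _correlate(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if np.allclose(x, y):
        return 1.0
    if method == "pearson":
        return float(pearsonr(x, y).statistic)
    return float(spearmanr(x, y).statistic)


def concordance_report(
    cells: pd.DataFrame,
    matrices: Mapping[str, ExpressionMatrix],
    repertoires: Mapping[str, Repertoire],
    correlation: str = "pearson",
) -> ConcordanceReport:
    """All three pairwise agreement matrices over a common sample set."""
    if correlation not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation {correlation!r}")
    samples = sorted(matrices)
    if len(samples) < 2:
        raise ValidationError("concordance needs at least 2 samples")
    if set(repertoires) != set(samples):
        raise ValidationError(
            f"sample sets differ: matrices {sorted(matrices)} vs repertoires {sorted(repertoires)}"
        )
    cell_samples = set(cells["sample_id"])
    missing = [s for s in samples if s not in cell_samples]
    if missing:
        raise ValidationError(f"samples {missing} absent from the cell table")

    vocabulary = sorted(cells["cell_type"].unique())
    proportions = {s: celltype_proportions(cells, s, vocabulary).to_numpy() for s in samples}
    bulks = {s: pseudobulk(matrices[s]).to_numpy() for s in samples}
    patients = cells.drop_duplicates("sample_id").set_index("sample_id")["patient_id"]

    n = len(samples)
    prop = np.eye(n)
    bulk = np.eye(n)
    jac = np.eye(n)
    labels = np.full((n, n), "self", dtype=object)
    for (i, a), (j, b) in combinations(enumerate(samples), 2):
        prop[i, j] = prop[j, i] = _correlate(proportions[a], proportions[b], correlation)
        bulk[i, j] = bulk[j, i] = _correlate(bulks[a], bulks[b], correlation)
        jac[i, j] = jac[j, i] = jaccard(repertoires[a], repertoires[b])
        label = "within_patient" if patients[a] == patients[b] else "cross_patient"
        labels[i, j] = labels[j, i] = label

    def frame(arr: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(arr, index=samples, columns=samples)

    return ConcordanceReport(
        samples=samples,
        proportion_corr=frame(prop),
        pseudobulk_corr=frame(bulk),
        repertoire_jaccard=frame(jac),
        pair_labels=frame(labels),
        metadata={
            "correlation": correlation,
            "pseudobulk": "sum -> CPM -> log1p",
            "pseudocount": 1.0,
        },
    )
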