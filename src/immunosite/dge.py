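"""Two-group differential expression: Wilcoxon rank-sum on CPM values,
Benjamini-Hochberg adjustment, strict-inequality significance filter.

The p-value uses exhaustive enumeration of rank assignments when both groups
have at most 8 cells (tie-safe), otherwise the tie-corrected normal
approximation with continuity correction. Fold changes are
log2((meanA + pc) / (meanB + pc)) on CPM-normalized values.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .errors import ValidationError
from .io_formats import ExpressionMatrix

__all__ = ["wilcoxon_dge", "deg_filter", "exact_ranksum_p", "bh_adjust"]

EXACT_MAX_GROUP = 8


def exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p by exhaustive enumeration of group assignments.

    Midranks make the enumeration valid under ties. The statistic is the
    rank sum of group A; the p-value is the fraction of assignments at least
    as extreme (in absolute deviation from the mean rank sum) as observed.
    """
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    observed = ranks[:n_a].sum()
    center = n_a * (n_a + n_b + 1) / 2.0
    deviation = abs(observed - center)
    total = 0
    extreme = 0
    for idx in combinations(range(n_a + n_b), n_a):
        total += 1
        if abs(ranks[list(idx)].sum() - center) >= deviation - 1e-12:
            extreme += 1
    return extreme / total


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg FDR adjustment; NaNs are passed through."""
    p = np.asarray(pvalues, dtype=float)
    adjusted = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    m = len(pv)
    if m == 0:
        return adjusted
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    adjusted[mask] = out
    return adjusted


def _cpm(matrix: ExpressionMatrix, columns: np.ndarray) -> np.ndarray:
    counts = np.asarray(matrix.counts[:, columns].todense(), dtype=float)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        totals = np.maximum(totals, 1.0)
    return counts / totals * 1e6


def wilcoxon_dge(
    matrix: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    pseudocount: float = 1.0,
    min_cells_detected: int = 3,
) -> pd.DataFrame:
    """Per-gene rank-sum test of group A versus group B.

    Genes detected in fewer than ``min_cells_detected`` cells of the two
    groups combined are left untested (NaN p); BH adjustment runs over all
    tested genes. Returns a DataFrame indexed by gene with columns
    log2fc, pvalue, padj, mean_a, mean_b, n_detected, significant.
    """
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValidationError(f"groups overlap: {sorted(overlap)[:5]}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs at least 2 cells")
    index = {bc: i for i, bc in enumerate(matrix.barcodes)}
    missing = [bc for bc in (*group_a, *group_b) if bc not in index]
    if missing:
        raise ValidationError(f"barcodes not in matrix: {missing[:5]}")
    cols_a = np.array([index[bc] for bc in group_a])
    cols_b = np.array([index[bc] for bc in group_b])

    cpm_a = _cpm(matrix, cols_a)
    cpm_b = _cpm(matrix, cols_b)
    raw = np.asarray(matrix.counts[:, np.concatenate([cols_a, cols_b])].todense())
    n_detected = (raw > 0).sum(axis=1)
    tested = n_detected >= min_cells_detected

    mean_a = cpm_a.mean(axis=1)
    mean_b = cpm_b.mean(axis=1)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))

    pvalues = np.full(matrix.n_genes, np.nan)
    exact = len(group_a) <= EXACT_MAX_GROUP and len(group_b) <= EXACT_MAX_GROUP
    if exact:
        for g in np.flatnonzero(tested):
            pvalues[g] = exact_ranksum_p(cpm_a[g], cpm_b[g])
    elif tested.any():
        rows = np.flatnonzero(tested)
        res = mannwhitneyu(cpm_a[rows], cpm_b[rows], axis=1, method="asymptotic")
        pvalues[rows] = res.pvalue

    padj = bh_adjust(pvalues)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvalues,
            "padj": padj,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "n_detected": n_detected,
        },
        index=pd.Index(matrix.genes, name="gene"),
    )
    table["significant"] = (np.abs(table["log2fc"]) > 0.5) & (table["padj"] < 0.05)
    return table


def deg_filter(
    table: pd.DataFrame,
    lfc_min: float = 0.5,
    padj_max: float = 0.05,
) -> dict[str, list[str]]:
    """Genes with |log2FC| strictly above ``lfc_min`` and adjusted p strictly
    below ``padj_max``, split into up- and down-regulated lists."""
    if table.empty:
        return {"up": [], "down": []}
    passing = table[(table["log2fc"].abs() > lfc_min) & (table["padj"] < padj_max)]
    return {
        "up": list(passing.index[passing["log2fc"] > 0]),
        "down": list(passing.index[passing["log2fc"] < 0]),
    }
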