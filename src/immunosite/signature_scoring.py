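"""Per-cell gene-set scoring.

Two rank-based statistics are provided:

* ``auc`` — recovery-curve AUC: genes of a cell are ranked by decreasing
  count and the score is the (normalized) area under the cumulative gene-set
  hit curve within the top ``max_rank`` positions. Depends only on the
  ranking, so it is invariant to any strictly monotone transform of
  expression.
* ``ssgsea`` — single-sample enrichment: rank-weighted difference between
  the in-set and out-of-set running ECDFs.

Zero-count genes participate in the ranking (below all detected genes)
rather than being dropped, so ``max_rank`` is stable across cells.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io_formats import ExpressionMatrix, GeneSet

__all__ = ["ScoringConfig", "ScoreTable", "rank_genes", "auc_score", "ssgsea_score", "score_matrix"]


@dataclass(frozen=True)
class ScoringConfig:
    """Knobs for both scoring methods.

    ``max_rank_fraction`` is the top fraction of the ranking the recovery
    curve integrates over (default 5% of the gene universe). ``tie_policy``
    'stable_index' keeps tied genes in original order for bitwise
    reproducibility; 'seeded_random' shuffles within tie groups.
    """

    max_rank_fraction: float = 0.05
    top_cell_percent: float = 5.0
    tie_policy: str = "stable_index"
    seed: int = 0
    ssgsea_alpha: float = 0.25
    min_geneset_coverage: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.max_rank_fraction <= 1:
            raise ConfigurationError("max_rank_fraction must be in (0, 1]")
        if not 0 < self.top_cell_percent < 100:
            raise ConfigurationError("top_cell_percent must be in (0, 100)")
        if self.tie_policy not in ("stable_index", "seeded_random"):
            raise ConfigurationError(f"unknown tie_policy {self.tie_policy!r}")

    def max_rank(self, n_genes: int) -> int:
        return max(1, math.ceil(self.max_rank_fraction * n_genes))


@dataclass
class ScoreTable:
    """cells x signatures score matrix plus per-signature metadata."""

    barcodes: list[str]
    signatures: list[str]
    scores: np.ndarray  # shape (n_cells, n_signatures); NaN = missing
    metadata: dict[str, dict] = field(default_factory=dict)
    method: str = "auc"

    def column(self, signature: str) -> np.ndarray:
        return self.scores[:, self.signatures.index(signature)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.barcodes, columns=self.signatures)

    def to_long_frame(self) -> pd.DataFrame:
        wide = self.to_frame()
        long = wide.reset_index(names="barcode").melt(
            id_vars="barcode", var_name="signature", value_name="score"
        )
        return long.dropna(subset=["score"]).reset_index(drop=True)


def rank_genes(values: np.ndarray, config: ScoringConfig = ScoringConfig()) -> np.ndarray:
    """Permutation of gene indices ordering genes by decreasing value.

    Ties resolved by ascending original index (stable) or by a seeded
    shuffle within each tie group.
    """
    values = np.asarray(values)
    if config.tie_policy == "stable_index":
        return np.argsort(-values, kind="stable")
    rng = np.random.default_rng(config.seed)
    jitter = rng.permutation(len(values))
    order = np.lexsort((jitter, -values))
    return order


def _hit_ranks(ranking: np.ndarray, gene_set: GeneSet, universe: Sequence[str]) -> np.ndarray:
    member = np.fromiter((universe[i] in gene_set.genes for i in ranking), dtype=bool, count=len(ranking))
    return np.flatnonzero(member) + 1  # 1-based ranks of set members


def auc_score(
    ranking: np.ndarray,
    gene_set: GeneSet,
    universe: Sequence[str],
    config: ScoringConfig = ScoringConfig(),
) -> float:
    """Normalized recovery-curve area for one cell's ranking.

    With y(x) = number of set members at rank <= x, raw area is
    sum_{x=1..max_rank} y(x); the score divides by the maximal area, reached
    when min(|G|, max_rank) members occupy the top ranks. Result in [0, 1].
    """
    effective = gene_set.genes & set(universe)
    if not effective:
        raise ValidationError(f"gene set {gene_set.name!r} disjoint from the universe")
    max_rank = config.max_rank(len(universe))
    ranks = _hit_ranks(ranking, gene_set, universe)
    in_window = ranks[ranks <= max_rank]
    raw = np.sum(max_rank - in_window + 1)
    n_hits = min(len(effective), max_rank)
    max_area = n_hits * (n_hits + 1) // 2 + n_hits * (max_rank - n_hits)
    return float(raw / max_area)


def ssgsea_score(
    values: np.ndarray,
    gene_set: GeneSet,
    universe: Sequence[str],
    config: ScoringConfig = ScoringConfig(),
) -> float:
    """Rank-weighted ECDF-difference enrichment for one cell.

    Genes are ranked by decreasing value; the rank statistic of the gene at
    position j (1-based from the top) is N - j + 1, weighted by
    ``|r|^alpha`` for in-set genes. The score sums the running difference of
    the weighted in-set ECDF and the unweighted out-of-set ECDF. Depends only
    on the ranking, hence monotone-transform invariant.
    """
    effective = gene_set.genes & set(universe)
    if not effective:
        raise ValidationError(f"gene set {gene_set.name!r} disjoint from the universe")
    n = len(universe)
    if len(effective) == n:
        raise ValidationError(f"gene set {gene_set.name!r} covers the whole universe")
    ranking = rank_genes(np.asarray(values), config)
    in_set = np.fromiter(
        (universe[i] in gene_set.genes for i in ranking), dtype=bool, count=n
    )
    rank_stat = np.arange(n, 0, -1, dtype=float)  # top position gets N
    weights = np.where(in_set, np.abs(rank_stat) ** config.ssgsea_alpha, 0.0)
    ecdf_in = np.cumsum(weights) / weights.sum()
    out = (~in_set).astype(float)
    ecdf_out = np.cumsum(out) / out.sum()
    return float(np.sum(ecdf_in - ecdf_out))


def score_matrix(
    matrix: ExpressionMatrix,
    gene_sets: Sequence[GeneSet],
    method: str = "auc",
    config: ScoringConfig = ScoringConfig(),
) -> ScoreTable:
    """Score every cell against every gene set; deterministic given config.

    Gene sets disjoint from the universe yield an all-missing column; sets
    with coverage below ``min_geneset_coverage`` are scored but flagged in
    the metadata.
    """
    if method not in ("auc", "ssgsea"):
        raise ConfigurationError(f"unknown scoring method {method!r}")
    universe = matrix.genes
    universe_set = set(universe)
    n_cells = matrix.n_cells
    scores = np.full((n_cells, len(gene_sets)), np.nan)
    metadata: dict[str, dict] = {}
    max_rank = config.max_rank(len(universe))

    scorable: list[tuple[int, GeneSet]] = []
    for j, gs in enumerate(gene_sets):
        found = gs.genes & universe_set
        coverage = len(found) / len(gs.genes)
        meta = {
            "genes_in_set": len(gs.genes),
            "genes_found": len(found),
            "coverage": coverage,
            "max_rank": max_rank,
            "method": method,
        }
        if not found:
            meta["warning"] = "gene set disjoint from matrix universe; column missing"
            warnings.warn(f"gene set {gs.name!r}: no genes found in matrix", stacklevel=2)
        else:
            if coverage < config.min_geneset_coverage:
                meta["warning"] = (
                    f"coverage {coverage:.2f} below min_geneset_coverage "
                    f"{config.min_geneset_coverage:.2f}"
                )
                warnings.warn(f"gene set {gs.name!r}: low coverage {coverage:.2f}", stacklevel=2)
            scorable.append((j, gs))
        metadata[gs.name] = meta

    dense = matrix.counts.tocsc()
    for i in range(n_cells):
        col = np.asarray(dense[:, i].todense()).ravel()
        if method == "auc":
            ranking = rank_genes(col, config)
            for j, gs in scorable:
                scores[i, j] = auc_score(ranking, gs, universe, config)
        else:
            for j, gs in scorable:
                scores[i, j] = ssgsea_score(col, gs, universe, config)

    return ScoreTable(
        barcodes=list(matrix.barcodes),
        signatures=[gs.name for gs in gene_sets],
        scores=scores,
        metadata=metadata,
        method=method,
    )
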