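"""Repertoire diversity and overlap statistics: D50, rarefaction, Jaccard."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .errors import ValidationError
from .repertoire import Repertoire

__all__ = ["RarefactionCurve", "d50", "rarefaction", "rarefaction_resampled", "jaccard"]


@dataclass
class RarefactionCurve:
    """Expected distinct-clone richness at each subsampling depth."""

    sample_id: str
    depths: list[int]
    expected_richness: list[float]


def d50(rep: Repertoire) -> tuple[int, float]:
    """Number of dominant clones covering half the pool, and that number as a
    percent of distinct clones.

    Clones are taken in descending count order (ties broken by clonotype key
    for determinism); k is the smallest number whose cumulative count reaches
    at least half the pool size.
    """
    if rep.pool_size == 0:
        raise ValidationError(f"repertoire {rep.sample_id!r} is empty")
    ordered = sorted(rep.clone_counts.items(), key=lambda kv: (-kv[1], kv[0].key))
    half = 0.5 * rep.pool_size
    cumulative = 0
    for k, (_, count) in enumerate(ordered, start=1):
        cumulative += count
        if cumulative >= half:
            return k, 100.0 * k / rep.n_clones
    raise AssertionError("unreachable: cumulative sum always reaches the pool size")


def _log_comb(n: np.ndarray | float, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefaction(rep: Repertoire, depths: Sequence[int]) -> RarefactionCurve:
    """Analytic rarefaction: hypergeometric expectation of richness.

    E[S_m] = sum_i (1 - C(N - n_i, m) / C(N, m)) with N the pool size and n_i
    the clone counts; computed in log space. Exact, no resampling.
    """
    n = np.array(sorted(rep.clone_counts.values()), dtype=float)
    total = rep.pool_size
    if total == 0:
        raise ValidationError(f"repertoire {rep.sample_id!r} is empty")
    expected: list[float] = []
    for m in depths:
        if not 1 <= m <= total:
            raise ValidationError(f"depth {m} outside [1, {total}]")
        remaining = total - n
        feasible = remaining >= m  # C(N - n_i, m) = 0 when m > N - n_i
        p_absent = np.zeros_like(n)
        if feasible.any():
            p_absent[feasible] = np.exp(
                _log_comb(remaining[feasible], m) - _log_comb(float(total), m)
            )
        expected.append(float(np.sum(1.0 - p_absent)))
    return RarefactionCurve(sample_id=rep.sample_id, depths=list(depths), expected_richness=expected)


def rarefaction_resampled(
    rep: Repertoire,
    depths: Sequence[int],
    n_draws: int = 1000,
    seed: int = 0,
) -> RarefactionCurve:
    """Monte-Carlo rarefaction (subsampling without replacement).

    Cross-check mode only; the analytic form is authoritative.
    """
    rng = np.random.default_rng(seed)
    counts = np.array(list(rep.clone_counts.values()), dtype=int)
    labels = np.repeat(np.arange(len(counts)), counts)
    total = rep.pool_size
    means: list[float] = []
    for m in depths:
        if not 1 <= m <= total:
            raise ValidationError(f"depth {m} outside [1, {total}]")
        richness = np.empty(n_draws)
        for i in range(n_draws):
            draw = rng.choice(labels, size=m, replace=False)
            richness[i] = len(np.unique(draw))
        means.append(float(richness.mean()))
    return RarefactionCurve(sample_id=rep.sample_id, depths=list(depths), expected_richness=means)


def jaccard(rep_a: Repertoire, rep_b: Repertoire) -> float:
    """Jaccard index of the two clone sets (presence/absence, not counts)."""
    a, b = rep_a.clone_set(), rep_b.clone_set()
    union = a | b
    if not union:
        warnings.warn("jaccard of two empty repertoires defined as 0.0", stacklevel=2)
        return 0.0
    return len(a & b) / len(union)
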