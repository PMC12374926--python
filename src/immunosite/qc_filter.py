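"""Cell-level quality-control gating of an :class:`ExpressionMatrix`.

A cell is kept iff, simultaneously:

* it expresses PTPRC (count > 0), when ``require_ptprc`` is set;
* total UMI count lies in ``[min_total_reads, max_total_reads]``;
* detected features lie in ``[min_features, max_features]``;
* mitochondrial fraction is at most ``max_mito_pct``.

Boundary values are kept: the exclusion rules are strict inequalities
("fewer than" / "greater than"), so a cell at exactly a threshold passes.
"Total reads" is interpreted as the cell's total UMI count in the matrix —
the only per-cell total available downstream of UMI counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .io_formats import ExpressionMatrix

__all__ = ["QcThresholds", "QcReport", "apply_qc", "THRESHOLD_CRITERIA"]

# Criterion labels for the five threshold rules; the PTPRC gate is reported
# separately under "ptprc".
THRESHOLD_CRITERIA = (
    "min_total_reads",
    "min_features",
    "max_total_reads",
    "max_features",
    "max_mito_pct",
)


@dataclass(frozen=True)
class QcThresholds:
    """QC gate parameters; defaults follow the strict-inequality reading."""

    min_total_reads: int = 500
    min_features: int = 300
    max_total_reads: int = 25000
    max_features: int = 6000
    max_mito_pct: float = 15.0
    require_ptprc: bool = True
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if not self.min_total_reads < self.max_total_reads:
            raise ConfigurationError("min_total_reads must be < max_total_reads")
        if not self.min_features < self.max_features:
            raise ConfigurationError("min_features must be < max_features")
        if not 0 <= self.max_mito_pct <= 100:
            raise ConfigurationError("max_mito_pct must be in [0, 100]")


@dataclass
class QcReport:
    """Bookkeeping for one QC pass.

    ``excluded_by`` maps criterion -> number of cells violating it; a cell
    failing several criteria counts under each.
    """

    sample_id: str
    cells_in: int
    cells_out: int
    excluded_by: dict[str, int] = field(default_factory=dict)
    kept_barcodes: list[str] = field(default_factory=list)
    thresholds: dict[str, object] = field(default_factory=dict)
    boundary_policy: str = "closed interval: boundary values are kept"

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "cells_in": self.cells_in,
            "cells_out": self.cells_out,
            "excluded_by": dict(self.excluded_by),
            "kept_barcodes": list(self.kept_barcodes),
            "thresholds": dict(self.thresholds),
            "boundary_policy": self.boundary_policy,
        }


def apply_qc(
    matrix: ExpressionMatrix,
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[ExpressionMatrix, QcReport]:
    """Apply the inclusion gate and return (filtered matrix, report)."""
    totals = matrix.cell_totals()
    n_features = matrix.cell_n_features()

    mito_rows = [i for i, g in enumerate(matrix.genes) if g.startswith(thresholds.mito_prefix)]
    if mito_rows:
        mito_totals = np.asarray(matrix.counts[mito_rows, :].sum(axis=0)).ravel()
    else:
        mito_totals = np.zeros(matrix.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_totals / np.maximum(totals, 1), 0.0)

    violations: dict[str, np.ndarray] = {
        "min_total_reads": totals < thresholds.min_total_reads,
        "min_features": n_features < thresholds.min_features,
        "max_total_reads": totals > thresholds.max_total_reads,
        "max_features": n_features > thresholds.max_features,
        "max_mito_pct": mito_frac > thresholds.max_mito_pct / 100.0,
    }

    if thresholds.require_ptprc:
        try:
            ptprc_row = matrix.genes.index("PTPRC")
        except ValueError:
            raise ConfigurationError(
                f"sample {matrix.sample_id!r}: require_ptprc is set but PTPRC "
                "is absent from the gene list"
            ) from None
        ptprc = np.asarray(matrix.counts[ptprc_row, :].todense()).ravel()
        violations["ptprc"] = ptprc <= 0

    excluded = np.zeros(matrix.n_cells, dtype=bool)
    excluded_by: dict[str, int] = {}
    for criterion, mask in violations.items():
        count = int(mask.sum())
        if count:
            excluded_by[criterion] = count
        excluded |= mask

    keep = np.flatnonzero(~excluded)
    filtered = matrix.subset_cells(keep)
    report = QcReport(
        sample_id=matrix.sample_id,
        cells_in=matrix.n_cells,
        cells_out=len(keep),
        excluded_by=excluded_by,
        kept_barcodes=list(filtered.barcodes),
        thresholds={
            "min_total_reads": thresholds.min_total_reads,
            "min_features": thresholds.min_features,
            "max_total_reads": thresholds.max_total_reads,
            "max_features": thresholds.max_features,
            "max_mito_pct": thresholds.max_mito_pct,
            "require_ptprc": thresholds.require_ptprc,
            "mito_prefix": thresholds.mito_prefix,
        },
    )
    return filtered, report
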