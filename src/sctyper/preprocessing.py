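"""Quality control and normalization of raw UMI counts.

QC removes low-complexity droplets (too few UMIs or too few detected genes);
normalization rescales each cell to a fixed library size and applies log1p, the
standard counts-per-10k + ln(1+x) representation used for training and
prediction throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_model import CountMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["NormalizedMatrix", "QCReport", "qc_filter", "normalize_log1p"]

DEFAULT_MIN_UMI = 1000
DEFAULT_MIN_GENES = 600
DEFAULT_TARGET_SUM = 10_000.0


@dataclass
class NormalizedMatrix:
    """log1p(counts-per-target_sum) expression, cells x genes."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    target_sum: float = DEFAULT_TARGET_SUM
    zero_cells: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValidationError("normalized matrix shape does not match identifier lists")
        if self.values.size and self.values.min() < 0:
            raise ValidationError("normalized matrix contains negative entries")
        if self.target_sum <= 0:
            raise ValidationError("target_sum must be positive")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class QCReport:
    """Removed cells with the reason each failed."""

    removed: list[tuple[str, str]] = field(default_factory=list)
    min_umi: int = DEFAULT_MIN_UMI
    min_genes: int = DEFAULT_MIN_GENES

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def qc_filter(
    counts: CountMatrix,
    min_umi: int = DEFAULT_MIN_UMI,
    min_genes: int = DEFAULT_MIN_GENES,
) -> tuple[CountMatrix, QCReport]:
    """Drop cells with fewer than ``min_umi`` total counts or fewer than
    ``min_genes`` detected (nonzero) genes; thresholds are exclusive, so a cell
    exactly at a threshold is retained.
    """
    if min_umi <= 0 or min_genes <= 0:
        raise ValidationError("QC thresholds must be positive")
    totals = counts.values.sum(axis=1)
    detected = (counts.values > 0).sum(axis=1)
    keep = (totals >= min_umi) & (detected >= min_genes)
    report = QCReport(min_umi=min_umi, min_genes=min_genes)
    for i in np.flatnonzero(~keep):
        reasons = []
        if totals[i] < min_umi:
            reasons.append(f"umi<{min_umi}")
        if detected[i] < min_genes:
            reasons.append(f"genes<{min_genes}")
        report.removed.append((counts.cell_ids[i], ",".join(reasons)))
    if not keep.any():
        logger.warning("QC removed all %d cells", counts.n_cells)
    kept_idx = np.flatnonzero(keep)
    filtered = CountMatrix(
        counts.values[kept_idx],
        [counts.cell_ids[i] for i in kept_idx],
        counts.gene_ids,
    )
    return filtered, report


def normalize_log1p(counts: CountMatrix, target_sum: float = DEFAULT_TARGET_SUM) -> NormalizedMatrix:
    """Per-cell library-size normalization to ``target_sum`` followed by ln(1+x).

    Cells with zero total counts are left all-zero and recorded in
    ``zero_cells``; the transform is invariant to uniform scaling of a cell's
    counts because counts are divided by the cell total first.
    """
    if target_sum <= 0:
        raise ValidationError("target_sum must be positive")
    X = counts.values.astype(np.float64)
    totals = X.sum(axis=1)
    zero = totals == 0
    scale = np.where(zero, 1.0, target_sum / np.where(zero, 1.0, totals))
    out = np.log1p(X * scale[:, None])
    out[zero] = 0.0
    zero_cells = [counts.cell_ids[i] for i in np.flatnonzero(zero)]
    if zero_cells:
        logger.warning("%d cells have zero total counts; left all-zero", len(zero_cells))
    return NormalizedMatrix(out, list(counts.cell_ids), list(counts.gene_ids),
                            target_sum=target_sum, zero_cells=zero_cells)
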