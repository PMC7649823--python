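"""Expression transform and gene filters applied before clustering.

Raw TPM values are log-transformed (``log2(x + 1)``) and three filters
remove uninformative genes: genes never expressed, *rare* genes expressed
in fewer than ``v``% of cells, and *ubiquitous* genes expressed in at
least ``(100 - v)``% of cells.  The default ``v = 10``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import SCALE_LOG_TPM, SCALE_TPM, ExpressionMatrix

logger = logging.getLogger("diffge")


@dataclass
class FilterReport:
    """Accounting of the gene filters; totals always reconcile."""

    n_input_genes: int
    n_zero_dropped: int
    n_rare_dropped: int
    n_ubiquitous_dropped: int
    v: float
    kept_genes: list[str]

    def __post_init__(self) -> None:
        total = self.n_zero_dropped + self.n_rare_dropped + self.n_ubiquitous_dropped + len(self.kept_genes)
        if total != self.n_input_genes:
            raise ValueError(f"filter accounting mismatch: {total} != {self.n_input_genes}")


def log_transform(matrix: ExpressionMatrix, base: float = 2.0, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Return ``log_base(x + pseudocount)`` with the scale tag flipped.

    Raises if the matrix is already log-scaled (double-transform guard).
    """
    if matrix.scale == SCALE_LOG_TPM:
        raise ValueError("matrix is already log-scaled; refusing to transform twice")
    if matrix.scale != SCALE_TPM:
        raise ValueError(f"unexpected scale {matrix.scale!r}")
    values = np.log(matrix.values + pseudocount) / np.log(base)
    return ExpressionMatrix(list(matrix.genes), list(matrix.cells), values, SCALE_LOG_TPM)


def filter_genes(
    matrix: ExpressionMatrix,
    v: float = 10.0,
    expressed_threshold: float = 0.0,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop never-expressed, rare, and ubiquitous genes.

    A gene is *expressed* in a cell iff its value is strictly greater than
    ``expressed_threshold``.  With expressed fraction ``f`` over cells, a
    gene is kept iff ``f > 0`` and ``f >= v/100`` (rare rule is a strict
    ``<``) and ``f < (100 - v)/100`` (ubiquitous rule is "at least").
    Fractions are exact, never rounded percentages.  Gene order is
    preserved.
    """
    if not 0 < v < 50:
        raise ValueError("v must be in (0, 50)")
    if expressed_threshold < 0:
        raise ValueError("expressed_threshold must be >= 0")
    expressed = matrix.values > expressed_threshold
    frac = expressed.sum(axis=1) / matrix.n_cells
    is_zero = frac == 0
    is_rare = ~is_zero & (frac < v / 100.0)
    is_ubiq = ~is_zero & ~is_rare & (frac >= (100.0 - v) / 100.0)
    keep = ~is_zero & ~is_rare & ~is_ubiq
    kept_genes = [g for g, k in zip(matrix.genes, keep) if k]
    report = FilterReport(
        n_input_genes=matrix.n_genes,
        n_zero_dropped=int(is_zero.sum()),
        n_rare_dropped=int(is_rare.sum()),
        n_ubiquitous_dropped=int(is_ubiq.sum()),
        v=v,
        kept_genes=kept_genes,
    )
    if not kept_genes:
        raise ValueError(
            "all genes removed by the expression filters; lower v or the expressed threshold"
        )
    logger.info(
        "filter_genes: %d -> %d genes (%d zero, %d rare, %d ubiquitous dropped)",
        matrix.n_genes, len(kept_genes),
        report.n_zero_dropped, report.n_rare_dropped, report.n_ubiquitous_dropped,
    )
    return matrix.subset_genes(kept_genes), report


def filter_report_frame(report: FilterReport):
    import pandas as pd

    return pd.DataFrame(
        [
            ("n_input_genes", report.n_input_genes),
            ("n_zero_dropped", report.n_zero_dropped),
            ("n_rare_dropped", report.n_rare_dropped),
            ("n_ubiquitous_dropped", report.n_ubiquitous_dropped),
            ("n_kept", len(report.kept_genes)),
            ("v", report.v),
        ],
        columns=["field", "value"],
    )
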