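"""QC filtering and normalization.

Two normalization dialects are built in, matching the two spatial
platforms the analysis covers: sequencing-based spots are scaled to a
per-cell total of 10,000 and log2-transformed with pseudocount 1
(``visium``), imaging-based cells are scaled to 1,000 and natural-log
transformed with pseudocount 1 (``xenium``).  QC removes cells first
(minimum detected genes, then total-count window), then genes detected
in too few of the surviving cells, and reports the count removed by
each rule in that order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .datatypes import CountMatrix


@dataclass
class QCThresholds:
    """Cell- and gene-level QC cutoffs.

    Defaults are the sequencing-based spatial filter: at least 100
    detected genes per cell, total counts in [2000, 35000], and every
    kept gene detected in at least 3 surviving cells.
    """

    min_genes_per_cell: int = 100
    min_cells_per_gene: int = 3
    min_counts_per_cell: int = 2000
    max_counts_per_cell: int = 35000

    def __post_init__(self) -> None:
        if min(self.min_genes_per_cell, self.min_cells_per_gene,
               self.min_counts_per_cell) < 0:
            raise ValueError("QC thresholds must be nonnegative")
        if self.min_counts_per_cell > self.max_counts_per_cell:
            raise ValueError("min_counts_per_cell exceeds max_counts_per_cell")


@dataclass
class QCReport:
    """Per-rule removal counts, in the order the rules were applied."""

    n_cells_in: int
    n_genes_in: int
    removed_min_genes: int
    removed_min_counts: int
    removed_max_counts: int
    removed_genes_min_cells: int
    n_cells_out: int
    n_genes_out: int
    thresholds: dict = field(default_factory=dict)

    @property
    def total_cells_removed(self) -> int:
        return self.removed_min_genes + self.removed_min_counts + self.removed_max_counts

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def write_json(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


class AllCellsRemovedError(ValueError):
    """Every cell failed QC; carries the report for diagnostics."""

    def __init__(self, report: QCReport):
        super().__init__(
            f"QC removed all {report.n_cells_in} cells "
            f"(min_genes: {report.removed_min_genes}, "
            f"min_counts: {report.removed_min_counts}, "
            f"max_counts: {report.removed_max_counts})"
        )
        self.report = report


def qc_filter(m: CountMatrix, t: QCThresholds) -> tuple[CountMatrix, QCReport]:
    """Filter poor-quality cells, then sparsely detected genes.

    Cells are removed by the first rule they fail, in the order
    min_genes -> min_counts -> max_counts, so the per-rule counts in
    the report sum to the total number of removed cells.  Genes are
    then removed if detected in fewer than ``min_cells_per_gene`` of
    the surviving cells.
    """
    m.require_layer("raw", "qc_filter")
    genes_per_cell = m.genes_per_cell()
    counts_per_cell = m.counts_per_cell()

    fail_genes = genes_per_cell < t.min_genes_per_cell
    fail_min = ~fail_genes & (counts_per_cell < t.min_counts_per_cell)
    fail_max = ~fail_genes & ~fail_min & (counts_per_cell > t.max_counts_per_cell)
    keep_cells = ~(fail_genes | fail_min | fail_max)

    kept = m.subset(cell_mask=keep_cells)
    if kept.n_cells == 0:
        report = QCReport(
            n_cells_in=m.n_cells,
            n_genes_in=m.n_genes,
            removed_min_genes=int(fail_genes.sum()),
            removed_min_counts=int(fail_min.sum()),
            removed_max_counts=int(fail_max.sum()),
            removed_genes_min_cells=0,
            n_cells_out=0,
            n_genes_out=m.n_genes,
            thresholds=t.__dict__.copy(),
        )
        raise AllCellsRemovedError(report)

    keep_genes = kept.cells_per_gene() >= t.min_cells_per_gene
    out = kept.subset(gene_mask=keep_genes)
    report = QCReport(
        n_cells_in=m.n_cells,
        n_genes_in=m.n_genes,
        removed_min_genes=int(fail_genes.sum()),
        removed_min_counts=int(fail_min.sum()),
        removed_max_counts=int(fail_max.sum()),
        removed_genes_min_cells=int((~keep_genes).sum()),
        n_cells_out=out.n_cells,
        n_genes_out=out.n_genes,
        thresholds=t.__dict__.copy(),
    )
    return out, report


@dataclass
class NormalizationDialect:
    """Per-cell scaling target plus log transform parameters.

    The transform is ``log_base(count / cell_total * target_sum +
    pseudocount)`` — the pseudocount is added after scaling.
    """

    target_sum: float
    log_base: str  # "2" or "e"
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.target_sum <= 0:
            raise ValueError("target_sum must be positive")
        if self.log_base not in ("2", "e"):
            raise ValueError("log_base must be '2' or 'e'")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


#: sequencing-based spatial dialect: total 10,000, log2, pseudocount 1
VISIUM_DIALECT = NormalizationDialect(target_sum=10000.0, log_base="2")
#: imaging-based spatial dialect: total 1,000, natural log, pseudocount 1
XENIUM_DIALECT = NormalizationDialect(target_sum=1000.0, log_base="e")

DIALECTS = {"visium": VISIUM_DIALECT, "xenium": XENIUM_DIALECT}


def normalize(m: CountMatrix, d: NormalizationDialect) -> CountMatrix:
    """Library-size normalize and log-transform a raw matrix.

    Each cell is scaled so its counts sum to ``target_sum``, then the
    pseudocount is added and the log taken.  Cells with zero total are
    an error (their scaling is undefined) and are named in the message.
    """
    m.require_layer("raw", "normalize")
    totals = m.counts_per_cell()
    zero = totals == 0
    if zero.any():
        bad = [m.cell_ids[i] for i in np.flatnonzero(zero)[:5]]
        raise ValueError(f"cannot normalize cells with zero total counts: {bad}")

    dense = m.dense()
    scaled = dense / totals[:, None] * d.target_sum + d.pseudocount
    values = np.log2(scaled) if d.log_base == "2" else np.log(scaled)
    return CountMatrix(list(m.cell_ids), list(m.gene_ids), values, layer="lognorm")
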