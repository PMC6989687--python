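"""Per-cell quality control and spike-in-excluded TPM rescaling.

Cells are discarded when they have fewer than 500,000 mapped reads (strict
``<``) or a mitochondrial expression fraction above 30% (strict ``>``). The
mitochondrial fraction is computed from expression units by default: the sum
of mitochondrial-gene expression over the sum of endogenous + mitochondrial
expression, with spike-ins excluded from both numerator and denominator. A
per-cell read-based fraction can be supplied instead.

After filtering, TPM values are rescaled to exclude ERCC spike-ins: spike-in
columns are dropped and each cell's remaining values are scaled so they sum
to 1e6 again.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import ExpressionMatrix, ReadCountTable

logger = logging.getLogger("ehtmark")

DEFAULT_MIN_READS = 500_000
DEFAULT_MAX_MITO = 0.30


@dataclass
class CellQCRecord:
    cell_id: str
    mapped_reads: int
    mito_fraction: float
    pass_qc: bool = True
    fail_reasons: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not 0.0 <= self.mito_fraction <= 1.0:
            raise ValueError(f"mito_fraction out of [0, 1]: {self.mito_fraction}")
        self.pass_qc = not self.fail_reasons


def compute_qc(
    matrix: ExpressionMatrix,
    reads: ReadCountTable,
    min_reads: int = DEFAULT_MIN_READS,
    max_mito: float = DEFAULT_MAX_MITO,
    mito_read_fraction: Mapping[str, float] | None = None,
) -> list[CellQCRecord]:
    """QC every cell of the matrix against depth and mitochondrial thresholds.

    Thresholds follow the strict reading of the filtering rule: a cell fails
    ``low_depth`` iff mapped_reads < min_reads and ``high_mito`` iff
    mito_fraction > max_mito (a cell exactly at either boundary passes).
    When ``mito_read_fraction`` is given it overrides the expression-based
    fraction per cell.
    """
    missing = [c for c in matrix.cell_ids if c not in reads]
    if missing:
        raise KeyError(f"cells missing from read-count table: {missing[:5]}")

    mito_mask = matrix.class_mask("mitochondrial")
    bio_mask = mito_mask | matrix.class_mask("endogenous")
    mito_sum = matrix.values[:, mito_mask].sum(axis=1)
    bio_sum = matrix.values[:, bio_mask].sum(axis=1)

    records: list[CellQCRecord] = []
    for i, cell in enumerate(matrix.cell_ids):
        reasons: set[str] = set()
        n_reads = reads[cell]
        if n_reads < min_reads:
            reasons.add("low_depth")
        if mito_read_fraction is not None and cell in mito_read_fraction:
            frac = float(mito_read_fraction[cell])
        elif bio_sum[i] == 0:
            logger.warning(
                "cell %s has zero biological expression; mito fraction undefined", cell
            )
            frac = 1.0
            reasons.add("high_mito")
        else:
            frac = float(mito_sum[i] / bio_sum[i])
        if frac > max_mito:
            reasons.add("high_mito")
        records.append(
            CellQCRecord(
                cell_id=cell,
                mapped_reads=n_reads,
                mito_fraction=frac,
                fail_reasons=reasons,
            )
        )
    n_fail = sum(not r.pass_qc for r in records)
    logger.info("QC: %d/%d cells fail", n_fail, len(records))
    return records


def filter_cells(
    matrix: ExpressionMatrix, qc: Sequence[CellQCRecord]
) -> ExpressionMatrix:
    """Sub-matrix of passing cells, cell order preserved."""
    by_cell = {r.cell_id: r for r in qc}
    uncovered = [c for c in matrix.cell_ids if c not in by_cell]
    if uncovered:
        raise KeyError(f"QC records missing for cells: {uncovered[:5]}")
    keep = [c for c in matrix.cell_ids if by_cell[c].pass_qc]
    return matrix.subset_cells(keep)


def rescale_tpm_excluding_spikeins(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Drop spike-in genes and rescale each cell's remaining TPM to sum to 1e6.

    Mitochondrial genes are retained — only ERCC spike-ins are removed from
    the transcriptome before renormalisation. Ratios between any two retained
    genes within a cell are preserved exactly.
    """
    keep = ~matrix.class_mask("spike_in")
    sub = matrix.subset_genes(keep)
    totals = sub.values.sum(axis=1)
    dead = np.flatnonzero(totals == 0)
    if dead.size:
        cells = [sub.cell_ids[i] for i in dead[:5]]
        raise ValueError(f"cells with all-zero non-spike-in expression: {cells}")
    return sub.with_values(sub.values * (1e6 / totals)[:, None])


def qc_report(qc: Sequence[CellQCRecord]) -> pd.DataFrame:
    """QC results as a writable table (fail reasons comma-joined, sorted)."""
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in qc],
            "mapped_reads": [r.mapped_reads for r in qc],
            "mito_fraction": [r.mito_fraction for r in qc],
            "pass": [int(r.pass_qc) for r in qc],
            "fail_reasons": [",".join(sorted(r.fail_reasons)) for r in qc],
        }
    )
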