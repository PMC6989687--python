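"""Core data model and I/O.

The central container is :class:`ExpressionMatrix`: a dense cells x genes
matrix of non-negative expression values (TPM units downstream of the
rescaling step) with unique cell and gene identifiers and a per-gene class
flag distinguishing endogenous genes, ERCC spike-ins and mitochondrial
genes. Readers and writers cover tab-separated tables (genes in rows, the
common Smart-seq2 layout) and MatrixMarket sparse files accompanied by
plain-text row/column name files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("ehtmark")

GENE_CLASSES = ("endogenous", "spike_in", "mitochondrial")

DEFAULT_SPIKE_IN_PREFIX = "ERCC-"
DEFAULT_MITO_PREFIXES = ("mt-",)

#: The ten-gene panel used to separate endothelial from haematopoietic cells.
DEFAULT_PANEL_GENES = (
    "Cdh5", "Kdr", "Pecam1", "Pcdh12", "Sox7",
    "Gfi1", "Gfi1b", "Myb", "Runx1", "Spi1",
)
DEFAULT_ANNOTATION_GENE = "Runx1"


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dupes = sorted({i for i in ids if i in seen or seen.add(i)})
        raise ValueError(f"duplicate {what} identifiers: {dupes[:5]}")


@dataclass
class ExpressionMatrix:
    """Cells x genes non-negative expression matrix with gene class flags."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    gene_class: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x genes array")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        if self.gene_class is None:
            self.gene_class = np.full(self.n_genes, "endogenous", dtype=object)
        else:
            self.gene_class = np.asarray(self.gene_class, dtype=object)
            if self.gene_class.shape != (self.n_genes,):
                raise ValueError("gene_class must have one entry per gene")
            bad = set(self.gene_class) - set(GENE_CLASSES)
            if bad:
                raise ValueError(f"unknown gene classes: {sorted(bad)}")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None

    def class_mask(self, gene_class: str) -> np.ndarray:
        if gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {gene_class!r}")
        return self.gene_class == gene_class

    def subset_cells(self, keep: Iterable[str]) -> "ExpressionMatrix":
        """Sub-matrix of the given cells, matrix order preserved."""
        keep = set(keep)
        missing = keep - set(self.cell_ids)
        if missing:
            raise KeyError(f"cells not in matrix: {sorted(missing)[:5]}")
        idx = [i for i, c in enumerate(self.cell_ids) if c in keep]
        return ExpressionMatrix(
            values=self.values[idx, :],
            cell_ids=[self.cell_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            gene_class=self.gene_class.copy(),
        )

    def subset_genes(self, keep_mask: np.ndarray) -> "ExpressionMatrix":
        keep_mask = np.asarray(keep_mask, dtype=bool)
        return ExpressionMatrix(
            values=self.values[:, keep_mask],
            cell_ids=list(self.cell_ids),
            gene_ids=[g for g, k in zip(self.gene_ids, keep_mask) if k],
            gene_class=self.gene_class[keep_mask].copy(),
        )

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        return replace(self, values=values, gene_class=self.gene_class.copy())

    def to_frame(self) -> pd.DataFrame:
        """Genes-in-rows DataFrame (genes index, cells columns)."""
        return pd.DataFrame(self.values.T, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class ReadCountTable:
    """Per-cell mapped-read counts."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        for cell, n in self.counts.items():
            if n < 0:
                raise ValueError(f"mapped_reads for {cell!r} is negative")
        self.counts = {str(c): int(n) for c, n in self.counts.items()}

    def __getitem__(self, cell_id: str) -> int:
        return self.counts[cell_id]

    def __contains__(self, cell_id: str) -> bool:
        return cell_id in self.counts

    def restrict(self, cells: Iterable[str]) -> "ReadCountTable":
        cells = set(cells)
        return ReadCountTable({c: n for c, n in self.counts.items() if c in cells})


@dataclass
class MarkerPanel:
    """Ordered marker-gene panel plus the cluster-annotation anchor gene."""

    gene_symbols: list[str] = field(default_factory=lambda: list(DEFAULT_PANEL_GENES))
    annotation_gene: str = DEFAULT_ANNOTATION_GENE

    def __post_init__(self) -> None:
        if not self.gene_symbols:
            raise ValueError("marker panel must be non-empty")
        _check_unique(self.gene_symbols, "panel gene")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(
    path: str | Path,
    format: str = "tsv",
    *,
    genes_in_rows: bool = True,
) -> ExpressionMatrix:
    """Read an expression matrix from a TSV table or a MatrixMarket triplet.

    TSV files carry genes in rows and cells in columns with a header row of
    cell identifiers (set ``genes_in_rows=False`` for the transposed layout).
    MTX files hold genes x cells values and must be accompanied by
    ``<stem>.genes.txt`` and ``<stem>.cells.txt`` name files, one identifier
    per line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise ValueError(f"duplicate identifiers in {path}")
        if df.isna().any().any():
            raise ValueError(f"ragged rows or missing values in {path}")
        if not genes_in_rows:
            df = df.T
        values = df.to_numpy(dtype=float).T  # -> cells x genes
        mat = ExpressionMatrix(
            values=values,
            cell_ids=list(df.columns.astype(str)),
            gene_ids=list(df.index.astype(str)),
        )
    elif format == "mtx":
        stem = path.with_suffix("") if path.suffix == ".mtx" else path
        gene_file = stem.with_suffix(".genes.txt")
        cell_file = stem.with_suffix(".cells.txt")
        for f in (gene_file, cell_file):
            if not f.exists():
                raise FileNotFoundError(f)
        sparse = scipy.io.mmread(path)
        values = np.asarray(sparse.todense(), dtype=float)  # genes x cells
        gene_ids = gene_file.read_text().split()
        cell_ids = cell_file.read_text().split()
        if values.shape != (len(gene_ids), len(cell_ids)):
            raise ValueError(
                f"{path}: matrix shape {values.shape} does not match name files"
            )
        mat = ExpressionMatrix(values=values.T, cell_ids=cell_ids, gene_ids=gene_ids)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'mtx')")
    logger.info("read %d cells x %d genes from %s", mat.n_cells, mat.n_genes, path)
    return mat


def write_expression_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    format: str = "tsv",
) -> None:
    """Write a matrix in a layout :func:`read_expression_matrix` round-trips."""
    path = Path(path)
    if format == "tsv":
        matrix.to_frame().to_csv(path, sep="\t", float_format="%.10g")
    elif format == "mtx":
        stem = path.with_suffix("") if path.suffix == ".mtx" else path
        scipy.io.mmwrite(
            str(path), scipy.sparse.coo_matrix(matrix.values.T), precision=12
        )
        stem.with_suffix(".genes.txt").write_text("\n".join(matrix.gene_ids) + "\n")
        stem.with_suffix(".cells.txt").write_text("\n".join(matrix.cell_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_read_counts(path: str | Path) -> ReadCountTable:
    """Read a two-column (cell_id, mapped_reads) tab-separated table."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected exactly two columns")
    cells = df.iloc[:, 0].astype(str)
    if cells.duplicated().any():
        raise ValueError(f"{path}: duplicate cell identifiers")
    return ReadCountTable(dict(zip(cells, df.iloc[:, 1].astype(int))))


def write_read_counts(table: ReadCountTable, path: str | Path) -> None:
    pd.DataFrame(
        {"cell_id": list(table.counts), "mapped_reads": list(table.counts.values())}
    ).to_csv(path, sep="\t", index=False)


def read_marker_panel(
    path: str | Path, annotation_gene: str = DEFAULT_ANNOTATION_GENE
) -> MarkerPanel:
    """Read a panel file: one gene symbol per line, '#' comments allowed."""
    symbols = [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return MarkerPanel(gene_symbols=symbols, annotation_gene=annotation_gene)


# ---------------------------------------------------------------------------
# Gene-class annotation
# ---------------------------------------------------------------------------

def annotate_gene_classes(
    matrix: ExpressionMatrix,
    spike_in_prefix: str = DEFAULT_SPIKE_IN_PREFIX,
    mito_prefixes: Sequence[str] = DEFAULT_MITO_PREFIXES,
) -> ExpressionMatrix:
    """Classify every gene as spike-in, mitochondrial or endogenous by prefix.

    The three classes partition the gene set; a gene whose identifier matches
    both the spike-in prefix and a mitochondrial prefix is an error.
    """
    if not spike_in_prefix or not mito_prefixes or not all(mito_prefixes):
        raise ValueError("prefixes must be non-empty")
    classes = np.full(matrix.n_genes, "endogenous", dtype=object)
    for i, gene in enumerate(matrix.gene_ids):
        is_spike = gene.startswith(spike_in_prefix)
        is_mito = any(gene.startswith(p) for p in mito_prefixes)
        if is_spike and is_mito:
            raise ValueError(f"gene {gene!r} matches both prefix families")
        if is_spike:
            classes[i] = "spike_in"
        elif is_mito:
            classes[i] = "mitochondrial"
    return replace(matrix, gene_class=classes)
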