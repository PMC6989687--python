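"""Synthetic single-cell expression data with planted ground truth.

The generator emulates the structure of a Smart-seq-style AGM endothelium
experiment: ~78 analysable cells of which a small minority (default 10)
co-express haematopoietic genes, a ten-gene marker panel with bimodal
blood-gene expression, a set of planted marker genes up-regulated in the
minority cluster (with a "Cd44"-role gene planted as the strongest), ERCC
spike-ins at a small read fraction, mitochondrial genes, and deliberately
injected QC failures (cells with too few mapped reads; cells with a high
mitochondrial fraction). Every downstream stage of the pipeline therefore
has an exact planted truth to be checked against.

Expression noise is log-normal: per gene g a baseline log-mean mu_g is
drawn, each cell's raw abundance is exp(Normal(mu_g + shift, sigma)), and
values are then scaled so endogenous + spike-in TPM sums to 1e6 per cell.
A count layer is deliberately omitted — the pipeline consumes TPM and all
tests operate on log-transformed TPM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .io_model import (
    DEFAULT_ANNOTATION_GENE,
    DEFAULT_PANEL_GENES,
    ExpressionMatrix,
    ReadCountTable,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_dataset",
    "generate_category_map",
    "generate_metabolite_network",
]

#: Panel genes expressed across the endothelium (retained by transitioning cells).
ENDOTHELIAL_PANEL_GENES = ("Cdh5", "Kdr", "Pecam1", "Pcdh12", "Sox7")
#: Panel genes switched on in the haematopoietic minority (bimodal).
BLOOD_PANEL_GENES = ("Gfi1", "Gfi1b", "Myb", "Runx1", "Spi1")

CD44_ROLE_GENE = "Cd44"

MIN_READS_THRESHOLD = 500_000


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the experiment the pipeline targets: 78 cells passing QC
    with a 10-cell haematopoietic minority, a 2000-gene endogenous
    transcriptome containing 25 planted markers with a natural-log effect of
    2.0, 92 ERCC spike-in species at a 2% read fraction, 13 mitochondrial
    genes, and ten injected QC failures (five low-depth, five high-mito).
    """

    n_cells_pass: int = 78
    n_haem: int = 10
    n_genes: int = 2000
    n_markers_planted: int = 25
    marker_effect: float = 2.0
    base_log_mean_sd: tuple[float, float] = (2.0, 1.5)
    within_cell_sd: float = 0.5
    panel_blood_shift: float = 3.0
    cd44_extra_effect: float = 1.0
    marker_baseline_floor: float = 1.0
    spike_in_fraction: float = 0.02
    n_spike_ins: int = 92
    n_mito: int = 13
    n_fail_depth: int = 5
    n_fail_mito: int = 5
    depth_mean: int = 1_500_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_haem >= self.n_cells_pass:
            raise ValueError("n_haem must be smaller than n_cells_pass")
        if not 0 < self.spike_in_fraction < 1:
            raise ValueError("spike_in_fraction must lie in (0, 1)")
        counts = (
            self.n_cells_pass, self.n_haem, self.n_genes, self.n_markers_planted,
            self.n_spike_ins, self.n_mito, self.n_fail_depth, self.n_fail_mito,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be non-negative")
        n_special = len(DEFAULT_PANEL_GENES) + self.n_markers_planted
        if self.n_genes < n_special:
            raise ValueError(
                f"n_genes={self.n_genes} too small for panel + planted markers"
            )
        if self.within_cell_sd <= 0:
            raise ValueError("within_cell_sd must be positive")


@dataclass
class GroundTruth:
    """Planted truth accompanying a synthetic dataset."""

    cell_label: dict[str, str]  # endothelial | haematopoietic | qc_fail_depth | qc_fail_mito
    planted_markers: set[str]
    marker_panel_map: dict[str, str] = field(default_factory=dict)
    mito_fraction: dict[str, float] = field(default_factory=dict)

    def cells_with_label(self, label: str) -> list[str]:
        return [c for c, lab in self.cell_label.items() if lab == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": list(self.cell_label),
                "label": list(self.cell_label.values()),
                "mito_fraction": [self.mito_fraction.get(c, np.nan) for c in self.cell_label],
            }
        )


def _gene_names(cfg: SimulationConfig) -> tuple[list[str], list[str]]:
    """Endogenous gene ids (panel + Cd44 + markers + background) and planted set."""
    n_other_markers = max(cfg.n_markers_planted - 1, 0)
    markers = [CD44_ROLE_GENE] + [f"MK{i + 1:04d}" for i in range(n_other_markers)]
    markers = markers[: cfg.n_markers_planted]
    n_bg = cfg.n_genes - len(DEFAULT_PANEL_GENES) - len(markers)
    background = [f"G{i + 1:05d}" for i in range(n_bg)]
    return list(DEFAULT_PANEL_GENES) + markers + background, markers


def generate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ReadCountTable, GroundTruth]:
    """Draw one synthetic dataset; bit-identical under a fixed config seed.

    Per-cell totals of endogenous + spike-in TPM equal 1e6 exactly, with
    spike-ins at ``spike_in_fraction``. Haematopoietic cells get the planted
    marker shift and switch on the blood-role panel genes while retaining
    endothelial-role panel expression. QC-failure cells are drawn below the
    500,000-read depth threshold or above a 0.30 mitochondrial fraction.
    """
    cfg = config
    endo_genes, planted = _gene_names(cfg)
    mito_genes = [f"mt-g{i + 1:02d}" for i in range(cfg.n_mito)]
    spike_genes = [f"ERCC-{i + 1:05d}" for i in range(cfg.n_spike_ins)]
    gene_ids = endo_genes + mito_genes + spike_genes
    gene_class = np.array(
        ["endogenous"] * len(endo_genes)
        + ["mitochondrial"] * cfg.n_mito
        + ["spike_in"] * cfg.n_spike_ins,
        dtype=object,
    )

    n_cells = cfg.n_cells_pass + cfg.n_fail_depth + cfg.n_fail_mito
    cell_ids = [f"cell_{i + 1:03d}" for i in range(n_cells)]

    # --- cell labels ------------------------------------------------------
    rng_lab = substream(cfg.seed, "labels")
    labels = np.array(
        ["endothelial"] * cfg.n_cells_pass
        + ["qc_fail_depth"] * cfg.n_fail_depth
        + ["qc_fail_mito"] * cfg.n_fail_mito,
        dtype=object,
    )
    haem_idx = rng_lab.choice(cfg.n_cells_pass, size=cfg.n_haem, replace=False)
    labels[haem_idx] = "haematopoietic"
    is_haem = labels == "haematopoietic"

    # --- gene baselines ---------------------------------------------------
    rng_gene = substream(cfg.seed, "gene_baselines")
    b0, b1 = cfg.base_log_mean_sd
    mu = rng_gene.normal(b0, b1, size=len(endo_genes))
    endo_pos = {g: i for i, g in enumerate(endo_genes)}
    for g in ENDOTHELIAL_PANEL_GENES:
        mu[endo_pos[g]] = 3.5
    for g in BLOOD_PANEL_GENES:
        mu[endo_pos[g]] = 0.0  # near-silent in plain endothelium
    for g in planted:
        # markers must be expressed to be discoverable
        mu[endo_pos[g]] = max(mu[endo_pos[g]], cfg.marker_baseline_floor)
    mu[endo_pos[CD44_ROLE_GENE]] = max(mu[endo_pos[CD44_ROLE_GENE]], 3.0)

    # --- log-mean shifts for haematopoietic cells -------------------------
    shift = np.zeros((n_cells, len(endo_genes)))
    for g in planted:
        shift[is_haem, endo_pos[g]] = cfg.marker_effect
    shift[is_haem, endo_pos[CD44_ROLE_GENE]] = cfg.marker_effect + cfg.cd44_extra_effect
    for g in BLOOD_PANEL_GENES:
        shift[is_haem, endo_pos[g]] = cfg.panel_blood_shift

    rng_expr = substream(cfg.seed, "expression")
    log_raw = mu[None, :] + shift + rng_expr.normal(
        0.0, cfg.within_cell_sd, size=(n_cells, len(endo_genes))
    )
    endo_raw = np.exp(log_raw)

    # --- mitochondrial fraction targeting ---------------------------------
    rng_mito = substream(cfg.seed, "mito")
    frac = rng_mito.uniform(0.02, 0.15, size=n_cells)
    fail_mito = labels == "qc_fail_mito"
    frac[fail_mito] = rng_mito.uniform(0.40, 0.60, size=int(fail_mito.sum()))
    mito_weights = rng_mito.lognormal(0.0, 1.0, size=(n_cells, cfg.n_mito))
    mito_weights /= mito_weights.sum(axis=1, keepdims=True)
    endo_tot = endo_raw.sum(axis=1)
    mito_raw = (frac / (1.0 - frac) * endo_tot)[:, None] * mito_weights

    # --- TPM scaling with spike-ins at a fixed fraction -------------------
    rng_spike = substream(cfg.seed, "spike_ins")
    spike_weights = rng_spike.lognormal(0.0, 1.0, size=cfg.n_spike_ins)
    spike_cell = spike_weights[None, :] * rng_spike.lognormal(
        0.0, 0.1, size=(n_cells, cfg.n_spike_ins)
    )
    spike_cell /= spike_cell.sum(axis=1, keepdims=True)
    spike_tpm = spike_cell * cfg.spike_in_fraction * 1e6

    biological = np.hstack([endo_raw, mito_raw])
    biological *= ((1.0 - cfg.spike_in_fraction) * 1e6 / biological.sum(axis=1))[:, None]
    values = np.hstack([biological, spike_tpm])

    matrix = ExpressionMatrix(
        values=values, cell_ids=cell_ids, gene_ids=gene_ids, gene_class=gene_class
    )

    # --- mapped reads -----------------------------------------------------
    rng_depth = substream(cfg.seed, "depth")
    reads = np.rint(
        rng_depth.lognormal(np.log(cfg.depth_mean), 0.2, size=n_cells)
    ).astype(int)
    reads = np.maximum(reads, MIN_READS_THRESHOLD)  # honest cells never fail depth
    fail_depth = labels == "qc_fail_depth"
    reads[fail_depth] = rng_depth.integers(
        100_000, MIN_READS_THRESHOLD, size=int(fail_depth.sum())
    )
    read_table = ReadCountTable(dict(zip(cell_ids, reads)))

    truth = GroundTruth(
        cell_label=dict(zip(cell_ids, labels)),
        planted_markers=set(planted),
        marker_panel_map={g: g for g in (*DEFAULT_PANEL_GENES, CD44_ROLE_GENE)},
        mito_fraction=dict(zip(cell_ids, frac)),
    )
    assert truth.marker_panel_map[DEFAULT_ANNOTATION_GENE] == DEFAULT_ANNOTATION_GENE
    return matrix, read_table, truth


def generate_category_map(
    n_genes: int,
    category_fraction: float,
    seed: int,
    gene_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assign each gene to a category independently with the given probability.

    Returns a two-column table (gene_id, in_category with 0/1 entries) used
    as input for Fisher-exact over-representation tests.
    """
    if not 0 <= category_fraction <= 1:
        raise ValueError("category_fraction must lie in [0, 1]")
    if gene_ids is None:
        gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    elif len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    rng = substream(seed, "category_map")
    member = rng.random(n_genes) < category_fraction
    return pd.DataFrame({"gene_id": list(gene_ids), "in_category": member.astype(int)})


def generate_metabolite_network(
    n_genes: int,
    n_metabolites: int,
    degree_law: Mapping[str, float] | None = None,
    seed: int = 0,
    gene_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Draw a bipartite gene-metabolite edge list.

    Each metabolite connects to k >= 1 distinct genes with
    k = 1 + Poisson(mean_degree - 1), truncated at the number of genes.
    Returned as a two-column (metabolite_id, gene_id) table.
    """
    if n_genes <= 0 or n_metabolites <= 0:
        raise ValueError("sizes must be positive")
    law = dict(degree_law or {})
    mean_degree = float(law.get("mean_degree", 5.0))
    if mean_degree < 1:
        raise ValueError("mean_degree must be >= 1")
    if gene_ids is None:
        gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    elif len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    rng = substream(seed, "metabolite_network")
    degrees = 1 + rng.poisson(mean_degree - 1.0, size=n_metabolites)
    degrees = np.minimum(degrees, n_genes)
    rows = []
    for m, k in enumerate(degrees):
        neighbours = rng.choice(n_genes, size=int(k), replace=False)
        met = f"met_{m + 1:04d}"
        rows.extend((met, gene_ids[j]) for j in neighbours)
    return pd.DataFrame(rows, columns=["metabolite_id", "gene_id"])
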