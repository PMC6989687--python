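"""Genome-wide likelihood-ratio marker scan with Bonferroni control.

Each gene's log expression is compared between the two labelled cell
populations with a Gaussian likelihood-ratio test: the null model fits one
common mean, the alternative adds a binary haematopoietic term (two group
means, shared variance), both with the MLE (1/n) variance. The statistic is

    LRT = n * ln(RSS_null / RSS_alt)  ~  chi-square(1 df) under the null,

equivalently n * ln(1 + t^2/(n-2)) for the pooled-variance t statistic.
Raw p-values are Bonferroni-adjusted over the number of genes actually
tested, and the effect size is the difference of group means of log
expression (haematopoietic minus endothelial).
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .classify_cells import CellLabelSet
from .io_model import ExpressionMatrix

logger = logging.getLogger("ehtmark")


class LRTResult(NamedTuple):
    lrt_stat: float
    p_raw: float
    effect: float


def lrt_gene(values: np.ndarray, labels: np.ndarray) -> LRTResult:
    """Likelihood-ratio test of a group-mean difference for one gene.

    ``labels`` is binary (1 = haematopoietic). Perfect separation
    (RSS_alt = 0 with RSS_null > 0) yields an infinite statistic and p = 0,
    with a logged warning.
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(labels).astype(bool)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 cells")
    if g.shape != x.shape:
        raise ValueError("values and labels must align")
    n1 = int(g.sum())
    if n1 == 0 or n1 == n:
        raise ValueError("both groups must be non-empty")

    rss_null = float(np.sum((x - x.mean()) ** 2))
    mu0 = x[~g].mean()
    mu1 = x[g].mean()
    rss_alt = float(np.sum((x[~g] - mu0) ** 2) + np.sum((x[g] - mu1) ** 2))
    effect = float(mu1 - mu0)

    if rss_alt == 0.0:
        if rss_null == 0.0:
            return LRTResult(0.0, 1.0, effect)
        logger.warning("perfect separation: RSS_alt = 0; p reported as 0")
        return LRTResult(float("inf"), 0.0, effect)
    stat = n * float(np.log(rss_null / rss_alt))
    stat = max(stat, 0.0)  # guard against -0.0 from rounding
    p = float(stats.chi2.sf(stat, df=1))
    return LRTResult(stat, p, effect)


def _scan_vectorised(
    X: np.ndarray, g: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(lrt_stat, p_raw, effect) for every column of X at once."""
    n = X.shape[0]
    rss_null = np.sum((X - X.mean(axis=0)) ** 2, axis=0)
    mu0 = X[~g].mean(axis=0)
    mu1 = X[g].mean(axis=0)
    rss_alt = np.sum((X[~g] - mu0) ** 2, axis=0) + np.sum((X[g] - mu1) ** 2, axis=0)
    effect = mu1 - mu0
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * np.log(rss_null / rss_alt)
    stat = np.where(rss_alt == 0, np.where(rss_null == 0, 0.0, np.inf), stat)
    stat = np.maximum(stat, 0.0)
    p = stats.chi2.sf(stat, df=1)
    p = np.where(np.isinf(stat), 0.0, p)
    return stat, p, effect


def scan_all(
    log_matrix: ExpressionMatrix,
    labels: CellLabelSet | np.ndarray,
    min_variance: float = 0.0,
) -> pd.DataFrame:
    """Per-gene LRT marker table, Bonferroni-corrected and ranked.

    Genes whose total variance is <= ``min_variance`` are excluded both from
    testing and from the Bonferroni family size m. Rows are sorted by raw
    p-value, ties broken by |effect| descending then gene identifier.
    Columns: gene_id, lrt_stat, p_raw, p_bonferroni, effect, n_tested.
    """
    if isinstance(labels, CellLabelSet):
        g = labels.binary_vector(log_matrix.cell_ids).astype(bool)
    else:
        g = np.asarray(labels).astype(bool)
        if g.shape != (log_matrix.n_cells,):
            raise ValueError("label vector must have one entry per cell")
    if g.sum() < 2 or (~g).sum() < 2:
        raise ValueError("need at least 2 cells per group")

    X = log_matrix.values
    variance = X.var(axis=0)
    testable = variance > min_variance
    m = int(testable.sum())
    if m == 0:
        raise ValueError("all genes excluded by the variance guard")

    stat, p, effect = _scan_vectorised(X[:, testable], g)
    table = pd.DataFrame(
        {
            "gene_id": [gid for gid, t in zip(log_matrix.gene_ids, testable) if t],
            "lrt_stat": stat,
            "p_raw": p,
            "p_bonferroni": np.minimum(1.0, m * p),
            "effect": effect,
            "n_tested": m,
        }
    )
    table["_abs_effect"] = table["effect"].abs()
    table = (
        table.sort_values(
            ["p_raw", "_abs_effect", "gene_id"], ascending=[True, False, True]
        )
        .drop(columns="_abs_effect")
        .reset_index(drop=True)
    )
    logger.info("marker scan: %d genes tested, %d excluded", m, int((~testable).sum()))
    return table


def volcano_table(table: pd.DataFrame) -> pd.DataFrame:
    """Plotting-ready (effect, -log10 adjusted p) long-format table.

    Adjusted p-values are floored at 1e-300 before taking the log so that
    perfectly separated genes stay finite.
    """
    if table.empty:
        raise ValueError("marker table is empty")
    p = np.maximum(table["p_bonferroni"].to_numpy(dtype=float), 1e-300)
    return pd.DataFrame(
        {
            "gene_id": table["gene_id"].to_numpy(),
            "effect": table["effect"].to_numpy(dtype=float),
            "neg_log10_p_bonferroni": -np.log10(p),
        }
    )


def heatmap_table(
    log_matrix: ExpressionMatrix,
    table: pd.DataFrame,
    labels: CellLabelSet,
    top_k: int = 25,
) -> pd.DataFrame:
    """Log expression of the top-k ranked markers, cells ordered by label."""
    genes = list(table["gene_id"].head(top_k))
    order = sorted(
        log_matrix.cell_ids, key=lambda c: (labels.labels[c] != "haematopoietic", c)
    )
    idx = [log_matrix.gene_index(gid) for gid in genes]
    cell_pos = {c: i for i, c in enumerate(log_matrix.cell_ids)}
    rows = log_matrix.values[np.ix_([cell_pos[c] for c in order], idx)]
    return pd.DataFrame(rows.T, index=genes, columns=order)
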