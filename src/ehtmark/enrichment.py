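"""Gene-set and reporter-metabolite enrichment.

Two complementary over-representation analyses:

* :func:`fisher_enrichment` — one-sided Fisher's exact test of a gene
  category within a selected gene set against a background universe, with
  fold enrichment (x/n)/(K/N).
* :func:`reporter_scores` — reporter-metabolite scoring over a bipartite
  gene-metabolite network: per-gene p-values are converted to normal
  quantiles z_g = Phi^-1(1 - p_g), aggregated per metabolite as
  z_agg = sum(z_g)/sqrt(k) over its k neighbour genes, and corrected
  against the mean and SD of z_agg over size-matched random gene sets, so
  a metabolite's corrected score is comparable across degrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

from ._rng import substream

logger = logging.getLogger("ehtmark")

P_CLIP = 1e-15


@dataclass
class EnrichmentResult:
    x: int  # category genes in the selected set
    n: int  # selected-set size
    K: int  # category genes in background
    N: int  # background size
    fold: float
    p_one_sided: float


def fisher_enrichment(
    selected: Iterable[str],
    category: Iterable[str],
    background: Iterable[str],
    alternative: str = "greater",
) -> EnrichmentResult:
    """Category over-representation in a selected set by Fisher's exact test.

    ``p_one_sided`` is P(X >= x) for X ~ Hypergeometric(N, K, n) when
    ``alternative='greater'`` (the default, matching an enrichment claim);
    ``alternative='two-sided'`` is available but non-default.
    """
    background = set(background)
    selected = set(selected)
    category = set(category)
    if not background:
        raise ValueError("background must be non-empty")
    if not category:
        raise ValueError("category must be non-empty")
    if not selected <= background:
        stray = sorted(selected - background)
        raise ValueError(f"selected genes outside background: {stray[:5]}")
    if not category <= background:
        stray = sorted(category - background)
        raise ValueError(f"category genes outside background: {stray[:5]}")

    N = len(background)
    n = len(selected)
    K = len(category)
    x = len(selected & category)
    if n == 0:
        raise ValueError("selected set must be non-empty")
    fold = (x / n) / (K / N)
    if alternative == "greater":
        p = float(stats.hypergeom.sf(x - 1, N, K, n))
    elif alternative == "two-sided":
        table = [[x, n - x], [K - x, N - K - (n - x)]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return EnrichmentResult(x=x, n=n, K=K, N=N, fold=fold, p_one_sided=min(p, 1.0))


def _background_moments(
    z: np.ndarray, k: int, n_background: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Mean and SD of z_agg over random size-k gene sets (without replacement)."""
    n = z.size
    chunk = max(1, int(2e6 // max(n, 1)))
    sums = np.empty(n_background)
    done = 0
    while done < n_background:
        b = min(chunk, n_background - done)
        keys = rng.random((b, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        sums[done : done + b] = z[idx].sum(axis=1)
        done += b
    agg = sums / np.sqrt(k)
    return float(agg.mean()), float(agg.std())


def reporter_scores(
    gene_p: Mapping[str, float],
    network: pd.DataFrame,
    n_background: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Reporter-metabolite table from gene p-values and a bipartite network.

    ``network`` must carry (metabolite_id, gene_id) columns. Edges to genes
    without a p-value are dropped with a warning; metabolites left with no
    scored neighbours are omitted. p-values are clipped to
    [1e-15, 1 - 1e-15] to keep the normal quantile finite. The background
    for each distinct degree k is ``n_background`` random size-k sets of
    scored genes drawn without replacement from the seeded generator.

    Returns columns: metabolite_id, k, z_agg, z_corrected, p_met.
    """
    if not gene_p:
        raise ValueError("gene_p is empty")
    genes = list(gene_p)
    z = ndtri(1.0 - np.clip([gene_p[g] for g in genes], P_CLIP, 1.0 - P_CLIP))
    z_by_gene = dict(zip(genes, z))

    cols = list(network.columns[:2])
    net = network.rename(columns=dict(zip(cols, ["metabolite_id", "gene_id"])))
    known = net["gene_id"].isin(z_by_gene)
    if not known.all():
        dropped = sorted(net.loc[~known, "gene_id"].unique())
        logger.warning("dropping %d network genes without p-values", len(dropped))
        net = net[known]
    if net.empty:
        raise ValueError("no network edge references a scored gene")

    grouped = net.groupby("metabolite_id")["gene_id"].apply(list)
    degrees = grouped.map(len)
    n_scored = len(genes)
    if int(degrees.max()) > n_scored:
        raise ValueError("a metabolite has more neighbours than scored genes")

    rng = substream(seed, "reporter_background")
    z_arr = np.asarray(z)
    moments: dict[int, tuple[float, float]] = {}
    for k in sorted(degrees.unique()):
        mu_k, sd_k = _background_moments(z_arr, int(k), n_background, rng)
        if sd_k == 0:
            raise ValueError(f"degenerate background (sd = 0) at degree k={k}")
        moments[int(k)] = (mu_k, sd_k)

    rows = []
    for met, neigh in grouped.items():
        k = len(neigh)
        z_agg = float(sum(z_by_gene[g] for g in neigh) / np.sqrt(k))
        mu_k, sd_k = moments[k]
        z_corr = (z_agg - mu_k) / sd_k
        rows.append((met, k, z_agg, z_corr, float(stats.norm.sf(z_corr))))
    out = pd.DataFrame(
        rows, columns=["metabolite_id", "k", "z_agg", "z_corrected", "p_met"]
    )
    return out.sort_values("p_met", kind="mergesort").reset_index(drop=True)
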