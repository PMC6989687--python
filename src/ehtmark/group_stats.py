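"""Welch's unequal-variance t-test, from raw data or printed summaries.

Figure legends often report only group means, sample SDs and sizes;
:func:`welch_t_from_summary` reproduces the Welch statistic and
Satterthwaite degrees of freedom from exactly those numbers, and
:func:`welch_t_from_raw` reduces raw samples to summaries first so the two
routes agree by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats


@dataclass
class GroupSummary:
    """Mean, sample SD (n-1 denominator) and size of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be at least 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


class WelchResult(NamedTuple):
    t: float
    df: float
    p_two_sided: float


def welch_t_from_summary(g1: GroupSummary, g2: GroupSummary) -> WelchResult:
    """Welch's two-sample t-test from summary statistics.

    t = (mean2 - mean1) / sqrt(sd1^2/n1 + sd2^2/n2), with the
    Welch-Satterthwaite degrees of freedom and a two-sided p-value. Sign
    convention: group 2 minus group 1.
    """
    v1 = g1.sd**2 / g1.n
    v2 = g2.sd**2 / g2.n
    se2 = v1 + v2
    if se2 == 0:
        raise ValueError("both group SDs are zero; t undefined")
    t = (g2.mean - g1.mean) / np.sqrt(se2)
    df = se2**2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return WelchResult(float(t), float(df), min(p, 1.0))


def summarise(x: Sequence[float]) -> GroupSummary:
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 observations")
    return GroupSummary(mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=arr.size)


def welch_t_from_raw(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Welch's t-test on raw samples (delegates to the summary form)."""
    return welch_t_from_summary(summarise(x), summarise(y))
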