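"""Per-cell translation statistics: normalized signal, robust group
comparisons, the Mann-Whitney rank test, and Pearson correlation with
bacterial load.

The translation readout is summed fluorescence (integrated density) over a
cell, normalized by cell area.  For grouped comparisons cells are coarsened
into three infection categories: no bacteria, low (1-10) and medium-high
(>= 11).  The rank test is exact (full enumeration of group assignments)
up to a combined sample size of 12 and a tie-corrected normal
approximation beyond that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .infection_profile import InfectionClassBins

EXACT_MAX_N = 12

NO_WOLBACHIA = "none"
LOW_WOLBACHIA = "low"
MEDIUM_HIGH_WOLBACHIA = "medium-high"


@dataclass
class CellMeasurement:
    """One cell's translation signal and bacterial load."""

    cell_id: str
    integrated_density: float
    area: float
    wolbachia_count: int

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("area must be positive")
        if self.wolbachia_count < 0:
            raise ValueError("wolbachia_count must be nonnegative")

    @property
    def normalized(self) -> float:
        return self.integrated_density / self.area

    @property
    def infection_group(self) -> str:
        return infection_group(self.wolbachia_count)


def infection_group(
    count: int, bins: InfectionClassBins = InfectionClassBins()
) -> str:
    """Three-way grouping: none / low / medium-high."""
    if count < 0:
        raise ValueError("count must be nonnegative")
    if count == 0:
        return NO_WOLBACHIA
    if count <= bins.low[1]:
        return LOW_WOLBACHIA
    return MEDIUM_HIGH_WOLBACHIA


def normalized_level(integrated_density: float, area: float) -> float:
    """Translation level: integrated density per unit cell area."""
    if area <= 0:
        raise ValueError("area must be positive")
    return integrated_density / area


def median_percent_decrease(
    group_a: Sequence[float], group_b: Sequence[float]
) -> float:
    """Percent by which median(b) sits below median(a)."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    med_a = float(np.median(group_a))
    med_b = float(np.median(group_b))
    if med_a == 0:
        raise ValueError("reference median is zero")
    return 100.0 * (med_a - med_b) / med_a


class RankTestResult(NamedTuple):
    u: float  # U statistic of the first group
    p_value: float
    method: str  # "exact" or "asymptotic"


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of ``a`` (pairs where a > b count 1, ties 0.5)."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def rank_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> RankTestResult:
    """Two-sided Mann-Whitney test.

    For combined n <= 12 the null distribution of U is enumerated over all
    group assignments of the pooled observations (exact even under ties);
    the two-sided p sums both tails at the observed extremity.  Larger
    samples use the tie-corrected normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    u_obs = _u_statistic(a, b)
    n1, n2 = a.size, b.size
    if n1 + n2 <= EXACT_MAX_N:
        pooled = np.concatenate([a, b])
        total = pooled.size
        us = []
        for idx in combinations(range(total), n1):
            mask = np.zeros(total, dtype=bool)
            mask[list(idx)] = True
            us.append(_u_statistic(pooled[mask], pooled[~mask]))
        us = np.asarray(us)
        u_min = min(u_obs, n1 * n2 - u_obs)
        eps = 1e-9
        p = ((us <= u_min + eps).sum() + (us >= n1 * n2 - u_min - eps).sum()) / us.size
        return RankTestResult(u=u_obs, p_value=min(float(p), 1.0), method="exact")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return RankTestResult(u=u_obs, p_value=float(res.pvalue), method="asymptotic")


class CorrelationResult(NamedTuple):
    r: float
    p_value: float
    n: int


def pearson_correlation(
    levels: Sequence[float], counts: Sequence[float]
) -> CorrelationResult:
    """Sample Pearson r between translation levels and bacterial counts,
    with the two-sided p from the t transform on n-2 degrees of freedom."""
    x = np.asarray(levels, dtype=float)
    y = np.asarray(counts, dtype=float)
    if x.size != y.size:
        raise ValueError("levels and counts must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 cells")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in one margin")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=int(x.size))
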