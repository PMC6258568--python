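"""Gene-set over-representation among hit genes.

The test is the one-sided hypergeometric (Fisher exact upper tail): with N
screened background genes of which n are hits, a set with K expressed
members in the background and k hit members has

    p = P(X >= k),  X ~ Hypergeom(N, K, n).

Sets are restricted to their expressed members inside the screened
background before sizing, matching "expressed proteins" denominators; sets
with K below ``min_size`` (default 3) are skipped.  Raw p < alpha (default
0.05) flags enrichment; Benjamini-Hochberg q-values are reported alongside
for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import math

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def _round_half_up(x: float, decimals: int = 1) -> float:
    f = 10.0**decimals
    return math.floor(x * f + 0.5) / f


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValueError("gene set must have at least one member")
        if len(set(self.members)) != len(self.members):
            raise ValueError("gene set members must be unique")


@dataclass
class EnrichmentResult:
    """One set's over-representation record; ``skipped_reason`` is non-empty
    for sets excluded before testing."""

    set_id: str
    name: str
    N: int
    K: int
    n: int
    k: int
    p_value: float
    coverage_percent: float
    enriched: bool
    q_value: float | None = None
    skipped_reason: str = ""


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Exact upper tail P(X >= k) of the hypergeometric distribution."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K <= N and 0 <= n <= N")
    if not 0 <= k <= min(K, n):
        raise ValueError("need 0 <= k <= min(K, n)")
    return float(hypergeom.sf(k - 1, N, K, n))


def coverage_percent(k: int, K: int) -> float:
    """Percent of a set's expressed members that are hits, to one decimal."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if not 0 <= k <= K:
        raise ValueError("need 0 <= k <= K")
    return _round_half_up(100.0 * k / K, 1)


def enrich_sets(
    sets: Sequence[GeneSet],
    hits: Iterable[str],
    background: Iterable[str],
    expressed: Iterable[str] | None = None,
    min_size: int = 3,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every set for over-representation of hits in the background.

    The effective background is the screened genes, intersected with the
    expressed genes when given; set membership is restricted the same way.
    Every input set appears in the output exactly once, tested or skipped.
    """
    bg = set(background)
    hit_set = set(hits)
    stray = hit_set - bg
    if stray:
        raise ValueError(f"hit genes not in background: {sorted(stray)[:10]}")
    if expressed is not None:
        bg = bg & set(expressed)
        hit_set = hit_set & bg
    N, n = len(bg), len(hit_set)

    results: list[EnrichmentResult] = []
    for gs in sets:
        members = set(gs.members) & bg
        K = len(members)
        if K < min_size:
            results.append(
                EnrichmentResult(
                    set_id=gs.set_id, name=gs.name, N=N, K=K, n=n,
                    k=len(members & hit_set), p_value=1.0,
                    coverage_percent=0.0, enriched=False,
                    skipped_reason=f"below min_size ({K} < {min_size})",
                )
            )
            continue
        k = len(members & hit_set)
        p = hypergeom_pvalue(N, K, n, k)
        results.append(
            EnrichmentResult(
                set_id=gs.set_id, name=gs.name, N=N, K=K, n=n, k=k,
                p_value=p, coverage_percent=coverage_percent(k, K),
                enriched=p < alpha,
            )
        )

    tested = [r for r in results if not r.skipped_reason]
    if tested:
        _, q, _, _ = multipletests([r.p_value for r in tested], method="fdr_bh")
        for r, qv in zip(tested, q):
            r.q_value = float(qv)
    return results
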