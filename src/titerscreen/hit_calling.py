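"""Replicate-consistent hit calling and gene-level aggregation.

An amplicon is a hit when at least ``min_replicates`` of its replicate
robust-Z scores pass the threshold (default |z| >= 1.5 in 2 of 3) *on the
same side*: replicates crossing the limit in opposite directions do not
reinforce each other.  Gene calls aggregate the amplicon calls:

* direction — majority direction among the gene's hit amplicons (an exact
  tie yields no call and is logged);
* confidence — ``high`` if >= 2 amplicons hit concordantly, ``medium`` if
  the gene's sole library amplicon hit, ``low`` if exactly 1 of >= 2
  library amplicons hit;
* proliferation class — the gene's median proliferation robust-Z crossed
  against a strict |z| > 1 limit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .normalization import NormalizedWell
from .synthetic_data import AmpliconRecord

logger = logging.getLogger(__name__)

INCREASE = "increase"
DECREASE = "decrease"
NONE = "none"
INSUFFICIENT = "insufficient data"

WOLBACHIA_DIRECTIONS = (INCREASE, DECREASE, NONE)
PROLIFERATION_CLASSES = (INCREASE, NONE, DECREASE)


@dataclass(frozen=True)
class HitThresholds:
    """Screen-wide calling limits, on the robust-Z scale."""

    z_hit: float = 1.5
    min_replicates: int = 2
    z_prolif: float = 1.0

    def __post_init__(self) -> None:
        if self.z_hit <= 0 or self.z_prolif <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_replicates < 1:
            raise ValueError("min_replicates must be >= 1")


@dataclass
class GeneCall:
    """Gene-level verdict aggregated over library amplicons."""

    gene_id: str
    direction: str
    confidence: str
    n_amplicons_in_library: int
    n_amplicons_hit: int
    proliferation_class: str = NONE

    def __post_init__(self) -> None:
        if (self.direction != NONE) != (self.n_amplicons_hit >= 1):
            raise ValueError("direction and supporting amplicon count disagree")
        if (self.confidence == NONE) != (self.direction == NONE):
            raise ValueError("confidence and direction disagree")
        if self.n_amplicons_hit > self.n_amplicons_in_library:
            raise ValueError("more hit amplicons than library amplicons")


def call_amplicon(
    z_scores: Sequence[float], thresholds: HitThresholds = HitThresholds()
) -> str:
    """Direction call for one amplicon from its replicate robust-Z scores.

    Missing replicates (NaN) are dropped; with fewer than ``min_replicates``
    usable scores the call is "insufficient data".
    """
    zs = [z for z in z_scores if not math.isnan(z)]
    if len(zs) < thresholds.min_replicates:
        return INSUFFICIENT
    n_up = sum(z >= thresholds.z_hit for z in zs)
    n_down = sum(z <= -thresholds.z_hit for z in zs)
    if n_up >= thresholds.min_replicates and n_down >= thresholds.min_replicates:
        # can only happen with >3 replicates; incoherent, no call
        logger.warning("amplicon passes both limits in >= %d replicates", thresholds.min_replicates)
        return NONE
    if n_up >= thresholds.min_replicates:
        return INCREASE
    if n_down >= thresholds.min_replicates:
        return DECREASE
    return NONE


def aggregate_gene(
    gene_id: str,
    amplicon_calls: Sequence[str],
    n_amplicons_in_library: int,
    proliferation_class: str = NONE,
) -> GeneCall:
    """Aggregate one gene's valid amplicon calls into a :class:`GeneCall`."""
    calls = [c for c in amplicon_calls if c != INSUFFICIENT]
    if not calls:
        raise ValueError(f"gene {gene_id!r}: no amplicon with a valid call")
    if len(calls) > n_amplicons_in_library:
        raise ValueError(f"gene {gene_id!r}: more calls than library amplicons")
    n_up = calls.count(INCREASE)
    n_down = calls.count(DECREASE)
    if n_up == n_down == 0:
        direction, n_hit = NONE, 0
    elif n_up == n_down:
        logger.info("gene %s: tied amplicon directions (%d vs %d); no call", gene_id, n_up, n_down)
        direction, n_hit = NONE, 0
    elif n_up > n_down:
        direction, n_hit = INCREASE, n_up
    else:
        direction, n_hit = DECREASE, n_down

    if direction == NONE:
        confidence = NONE
    elif n_hit >= 2:
        confidence = "high"
    elif n_amplicons_in_library == 1:
        confidence = "medium"
    else:
        confidence = "low"
    return GeneCall(
        gene_id=gene_id,
        direction=direction,
        confidence=confidence,
        n_amplicons_in_library=n_amplicons_in_library,
        n_amplicons_hit=n_hit,
        proliferation_class=proliferation_class,
    )


def classify_proliferation(
    median_z: float, thresholds: HitThresholds = HitThresholds()
) -> str:
    """Proliferation class from a gene's median robust-Z; strict inequality."""
    if math.isnan(median_z):
        return NONE
    if median_z > thresholds.z_prolif:
        return INCREASE
    if median_z < -thresholds.z_prolif:
        return DECREASE
    return NONE


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting precision for percents)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - math.floor(math.log10(abs(x))))


@dataclass
class CrossTab:
    """Wolbachia direction x proliferation class contingency."""

    counts: pd.DataFrame
    percent: pd.DataFrame  # row percentages at 2 significant figures


def cross_tabulate(gene_calls: Iterable[GeneCall]) -> CrossTab:
    """Cross-tabulate gene direction against proliferation class.

    Percentages are per Wolbachia-direction row, rounded to two significant
    figures (the reporting precision used for screen summaries).
    """
    calls = list(gene_calls)
    if not calls:
        raise ValueError("no gene calls")
    counts = pd.DataFrame(
        0, index=list(WOLBACHIA_DIRECTIONS), columns=list(PROLIFERATION_CLASSES)
    )
    for c in calls:
        counts.loc[c.direction, c.proliferation_class] += 1
    totals = counts.sum(axis=1)
    percent = counts.div(totals.replace(0, np.nan), axis=0) * 100.0
    percent = percent.map(lambda v: round_sig(v, 2) if not math.isnan(v) else v)
    counts.index.name = percent.index.name = "wolbachia"
    counts.columns.name = percent.columns.name = "proliferation"
    return CrossTab(counts=counts, percent=percent)


def call_screen(
    normalized: Sequence[NormalizedWell],
    manifest: Sequence[AmpliconRecord],
    thresholds: HitThresholds = HitThresholds(),
) -> list[GeneCall]:
    """Full hit-calling pass: amplicon calls from replicate scores, then
    gene aggregation with proliferation classification.

    ``manifest`` should be the QC-retained library (single-target amplicons
    off the artifact well); flagged amplicons present anyway are ignored.
    """
    z_wol: dict[tuple[int, str], list[float]] = {}
    z_pro: dict[tuple[int, str], list[float]] = {}
    for w in normalized:
        key = (w.plate, w.well)
        z_wol.setdefault(key, []).append(w.robust_z_wolbachia)
        z_pro.setdefault(key, []).append(w.robust_z_proliferation)

    per_gene_calls: dict[str, list[str]] = {}
    per_gene_prolif: dict[str, list[float]] = {}
    n_in_library: dict[str, int] = {}
    for rec in manifest:
        if rec.flag_outdated or rec.flag_multitarget or rec.flag_positional:
            continue
        gene = rec.targets[0]
        n_in_library[gene] = n_in_library.get(gene, 0) + 1
        key = (rec.plate, rec.well)
        if key not in z_wol:
            logger.warning("amplicon %s at plate %d well %s has no readouts", rec.amplicon_id, *key)
            continue
        call = call_amplicon(z_wol[key], thresholds)
        if call == INSUFFICIENT:
            logger.info("amplicon %s: insufficient replicates", rec.amplicon_id)
            continue
        per_gene_calls.setdefault(gene, []).append(call)
        pro = [z for z in z_pro[key] if not math.isnan(z)]
        if pro:
            per_gene_prolif.setdefault(gene, []).append(float(np.median(pro)))

    out: list[GeneCall] = []
    for gene in sorted(per_gene_calls):
        pro_scores = per_gene_prolif.get(gene, [])
        pro_class = classify_proliferation(
            float(np.median(pro_scores)) if pro_scores else math.nan, thresholds
        )
        out.append(
            aggregate_gene(gene, per_gene_calls[gene], n_in_library[gene], pro_class)
        )
    return out


def gene_calls_to_frame(calls: Iterable[GeneCall]) -> pd.DataFrame:
    """Tabular view of gene calls (one row per gene)."""
    return pd.DataFrame(
        [
            {
                "gene": c.gene_id,
                "direction": c.direction,
                "confidence": c.confidence,
                "n_amplicons_in_library": c.n_amplicons_in_library,
                "n_amplicons_hit": c.n_amplicons_hit,
                "proliferation_class": c.proliferation_class,
            }
            for c in calls
        ]
    )
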