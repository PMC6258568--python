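"""Relative qPCR quantification and culture growth arithmetic.

Bacterial genome abundance per host genome is quantified from paired Cq
values by the efficiency-exponentiated Cq difference (delta-Cq on the mean
of technical replicates):

    abundance = E ** (mean(Cq_reference) - mean(Cq_target)),

with perfect amplification (E = 2) by default.  Fold changes between
samples are ratios of those abundances (delta-delta-Cq).  RNAi knockdown
efficiency converts a treated/control expression ratio to a percent
reduction.  Doubling time follows the base-10 growth-curve formula with the
3.32 ~ 1/log10(2) constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

DOUBLING_CONSTANT = 3.32  # ~ 1/log10(2)


@dataclass
class QpcrSample:
    """Technical-replicate Cq values for one sample's target and reference."""

    sample_id: str
    target_cq: Sequence[float]
    reference_cq: Sequence[float]
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        if len(self.target_cq) < 1 or len(self.reference_cq) < 1:
            raise ValueError("need at least one technical replicate per amplicon")
        if not 1.0 < self.efficiency <= 2.0:
            raise ValueError("efficiency must be in (1, 2]")


@dataclass(frozen=True)
class GrowthObservation:
    """Two time points of a growth curve (hours, cell counts)."""

    t1: float
    t2: float
    n1: float
    n2: float

    def __post_init__(self) -> None:
        if not self.t2 > self.t1:
            raise ValueError("t2 must exceed t1")
        if not self.n2 > self.n1 > 0:
            raise ValueError("need n2 > n1 > 0")


@dataclass(frozen=True)
class KnockdownResult:
    percent_knockdown: float
    upregulated: bool = False


def relative_abundance(sample: QpcrSample) -> float:
    """Target copies per reference copy from mean technical-replicate Cq."""
    delta = float(np.mean(sample.reference_cq)) - float(np.mean(sample.target_cq))
    return sample.efficiency**delta


def fold_change(sample_ratio: float, control_ratio: float) -> float:
    """Relative abundance of a sample versus a control sample."""
    if control_ratio <= 0:
        raise ValueError("control ratio must be positive")
    return sample_ratio / control_ratio


def knockdown_efficiency(treated_expression_ratio: float) -> KnockdownResult:
    """Percent knockdown from a treated/control expression ratio.

    A ratio above 1 means the transcript went up, not down; the percent is
    floored at 0 and the result flagged upregulated.
    """
    if treated_expression_ratio < 0:
        raise ValueError("expression ratio must be nonnegative")
    if treated_expression_ratio > 1.0:
        return KnockdownResult(0.0, upregulated=True)
    return KnockdownResult(100.0 * (1.0 - treated_expression_ratio))


def doubling_time(obs: GrowthObservation) -> float:
    """Culture doubling time in hours: (t2-t1) / (3.32 * (log10 n2 - log10 n1))."""
    return (obs.t2 - obs.t1) / (
        DOUBLING_CONSTANT * (math.log10(obs.n2) - math.log10(obs.n1))
    )
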