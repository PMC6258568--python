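"""Per-cell infection classes and population summaries.

Cells are binned by bacterial count: uninfected (0), low (1-10), medium
(11-30) and high (>30).  Population summaries report the infected fraction
and the class mixture *among infected cells*, the scale on which treatment
comparisons (e.g. the medium+high fold change after a knockdown) are made.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

UNINFECTED = "uninfected"
LOW = "low"
MEDIUM = "medium"
HIGH = "high"
CLASSES = (UNINFECTED, LOW, MEDIUM, HIGH)


@dataclass(frozen=True)
class InfectionClassBins:
    """Inclusive count intervals; ``high`` is open above."""

    low: tuple[int, int] = (1, 10)
    medium: tuple[int, int] = (11, 30)
    high_min: int = 31

    def __post_init__(self) -> None:
        if not (1 <= self.low[0] <= self.low[1] < self.medium[0] <= self.medium[1] < self.high_min):
            raise ValueError("bins must be disjoint, ordered, and cover all positive counts")
        if self.medium[0] != self.low[1] + 1 or self.high_min != self.medium[1] + 1:
            raise ValueError("bins must leave no gap between classes")


@dataclass
class PopulationSummary:
    """Infection profile of one cell population."""

    n_cells: int
    frac_infected: float
    class_fractions_among_infected: tuple[float, float, float]  # (low, medium, high)

    def __post_init__(self) -> None:
        if self.frac_infected > 0:
            s = sum(self.class_fractions_among_infected)
            if abs(s - 1.0) > 1e-9:
                raise ValueError("class fractions among infected must sum to 1")


def classify_cell(count: int, bins: InfectionClassBins = InfectionClassBins()) -> str:
    """Infection class of one cell from its bacterial count."""
    if count < 0:
        raise ValueError("count must be nonnegative")
    if count == 0:
        return UNINFECTED
    if count <= bins.low[1]:
        return LOW
    if count <= bins.medium[1]:
        return MEDIUM
    return HIGH


def classify_counts(
    counts: Sequence[int], bins: InfectionClassBins = InfectionClassBins()
) -> np.ndarray:
    """Vectorized :func:`classify_cell`."""
    arr = np.asarray(counts, dtype=int)
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    out = np.full(arr.shape, UNINFECTED, dtype=object)
    out[(arr >= 1) & (arr <= bins.low[1])] = LOW
    out[(arr > bins.low[1]) & (arr <= bins.medium[1])] = MEDIUM
    out[arr >= bins.high_min] = HIGH
    return out


def population_summary(
    counts: Sequence[int], bins: InfectionClassBins = InfectionClassBins()
) -> PopulationSummary:
    """Infected fraction and class mixture among infected cells."""
    arr = np.asarray(counts, dtype=int)
    if arr.size == 0:
        raise ValueError("counts is empty")
    classes = classify_counts(arr, bins)
    n_inf = int((arr > 0).sum())
    if n_inf == 0:
        fractions = (0.0, 0.0, 0.0)
    else:
        fractions = tuple(
            float((classes == c).sum()) / n_inf for c in (LOW, MEDIUM, HIGH)
        )
    return PopulationSummary(
        n_cells=int(arr.size),
        frac_infected=n_inf / arr.size,
        class_fractions_among_infected=fractions,  # type: ignore[arg-type]
    )


def class_fold_change(
    summary_control: PopulationSummary, summary_treated: PopulationSummary
) -> float:
    """Fold change of the combined medium+high fraction among infected cells,
    treated over control, reported to one decimal."""
    ctrl = summary_control.class_fractions_among_infected
    trt = summary_treated.class_fractions_among_infected
    denom = ctrl[1] + ctrl[2]
    if denom == 0:
        raise ValueError("control medium+high fraction is zero")
    return math.floor((trt[1] + trt[2]) / denom * 10.0 + 0.5) / 10.0
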