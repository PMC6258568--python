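"""Plate-level robust-Z normalization of screen well readouts.

Each 384-well plate-replicate is normalized independently.  The per-well
*Wolbachia* readout is total FISH intensity divided by the number of
DAPI-stained nuclei; the proliferation readout is nuclei per field of view.
Both are converted to robust Z scores

    z = (x - median) / (1.4826 * MAD),

where the median and MAD are taken over the plate's *experimental* wells
only: designed control wells and the A1 artifact well are scored against
that reference but never contribute to it.  The 1.4826 consistency constant
makes the scale comparable to a classical standard deviation under
normality.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Collection, Iterable, Sequence

import numpy as np

from .synthetic_data import WellReadout

logger = logging.getLogger(__name__)

#: scale factor making 1.4826*MAD a consistent estimator of sigma
MAD_SCALE = 1.4826

#: minimum number of scorable experimental wells for a plate to be normalized
MIN_SCORABLE_WELLS = 8

#: well label carrying the systematic positional artifact
A1_WELL = "A1"


class DegeneratePlateError(ValueError):
    """Raised when a plate's experimental wells have zero robust spread."""


class InsufficientWellsError(ValueError):
    """Raised when a plate-replicate has too few scorable experimental wells."""


class FailedWellError(ValueError):
    """Raised for a well with zero nuclei (no denominator for the readout)."""


@dataclass
class NormalizedWell:
    """One well of one plate-replicate after plate normalization."""

    plate: int
    well: str
    replicate: int
    wolbachia_per_cell: float
    robust_z_wolbachia: float
    proliferation_ratio: float
    robust_z_proliferation: float
    excluded_from_stats: bool
    failed: bool = False
    control: str = ""


def wolbachia_per_cell(fish_total_intensity: float, cell_count: int) -> float:
    """Average bacterial FISH signal per host nucleus in a well.

    Raises :class:`FailedWellError` when ``cell_count`` is zero: such a well
    is a staining/seeding failure and must be excluded explicitly, not given
    an arbitrary value.
    """
    if cell_count == 0:
        raise FailedWellError("well has zero nuclei; mark as failed")
    if cell_count < 0 or fish_total_intensity < 0:
        raise ValueError("readouts must be nonnegative")
    return fish_total_intensity / cell_count


def proliferation_ratio(cell_count: int, fields_of_view: int) -> float:
    """Nuclei per field of view: the screen's proliferation proxy."""
    if fields_of_view < 1:
        raise ValueError("fields_of_view must be >= 1")
    if cell_count < 0:
        raise ValueError("cell_count must be nonnegative")
    return cell_count / fields_of_view


def robust_center_scale(values: Sequence[float]) -> tuple[float, float]:
    """Median and scaled MAD (1.4826*MAD) of a collection of readouts."""
    arr = np.asarray(values, dtype=float)
    med = float(np.median(arr))
    mad = float(np.median(np.abs(arr - med)))
    return med, MAD_SCALE * mad


def robust_z(values: Sequence[float], x: float) -> float:
    """Robust Z score of ``x`` against the reference ``values``.

    Raises :class:`DegeneratePlateError` when the MAD of the reference is
    zero (no resolvable spread).
    """
    med, scale = robust_center_scale(values)
    if scale == 0.0:
        raise DegeneratePlateError("MAD of reference values is zero")
    return (x - med) / scale


def robust_z_scores(values: Sequence[float], xs: Sequence[float]) -> np.ndarray:
    """Vectorized :func:`robust_z` of each entry of ``xs`` against ``values``."""
    med, scale = robust_center_scale(values)
    if scale == 0.0:
        raise DegeneratePlateError("MAD of reference values is zero")
    return (np.asarray(xs, dtype=float) - med) / scale


def normalize_plate(
    readouts: Sequence[WellReadout],
    control_wells: Collection[str] = (),
    a1_well: str = A1_WELL,
    min_wells: int = MIN_SCORABLE_WELLS,
) -> list[NormalizedWell]:
    """Normalize one plate-replicate's wells to robust Z scores.

    ``control_wells`` are the designed control positions; they and the A1
    artifact well are flagged ``excluded_from_stats``: scored against the
    experimental reference but not part of it.  Failed wells (zero nuclei)
    are emitted with NaN scores and ``failed=True``.
    """
    plates = {(r.plate, r.replicate) for r in readouts}
    if len(plates) != 1:
        raise ValueError(f"expected one plate-replicate, got {sorted(plates)}")
    plate, replicate = plates.pop()

    excluded = set(control_wells) | {a1_well}
    per_cell: dict[str, float] = {}
    ratio: dict[str, float] = {}
    failed: set[str] = set()
    for r in readouts:
        try:
            per_cell[r.well] = wolbachia_per_cell(r.fish_total_intensity, r.cell_count)
        except FailedWellError:
            failed.add(r.well)
            logger.warning("plate %s rep %s well %s failed (zero nuclei)", plate, replicate, r.well)
            continue
        ratio[r.well] = proliferation_ratio(r.cell_count, r.fields_of_view)

    exp_wells = [w for w in per_cell if w not in excluded]
    if len(exp_wells) < min_wells:
        raise InsufficientWellsError(
            f"plate {plate} replicate {replicate}: only {len(exp_wells)} scorable "
            f"experimental wells (< {min_wells})"
        )

    ref_wol = [per_cell[w] for w in exp_wells]
    ref_pro = [ratio[w] for w in exp_wells]
    med_w, scale_w = robust_center_scale(ref_wol)
    med_p, scale_p = robust_center_scale(ref_pro)
    if scale_w == 0.0 or scale_p == 0.0:
        raise DegeneratePlateError(
            f"plate {plate} replicate {replicate}: degenerate spread "
            f"(Wolbachia scale {scale_w}, proliferation scale {scale_p})"
        )

    out: list[NormalizedWell] = []
    for r in readouts:
        if r.well in failed:
            out.append(
                NormalizedWell(
                    plate=plate, well=r.well, replicate=replicate,
                    wolbachia_per_cell=math.nan, robust_z_wolbachia=math.nan,
                    proliferation_ratio=math.nan, robust_z_proliferation=math.nan,
                    excluded_from_stats=True, failed=True, control=r.control,
                )
            )
            continue
        out.append(
            NormalizedWell(
                plate=plate, well=r.well, replicate=replicate,
                wolbachia_per_cell=per_cell[r.well],
                robust_z_wolbachia=(per_cell[r.well] - med_w) / scale_w,
                proliferation_ratio=ratio[r.well],
                robust_z_proliferation=(ratio[r.well] - med_p) / scale_p,
                excluded_from_stats=r.well in excluded,
                control=r.control,
            )
        )
    return out


def normalize_screen(
    readouts: Iterable[WellReadout],
    control_wells: Collection[str] = (),
    a1_well: str = A1_WELL,
) -> list[NormalizedWell]:
    """Normalize every plate-replicate of a screen independently.

    Plates with too few scorable wells are skipped with a logged reason;
    degenerate plates raise, since silent loss of a whole plate's signal
    would bias downstream hit calling.
    """
    groups: dict[tuple[int, int], list[WellReadout]] = {}
    for r in readouts:
        groups.setdefault((r.plate, r.replicate), []).append(r)
    out: list[NormalizedWell] = []
    for (plate, replicate), rs in sorted(groups.items()):
        try:
            out.extend(normalize_plate(rs, control_wells, a1_well=a1_well))
        except InsufficientWellsError as exc:
            logger.warning("skipping plate: %s", exc)
    return out
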