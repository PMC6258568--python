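"""Library-level amplicon exclusions and the expression filter.

Three reagent categories are removed before analysis, with a fixed
precedence so every amplicon is removed under exactly one reason and the
audit counts are additive:

1. ``outdated``      — the amplicon no longer maps to any current gene model;
2. ``multitarget``   — it is predicted to silence two or more genes;
3. ``positional``    — it was plated in well A1, which carries a systematic
   plate-handling artifact.

The expression filter removes genes with undetectable expression in the
assay cell line; it is applied to candidate hit genes after calling (a
knockdown of an unexpressed gene cannot cause a real phenotype), though the
function is generic and can equally pre-filter a library's targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .synthetic_data import AmpliconRecord

REASON_OUTDATED = "outdated"
REASON_MULTITARGET = "multitarget"
REASON_POSITIONAL = "positional"
REASON_NOT_IN_TABLE = "not in expression table"
REASON_BELOW_THRESHOLD = "expression below threshold"


@dataclass
class QcReport:
    """Auditable record of library filtering."""

    n_input: int
    n_removed_outdated: int
    n_removed_multitarget: int
    n_removed_positional: int
    n_retained: int
    removed_ids_by_reason: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = (
            self.n_retained
            + self.n_removed_outdated
            + self.n_removed_multitarget
            + self.n_removed_positional
        )
        if total != self.n_input:
            raise ValueError(
                f"QC counts inconsistent: {total} accounted for, {self.n_input} input"
            )


def filter_library(
    manifest: Sequence[AmpliconRecord],
) -> tuple[list[AmpliconRecord], QcReport]:
    """Apply the three exclusions, returning the screened set and a report.

    Precedence outdated > multitarget > positional keeps the removal
    categories disjoint.  Duplicate amplicon ids are an error: the manifest
    is the unit of accounting.
    """
    if not manifest:
        raise ValueError("manifest is empty")
    seen: set[str] = set()
    for rec in manifest:
        if rec.amplicon_id in seen:
            raise ValueError(f"duplicate amplicon_id {rec.amplicon_id!r}")
        seen.add(rec.amplicon_id)

    removed: dict[str, list[str]] = {
        REASON_OUTDATED: [],
        REASON_MULTITARGET: [],
        REASON_POSITIONAL: [],
    }
    retained: list[AmpliconRecord] = []
    for rec in manifest:
        if rec.flag_outdated:
            removed[REASON_OUTDATED].append(rec.amplicon_id)
        elif rec.flag_multitarget:
            removed[REASON_MULTITARGET].append(rec.amplicon_id)
        elif rec.flag_positional:
            removed[REASON_POSITIONAL].append(rec.amplicon_id)
        else:
            retained.append(rec)

    report = QcReport(
        n_input=len(manifest),
        n_removed_outdated=len(removed[REASON_OUTDATED]),
        n_removed_multitarget=len(removed[REASON_MULTITARGET]),
        n_removed_positional=len(removed[REASON_POSITIONAL]),
        n_retained=len(retained),
        removed_ids_by_reason=removed,
    )
    return retained, report


def expression_filter(
    gene_ids: Sequence[str],
    expression_table: Mapping[str, float],
    threshold: float = 0.0,
) -> tuple[list[str], dict[str, str]]:
    """Split genes into (kept, dropped-with-reason) by detectable expression.

    Kept genes have expression strictly greater than ``threshold``; genes
    absent from the table are treated as undetectable and dropped with their
    own reason so the omission is visible downstream.
    """
    kept: list[str] = []
    dropped: dict[str, str] = {}
    for g in gene_ids:
        if g not in expression_table:
            dropped[g] = REASON_NOT_IN_TABLE
        elif expression_table[g] > threshold:
            kept.append(g)
        else:
            dropped[g] = REASON_BELOW_THRESHOLD
    return kept, dropped
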