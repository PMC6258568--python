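"""TSV / GMT / YAML readers and writers for all pipeline artifacts.

Every writer round-trips with its reader.  Formats are deliberately plain:
tab-separated tables with headers, GMT for gene sets, YAML for simulation
configs, JSON for reports.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .amplicon_qc import QcReport
from .enrichment import EnrichmentResult, GeneSet
from .hit_calling import GeneCall, gene_calls_to_frame
from .normalization import NormalizedWell
from .quant_pcr import QpcrSample
from .synthetic_data import AmpliconRecord, ScreenSimConfig, WellReadout


# -- library manifest ---------------------------------------------------------

def write_manifest(manifest: Sequence[AmpliconRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "amplicon_id": [r.amplicon_id for r in manifest],
            "plate": [r.plate for r in manifest],
            "well": [r.well for r in manifest],
            "targets": [";".join(r.targets) for r in manifest],
            "flag_outdated": [int(r.flag_outdated) for r in manifest],
            "flag_multitarget": [int(r.flag_multitarget) for r in manifest],
            "flag_positional": [int(r.flag_positional) for r in manifest],
        }
    ).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> list[AmpliconRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"targets": str}, keep_default_na=False)
    return [
        AmpliconRecord(
            amplicon_id=row.amplicon_id,
            plate=int(row.plate),
            well=row.well,
            targets=tuple(t for t in str(row.targets).split(";") if t),
            flag_positional=bool(int(row.flag_positional)),
        )
        for row in df.itertuples()
    ]


# -- well readouts ------------------------------------------------------------

def write_readouts(readouts: Sequence[WellReadout], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in readouts]).to_csv(
        path, sep="\t", index=False
    )


def read_readouts(path: str | Path) -> list[WellReadout]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        WellReadout(
            plate=int(row.plate), well=row.well, replicate=int(row.replicate),
            fish_total_intensity=float(row.fish_total_intensity),
            cell_count=int(row.cell_count), fields_of_view=int(row.fields_of_view),
            control=str(getattr(row, "control", "")),
        )
        for row in df.itertuples()
    ]


# -- normalized wells ---------------------------------------------------------

def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("true", "1")
    return bool(v)


def write_normalized(wells: Sequence[NormalizedWell], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(w) for w in wells]).to_csv(
        path, sep="\t", index=False
    )


def read_normalized(path: str | Path) -> list[NormalizedWell]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    out = []
    for row in df.itertuples():
        out.append(
            NormalizedWell(
                plate=int(row.plate), well=row.well, replicate=int(row.replicate),
                wolbachia_per_cell=float(row.wolbachia_per_cell),
                robust_z_wolbachia=float(row.robust_z_wolbachia),
                proliferation_ratio=float(row.proliferation_ratio),
                robust_z_proliferation=float(row.robust_z_proliferation),
                excluded_from_stats=_as_bool(row.excluded_from_stats),
                failed=_as_bool(row.failed),
                control="" if pd.isna(row.control) else str(row.control),
            )
        )
    return out


# -- gene calls, QC, expression ----------------------------------------------

def write_gene_calls(calls: Sequence[GeneCall], path: str | Path) -> None:
    gene_calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def write_qc_report(report: QcReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(report), indent=2))


def read_expression(path: str | Path) -> dict[str, float]:
    """Two-column gene -> expression TSV (header optional but recommended)."""
    df = pd.read_csv(path, sep="\t")
    gene_col, expr_col = df.columns[:2]
    return dict(zip(df[gene_col].astype(str), df[expr_col].astype(float)))


# -- per-cell counts ----------------------------------------------------------

def write_cell_counts(counts: Iterable[int], path: str | Path) -> None:
    pd.DataFrame({"count": list(counts)}).to_csv(path, sep="\t", index=False)


def read_cell_counts(path: str | Path) -> list[int]:
    return pd.read_csv(path, sep="\t")["count"].astype(int).tolist()


# -- qPCR Cq tables -----------------------------------------------------------

def write_cq_table(samples: Sequence[QpcrSample], path: str | Path) -> None:
    """Long-format Cq table: sample, amplicon role, replicate, Cq."""
    rows = []
    for s in samples:
        for i, cq in enumerate(s.target_cq, 1):
            rows.append((s.sample_id, "target", i, cq, s.efficiency))
        for i, cq in enumerate(s.reference_cq, 1):
            rows.append((s.sample_id, "reference", i, cq, s.efficiency))
    pd.DataFrame(
        rows, columns=["sample", "role", "replicate", "cq", "efficiency"]
    ).to_csv(path, sep="\t", index=False)


def read_cq_table(path: str | Path) -> list[QpcrSample]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for sample_id, grp in df.groupby("sample", sort=True):
        out.append(
            QpcrSample(
                sample_id=str(sample_id),
                target_cq=grp.loc[grp.role == "target", "cq"].tolist(),
                reference_cq=grp.loc[grp.role == "reference", "cq"].tolist(),
                efficiency=float(grp.efficiency.iloc[0]),
            )
        )
    return out


# -- gene sets ----------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    """GMT: set_id <tab> description <tab> member1 <tab> member2 ..."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets.append(GeneSet(set_id=parts[0], name=parts[1], members=tuple(parts[2:])))
    return sets


def read_gene_sets_tsv(path: str | Path) -> list[GeneSet]:
    """Two-column set_id <tab> gene long format."""
    df = pd.read_csv(path, sep="\t")
    id_col, gene_col = df.columns[:2]
    return [
        GeneSet(set_id=str(sid), name=str(sid), members=tuple(grp[gene_col].astype(str)))
        for sid, grp in df.groupby(id_col, sort=True)
    ]


def write_enrichment(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
        path, sep="\t", index=False
    )


# -- simulation config --------------------------------------------------------

def write_config(config: ScreenSimConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    d["amplicons_per_gene"] = {int(k): float(v) for k, v in d["amplicons_per_gene"].items()}
    d["class_mix"] = list(d["class_mix"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def read_config(path: str | Path) -> ScreenSimConfig:
    d = yaml.safe_load(Path(path).read_text())
    d["class_mix"] = tuple(d["class_mix"])
    return ScreenSimConfig(**d)
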