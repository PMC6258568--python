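"""Seeded generators for every input the screen pipeline consumes.

The generators emulate the statistical structure of a genome-wide RNAi
screen read out by *Wolbachia* FISH in 384-well plates: a multi-plate
library manifest with outdated / multi-target / positional (A1) reagent
categories, triplicate well readouts carrying gene effects expressed in
robust-Z units, per-cell bacterial counts with a low/medium/high infection
class mixture, qPCR Cq tables with technical-replicate noise, and per-cell
translation measurements with a target Pearson correlation.

Effect calibration.  Downstream plate normalization standardizes the bulk of
each plate's experimental wells to unit robust spread, so an injected effect
is recovered on its intended scale only if the simulated bulk has unit
spread in effect space.  Genes without an explicit entry in ``effect_map``
therefore carry a persistent per-gene background effect drawn from
N(0, sqrt(1 - noise_sd^2)); genes listed in ``effect_map`` (including genes
pinned to exactly 0) receive precisely their stated effect.  Observed
robust-Z per well-replicate is then  z_true(+background) + eps,
eps ~ N(0, noise_sd), mapped to raw intensities log-linearly.
"""

from __future__ import annotations

import functools
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

PLATE_ROWS = "ABCDEFGHIJKLMNOP"
PLATE_COLS = 24
PLATE_WELLS = [f"{r}{c}" for r in PLATE_ROWS for c in range(1, PLATE_COLS + 1)]

INCREASE_CONTROL = "rpl40"       # ribosomal-gene knockdown raising titer
DECREASE_CONTROL = "doxycycline"  # antibiotic treatment lowering titer
NEUTRAL_CONTROLS = ("rho1", "gfp")

DEFAULT_CONTROL_EFFECTS = {
    INCREASE_CONTROL: 2.2,
    DECREASE_CONTROL: -3.5,
    "rho1": 0.0,
    "gfp": 0.0,
}


def default_control_layout() -> dict[str, str]:
    """Fixed control positions: four wells per control, 16 per plate."""
    layout = {}
    for well in ("A2", "B2", "A12", "B12"):
        layout[well] = INCREASE_CONTROL
    for well in ("A23", "B23", "A13", "B13"):
        layout[well] = DECREASE_CONTROL
    for well in ("P1", "P2", "O1", "O2"):
        layout[well] = "rho1"
    for well in ("P23", "P24", "O23", "O24"):
        layout[well] = "gfp"
    return layout


@dataclass
class AmpliconRecord:
    """One dsRNA library reagent and its QC flags."""

    amplicon_id: str
    plate: int
    well: str
    targets: tuple[str, ...]
    flag_positional: bool = False

    @property
    def flag_outdated(self) -> bool:
        return len(self.targets) == 0

    @property
    def flag_multitarget(self) -> bool:
        return len(self.targets) >= 2


@dataclass
class WellReadout:
    """Raw measurements for one well of one plate-replicate."""

    plate: int
    well: str
    replicate: int
    fish_total_intensity: float
    cell_count: int
    fields_of_view: int
    control: str = ""  # control name, or "" for an experimental well

    def __post_init__(self) -> None:
        if self.fields_of_view < 1:
            raise ValueError("fields_of_view must be >= 1")
        if self.cell_count < 0 or self.fish_total_intensity < 0:
            raise ValueError("readouts must be nonnegative")


@dataclass
class ScreenSimConfig:
    """Study conditions for the simulated screen.

    Proportions are fractions of the whole manifest; effects are in
    robust-Z units (the screen's effect-size scale).  ``n_amplicons``, when
    given, fixes the total manifest size exactly (category counts are then
    round(frac * n_amplicons)); otherwise the size follows from ``n_genes``
    and the amplicons-per-gene distribution.
    """

    n_genes: int = 200
    amplicons_per_gene: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.55, 2: 0.36, 3: 0.07, 4: 0.02}
    )
    frac_outdated: float = 0.06
    frac_multitarget: float = 0.06
    n_plates: int | None = None
    replicates: int = 3
    control_layout: Mapping[str, str] = field(default_factory=default_control_layout)
    effect_map: Mapping[str, float] = field(default_factory=dict)
    control_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_EFFECTS)
    )
    noise_sd: float = 0.3
    proliferation_effect_map: Mapping[str, float] = field(default_factory=dict)
    infected_fraction: float = 0.14
    class_mix: tuple[float, float, float] = (0.73, 0.135, 0.135)
    seed: int = 0
    # manifest sizing / layout extras
    n_amplicons: int | None = None
    # raw-intensity mapping
    baseline_intensity_per_cell: float = 200.0
    log_slope: float = 0.02
    cells_per_fov: float = 450.0
    fields_of_view: int = 4
    # A1 positional artifact (strong negative shift, high variance)
    a1_artifact_z: float = -4.0
    a1_artifact_sd: float = 2.0
    # per-cell count upper bound for the "high" infection class
    count_max: int = 90

    def __post_init__(self) -> None:
        for name in ("frac_outdated", "frac_multitarget", "infected_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if any(p < 0 for p in self.class_mix):
            raise ValueError("class_mix entries must be nonnegative")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if self.n_plates is not None and self.n_plates < 1:
            raise ValueError("n_plates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not math.isclose(sum(self.amplicons_per_gene.values()), 1.0, abs_tol=1e-9):
            raise ValueError("amplicons_per_gene probabilities must sum to 1")
        if any(k not in (1, 2, 3, 4) for k in self.amplicons_per_gene):
            raise ValueError("amplicons_per_gene support is 1..4")

    @property
    def background_effect_sd(self) -> float:
        """Per-gene background spread making plate bulk spread unity."""
        return math.sqrt(max(0.0, 1.0 - self.noise_sd**2))

    @property
    def experimental_wells_per_plate(self) -> int:
        return len(PLATE_WELLS) - len(self.control_layout)


def genome_scale_config(seed: int = 0, **overrides) -> ScreenSimConfig:
    """Conditions of a whole-genome screen: 24,036 amplicons over 66 plates.

    Category fractions reproduce 1,499 zero-target and 1,481 multi-target
    amplicons exactly under round(frac * total); with 16 control wells per
    plate the manifest occupies 66 plates, so exactly 66 amplicons land in
    the A1 artifact position.
    """
    cfg = dict(
        n_genes=15_589,
        n_amplicons=24_036,
        frac_outdated=1_499 / 24_036,
        frac_multitarget=1_481 / 24_036,
        n_plates=66,
        seed=seed,
    )
    cfg.update(overrides)
    return ScreenSimConfig(**cfg)


def generate_library(config: ScreenSimConfig) -> list[AmpliconRecord]:
    """Generate a plate-arrayed amplicon manifest.

    Amplicons fill experimental wells plate by plate in row-major order (A1
    first).  Outdated (zero-target) and multi-target flags are assigned by
    seeded sampling among non-A1 amplicons so the three QC categories are
    disjoint and their counts additive.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i:05d}" for i in range(1, config.n_genes + 1)]

    ks = sorted(config.amplicons_per_gene)
    probs = np.array([config.amplicons_per_gene[k] for k in ks], dtype=float)
    per_gene = rng.choice(ks, size=config.n_genes, p=probs / probs.sum())

    targets: list[tuple[str, ...]] = []
    for g, k in zip(genes, per_gene):
        targets.extend([(g,)] * int(k))

    if config.n_amplicons is not None:
        total = config.n_amplicons
        n_out = round(config.frac_outdated * total)
        n_multi = round(config.frac_multitarget * total)
        n_targeting = total - n_out
        if len(targets) < n_targeting:
            raise ValueError(
                f"n_genes x amplicons_per_gene yields {len(targets)} gene-targeting "
                f"amplicons; {n_targeting} required for n_amplicons={total}"
            )
        targets = targets[:n_targeting]
    else:
        n_targeting = len(targets)
        total = round(n_targeting / (1.0 - config.frac_outdated)) if config.frac_outdated < 1 else n_targeting
        n_out = total - n_targeting
        n_multi = round(config.frac_multitarget * total)

    exp_wells = [w for w in PLATE_WELLS if w not in config.control_layout]
    capacity_per_plate = len(exp_wells)
    n_plates = config.n_plates or math.ceil(total / capacity_per_plate)
    if n_plates * capacity_per_plate < total:
        raise ValueError(
            f"{total} amplicons exceed capacity of {n_plates} plates "
            f"({capacity_per_plate} experimental wells each)"
        )

    # interleave outdated amplicons at seeded non-A1 positions (A1 slots are
    # index multiples of the plate capacity) so the QC categories stay disjoint
    non_a1 = [i for i in range(total) if i % capacity_per_plate != 0]
    if n_out > len(non_a1):
        raise ValueError("frac_outdated too high for the non-A1 amplicon pool")
    out_positions = (
        {non_a1[int(j)] for j in rng.choice(len(non_a1), size=n_out, replace=False)}
        if n_out else set()
    )
    it = iter(targets)
    all_targets = [() if i in out_positions else next(it) for i in range(total)]

    records: list[AmpliconRecord] = []
    for i, tg in enumerate(all_targets):
        plate, slot = divmod(i, capacity_per_plate)
        well = exp_wells[slot]
        records.append(
            AmpliconRecord(
                amplicon_id=f"amp{i + 1:06d}",
                plate=plate + 1,
                well=well,
                targets=tg,
                flag_positional=(well == "A1"),
            )
        )

    # multi-target flags: add one extra target to sampled single-target,
    # non-A1 amplicons
    eligible = [
        i for i, r in enumerate(records)
        if len(r.targets) == 1 and not r.flag_positional
    ]
    if n_multi > len(eligible):
        raise ValueError("frac_multitarget too high for the eligible amplicon pool")
    for i in rng.choice(len(eligible), size=n_multi, replace=False):
        idx = eligible[int(i)]
        primary = records[idx].targets[0]
        extra = genes[int(rng.integers(config.n_genes))]
        while extra == primary:
            extra = genes[int(rng.integers(config.n_genes))]
        records[idx] = replace(records[idx], targets=(primary, extra))
    return records


def _gene_effects(
    genes: Sequence[str], config: ScreenSimConfig, rng: np.random.Generator,
    effect_map: Mapping[str, float],
) -> dict[str, float]:
    """Explicit effects where given, persistent background draws elsewhere."""
    bg = rng.normal(0.0, config.background_effect_sd, size=len(genes))
    effects = {g: float(b) for g, b in zip(sorted(genes), bg)}
    effects.update(effect_map)
    return effects


def generate_screen(
    manifest: Sequence[AmpliconRecord], config: ScreenSimConfig
) -> list[WellReadout]:
    """Simulate raw triplicate well readouts for a manifest.

    Per well-replicate the intended robust-Z score is the amplicon's true
    effect (mean over its targets' effects; 0 for zero-target amplicons)
    plus N(0, noise_sd) replicate noise; control wells carry their designed
    effects and the A1 well an added negative, high-variance artifact.  Raw
    FISH intensity per cell is baseline * exp(log_slope * z); cell counts
    carry the proliferation effect through the same mapping.
    """
    rng = np.random.default_rng(config.seed + 1)
    manifest_genes = sorted({g for r in manifest for g in r.targets})
    for g in config.effect_map:
        if g not in manifest_genes:
            warnings.warn(f"effect_map gene {g!r} absent from manifest; ignored")
    for g in config.proliferation_effect_map:
        if g not in manifest_genes:
            warnings.warn(f"proliferation_effect_map gene {g!r} absent from manifest; ignored")

    wol_eff = _gene_effects(manifest_genes, config, rng, config.effect_map)
    pro_eff = _gene_effects(manifest_genes, config, rng, config.proliferation_effect_map)
    # zero-target reagents retain residual off-target activity: a persistent
    # per-amplicon draw from the background distribution (keeps the plate
    # bulk at unit robust spread)
    orphan_wol = {
        r.amplicon_id: float(rng.normal(0.0, config.background_effect_sd))
        for r in manifest if not r.targets
    }
    orphan_pro = {
        r.amplicon_id: float(rng.normal(0.0, config.background_effect_sd))
        for r in manifest if not r.targets
    }

    def amplicon_truth(
        rec: AmpliconRecord, table: Mapping[str, float], orphan: Mapping[str, float]
    ) -> float:
        if not rec.targets:
            return orphan[rec.amplicon_id]
        # multi-target reagents silence every target; phenotypes add
        return float(np.sum([table[g] for g in rec.targets]))

    n_plates = max((r.plate for r in manifest), default=0)
    by_plate: dict[int, list[AmpliconRecord]] = {}
    for r in manifest:
        by_plate.setdefault(r.plate, []).append(r)

    out: list[WellReadout] = []
    for plate in range(1, n_plates + 1):
        for rep in range(1, config.replicates + 1):
            for rec in by_plate.get(plate, []):
                z_w = amplicon_truth(rec, wol_eff, orphan_wol) + rng.normal(0.0, config.noise_sd)
                z_p = amplicon_truth(rec, pro_eff, orphan_pro) + rng.normal(0.0, config.noise_sd)
                if rec.flag_positional:
                    z_w += config.a1_artifact_z + rng.normal(0.0, config.a1_artifact_sd)
                out.append(_make_readout(plate, rec.well, rep, z_w, z_p, config))
            for well, name in sorted(config.control_layout.items()):
                eff = config.control_effects.get(name, 0.0)
                z_w = eff + rng.normal(0.0, config.noise_sd)
                z_p = rng.normal(0.0, config.noise_sd)
                out.append(_make_readout(plate, well, rep, z_w, z_p, config, control=name))
    return out


def _make_readout(
    plate: int, well: str, rep: int, z_wol: float, z_pro: float,
    config: ScreenSimConfig, control: str = "",
) -> WellReadout:
    cells = int(round(
        config.cells_per_fov * config.fields_of_view * math.exp(config.log_slope * z_pro)
    ))
    cells = max(cells, 1)
    per_cell = config.baseline_intensity_per_cell * math.exp(config.log_slope * z_wol)
    return WellReadout(
        plate=plate, well=well, replicate=rep,
        fish_total_intensity=per_cell * cells,
        cell_count=cells, fields_of_view=config.fields_of_view,
        control=control,
    )


def generate_cell_counts(
    n_cells: int,
    infected_fraction: float = 0.14,
    class_mix: tuple[float, float, float] = (0.73, 0.135, 0.135),
    seed: int = 0,
    count_max: int = 90,
) -> np.ndarray:
    """Per-cell bacterial counts: 0 with prob 1-infected_fraction, else a
    uniform draw within the low (1-10), medium (11-30) or high (31-count_max)
    class range chosen by ``class_mix``."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not 0.0 <= infected_fraction <= 1.0:
        raise ValueError("infected_fraction must be in [0, 1]")
    if abs(sum(class_mix) - 1.0) > 1e-9:
        raise ValueError("class_mix must sum to 1")
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_cells, dtype=int)
    infected = rng.random(n_cells) < infected_fraction
    n_inf = int(infected.sum())
    if n_inf:
        cls = rng.choice(3, size=n_inf, p=np.asarray(class_mix) / sum(class_mix))
        lo = np.array([1, 11, 31])[cls]
        hi = np.array([10, 30, count_max])[cls]
        counts[infected] = rng.integers(lo, hi + 1)
    return counts


def generate_qpcr(
    true_ratio: float,
    cq_ref_mean: float = 20.0,
    noise_sd: float = 0.1,
    n_tech: int = 3,
    efficiency: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired technical-replicate Cq lists (target, reference) such that
    E[Cq_ref - Cq_target] = log_efficiency(true_ratio)."""
    if true_ratio <= 0:
        raise ValueError("true_ratio must be positive")
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("efficiency must be in (1, 2]")
    if n_tech < 1:
        raise ValueError("n_tech must be >= 1")
    rng = np.random.default_rng(seed)
    delta = math.log(true_ratio) / math.log(efficiency)
    target = cq_ref_mean - delta + rng.normal(0.0, noise_sd, size=n_tech)
    ref = cq_ref_mean + rng.normal(0.0, noise_sd, size=n_tech)
    return target, ref


_COUNT_MEAN = 12.0
_COUNT_SD = 9.0
_LEVEL_MEAN = 100.0
_LEVEL_SD = 15.0


def _count_transform(g: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(_COUNT_MEAN + _COUNT_SD * g), 0, None)


@functools.cache
def _count_attenuation() -> float:
    """Corr(G, count(G)) for standard normal G, by deterministic quadrature."""
    q = (np.arange(20001) + 0.5) / 20001
    from scipy.stats import norm

    g = norm.ppf(q)
    c = _count_transform(g)
    return float(np.corrcoef(g, c)[0, 1])


def generate_translation_cells(
    n_cells: int, target_correlation: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Paired per-cell (bacterial count, translation level, cell area).

    Counts are a floored/discretized Gaussian (≈9% of cells uninfected);
    translation level is Gaussian and linear in the latent variable, so the
    latent correlation is inflated by the count transform's attenuation
    factor to make the sample Pearson r of (level, count) converge to
    ``target_correlation``.  For |target| = 1 an exact affine monotone
    coupling is used.
    """
    if not -1.0 <= target_correlation <= 1.0:
        raise ValueError("target_correlation must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    area = np.exp(rng.normal(math.log(300.0), 0.25, size=n_cells))
    if abs(target_correlation) == 1.0:
        counts = _count_transform(rng.normal(size=n_cells))
        level = _LEVEL_MEAN + target_correlation * (counts - _COUNT_MEAN) * (
            _LEVEL_SD / _COUNT_SD
        )
        return counts.astype(int), level, area
    lam = _count_attenuation()
    rho = float(np.clip(target_correlation / lam, -1.0, 1.0))
    g1 = rng.normal(size=n_cells)
    g2 = rho * g1 + math.sqrt(1.0 - rho**2) * rng.normal(size=n_cells)
    level = _LEVEL_MEAN + _LEVEL_SD * g1
    counts = _count_transform(g2)
    return counts.astype(int), level, area
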