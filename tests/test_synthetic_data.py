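"""Seeded generators: determinism, category arithmetic, recovery."""

import math

import numpy as np
import pytest

from titerscreen.normalization import normalize_screen
from titerscreen.synthetic_data import (
    PLATE_WELLS,
    ScreenSimConfig,
    default_control_layout,
    generate_cell_counts,
    generate_library,
    generate_qpcr,
    generate_screen,
    generate_translation_cells,
    genome_scale_config,
)


class TestConfigValidation:
    def test_bad_proportion_rejected(self):
        with pytest.raises(ValueError):
            ScreenSimConfig(frac_outdated=1.5)

    def test_class_mix_must_sum_to_one(self):
        with pytest.raises(ValueError):
            ScreenSimConfig(class_mix=(0.5, 0.3, 0.3))

    def test_replicate_minimum(self):
        with pytest.raises(ValueError):
            ScreenSimConfig(replicates=1)


class TestGenerateLibrary:
    def test_seeded_determinism_byte_identical(self, tmp_path):
        from titerscreen.io import write_manifest

        cfg = ScreenSimConfig(n_genes=80, seed=42)
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_manifest(generate_library(cfg), a)
        write_manifest(generate_library(cfg), b)
        assert a.read_bytes() == b.read_bytes()

    def test_no_flags_when_fractions_zero(self):
        cfg = ScreenSimConfig(n_genes=60, frac_outdated=0.0, frac_multitarget=0.0, seed=1)
        manifest = generate_library(cfg)
        assert not any(r.flag_outdated or r.flag_multitarget for r in manifest)

    def test_category_proportions_match_config(self):
        cfg = ScreenSimConfig(
            n_genes=2000, frac_outdated=0.1, frac_multitarget=0.05, seed=2
        )
        manifest = generate_library(cfg)
        n = len(manifest)
        assert sum(r.flag_outdated for r in manifest) == round(0.1 * n)
        assert sum(r.flag_multitarget for r in manifest) == round(0.05 * n)

    def test_genome_scale_reproduces_printed_category_counts(self):
        manifest = generate_library(genome_scale_config(seed=0))
        assert len(manifest) == 24_036
        assert sum(r.flag_outdated for r in manifest) == 1_499
        assert sum(r.flag_multitarget for r in manifest) == 1_481
        assert sum(r.flag_positional for r in manifest) == 66
        # categories are disjoint by construction
        assert not any(
            r.flag_positional and (r.flag_outdated or r.flag_multitarget)
            for r in manifest
        )

    def test_positions_unique_and_valid(self):
        cfg = ScreenSimConfig(n_genes=300, seed=3)
        manifest = generate_library(cfg)
        positions = [(r.plate, r.well) for r in manifest]
        assert len(set(positions)) == len(positions)
        controls = set(default_control_layout())
        assert all(r.well in PLATE_WELLS and r.well not in controls for r in manifest)


class TestGenerateScreen:
    def test_deterministic_given_seed(self, small_config, small_screen):
        manifest, readouts, _ = small_screen
        again = generate_screen(manifest, small_config)
        assert again == readouts

    def test_unknown_effect_gene_warns(self, small_config, small_screen):
        manifest, _, _ = small_screen
        cfg = ScreenSimConfig(
            n_genes=small_config.n_genes, amplicons_per_gene={1: 1.0},
            effect_map={"not_a_gene": 3.0}, seed=11,
        )
        with pytest.warns(UserWarning, match="not_a_gene"):
            generate_screen(manifest, cfg)

    def test_single_gene_effect_recovered_across_seeds(self):
        # z_true = +3, noise 0.3: downstream robust Z within 3 +/- 1 in >=95%
        # of replicate measurements, Monte-Carlo over 1000 seeded screens
        hits = total = 0
        for seed in range(1000):
            cfg = ScreenSimConfig(
                n_genes=150, amplicons_per_gene={1: 1.0},
                frac_outdated=0.0, frac_multitarget=0.0,
                effect_map={"g00077": 3.0}, seed=seed,
            )
            manifest = generate_library(cfg)
            target_pos = {
                (r.plate, r.well) for r in manifest if r.targets == ("g00077",)
            }
            readouts = generate_screen(manifest, cfg)
            normalized = normalize_screen(
                readouts, control_wells=list(default_control_layout())
            )
            for w in normalized:
                if (w.plate, w.well) in target_pos:
                    total += 1
                    hits += 2.0 <= w.robust_z_wolbachia <= 4.0
        assert total == 3000
        assert hits / total >= 0.95


class TestGenerateCellCounts:
    def test_infected_fraction_zero_means_all_zero(self):
        assert not generate_cell_counts(500, infected_fraction=0.0, seed=0).any()

    def test_degenerate_mix_confined_to_low_range(self):
        counts = generate_cell_counts(2000, class_mix=(1.0, 0.0, 0.0), seed=1)
        infected = counts[counts > 0]
        assert infected.size and infected.min() >= 1 and infected.max() <= 10

    def test_mixture_recovered_at_large_n(self):
        counts = generate_cell_counts(100_000, seed=2)
        infected = counts[counts > 0]
        assert infected.size / counts.size == pytest.approx(0.14, abs=0.01)
        low = ((infected >= 1) & (infected <= 10)).sum() / infected.size
        med = ((infected >= 11) & (infected <= 30)).sum() / infected.size
        high = (infected >= 31).sum() / infected.size
        assert low == pytest.approx(0.73, abs=0.01)
        assert med == pytest.approx(0.135, abs=0.01)
        assert high == pytest.approx(0.135, abs=0.01)

    def test_bad_mix_rejected(self):
        with pytest.raises(ValueError):
            generate_cell_counts(10, class_mix=(0.6, 0.3, 0.3))


class TestGenerateQpcr:
    def test_noiseless_equal_ratio_gives_equal_cq(self):
        target, ref = generate_qpcr(1.0, noise_sd=0.0, seed=0)
        assert np.allclose(target, ref)

    def test_noiseless_fourfold_is_two_cycles(self):
        target, ref = generate_qpcr(4.0, noise_sd=0.0, efficiency=2.0, seed=0)
        assert np.mean(ref) - np.mean(target) == pytest.approx(2.0)

    def test_ratio_recovery_over_seeds(self):
        # the increase-control's 3.4-fold effect, recovered within 5%
        recovered = []
        for seed in range(500):
            target, ref = generate_qpcr(3.4, noise_sd=0.1, n_tech=3, seed=seed)
            recovered.append(2.0 ** (np.mean(ref) - np.mean(target)))
        assert np.mean(recovered) == pytest.approx(3.4, rel=0.05)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_qpcr(0.0)
        with pytest.raises(ValueError):
            generate_qpcr(2.0, efficiency=2.5)
        with pytest.raises(ValueError):
            generate_qpcr(2.0, n_tech=0)


class TestGenerateTranslationCells:
    def test_zero_target_gives_near_zero_r(self):
        counts, level, _ = generate_translation_cells(10_000, 0.0, seed=0)
        r = np.corrcoef(level, counts)[0, 1]
        assert abs(r) < 0.05

    def test_perfect_correlation_is_exactly_monotone(self):
        counts, level, _ = generate_translation_cells(500, 1.0, seed=1)
        order = np.argsort(level)
        assert (np.diff(counts[order]) >= 0).all()
        assert np.corrcoef(level, counts)[0, 1] == pytest.approx(1.0)

    def test_reported_negative_correlation_recovered(self):
        # target r = -0.1344 at n = 653 cells: mean sample r within 0.01
        rs = [
            np.corrcoef(lv, ct)[0, 1]
            for ct, lv, _ in (
                generate_translation_cells(653, -0.1344, seed=s) for s in range(1000)
            )
        ]
        assert np.mean(rs) == pytest.approx(-0.1344, abs=0.01)

    def test_counts_nonnegative_area_positive(self):
        counts, _, area = generate_translation_cells(2000, -0.5, seed=3)
        assert counts.min() >= 0 and (area > 0).all()
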