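"""Plate robust-Z normalization: formula, invariances, plate handling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_unit_spread_scores
from titerscreen.normalization import (
    DegeneratePlateError,
    FailedWellError,
    InsufficientWellsError,
    normalize_plate,
    normalize_screen,
    proliferation_ratio,
    robust_center_scale,
    robust_z,
    robust_z_scores,
    wolbachia_per_cell,
)
from titerscreen.synthetic_data import PLATE_WELLS, WellReadout


class TestPerWellRatios:
    @pytest.mark.parametrize(
        "intensity,cells,expected", [(1000, 100, 10.0), (0, 50, 0.0), (137.5, 11, 12.5)]
    )
    def test_wolbachia_per_cell(self, intensity, cells, expected):
        assert wolbachia_per_cell(intensity, cells) == pytest.approx(expected)

    def test_zero_nuclei_is_a_signaled_failure(self):
        with pytest.raises(FailedWellError):
            wolbachia_per_cell(100.0, 0)

    @pytest.mark.parametrize(
        "cells,fov,expected", [(1500, 3, 500.0), (0, 5, 0.0), (1500, 4, 375.0)]
    )
    def test_proliferation_ratio(self, cells, fov, expected):
        assert proliferation_ratio(cells, fov) == pytest.approx(expected)

    def test_zero_fields_of_view_rejected(self):
        with pytest.raises(ValueError):
            proliferation_ratio(100, 0)


class TestRobustZ:
    def test_median_scores_zero(self):
        values = [3.0, 1.0, 7.0, 5.0, 9.0]
        assert robust_z(values, float(np.median(values))) == 0.0

    def test_one_to_nine_example(self):
        # median 5, MAD 2 -> (8-5)/(1.4826*2)
        assert robust_z(list(range(1, 10)), 8.0) == pytest.approx(1.0118, abs=1e-4)

    def test_agrees_with_sort_based_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            v = rng.normal(size=rng.integers(9, 40))
            x = float(rng.normal())
            sv = np.sort(v)
            med = (sv[(len(sv) - 1) // 2] + sv[len(sv) // 2]) / 2
            dev = np.sort(np.abs(v - med))
            mad = (dev[(len(dev) - 1) // 2] + dev[len(dev) // 2]) / 2
            assert robust_z(v, x) == pytest.approx((x - med) / (1.4826 * mad))

    @settings(derandomize=True, max_examples=50)
    @given(
        values=st.lists(
            st.floats(-50, 50), min_size=9, max_size=30, unique=True
        ),
        x=st.floats(-50, 50),
        shift=st.floats(-100, 100),
        scale=st.floats(0.01, 100),
    )
    def test_affine_invariance(self, values, x, shift, scale):
        z0 = robust_z(values, x)
        z1 = robust_z([scale * v + shift for v in values], scale * x + shift)
        assert z1 == pytest.approx(z0, rel=1e-6, abs=1e-6)

    def test_degenerate_spread_raises(self):
        with pytest.raises(DegeneratePlateError):
            robust_z([2.0] * 10, 5.0)

    def test_vectorized_matches_scalar(self):
        v = [1.0, 4.0, 2.0, 8.0, 5.0, 7.0, 3.0, 9.0, 6.0]
        xs = [0.0, 5.0, 10.0]
        assert robust_z_scores(v, xs) == pytest.approx([robust_z(v, x) for x in xs])


def _plate_from_scores(scores, wells=None, plate=1, rep=1, base=100.0, slope=7.0):
    """Raw readouts whose Wolbachia ratio is an affine image of ``scores``."""
    wells = wells or [w for w in PLATE_WELLS if w != "A1"][: len(scores)]
    out = []
    for i, (w, z) in enumerate(zip(wells, scores)):
        cells = 100 + i  # distinct, so the proliferation margin is nondegenerate
        ratio = base + slope * z
        out.append(
            WellReadout(
                plate=plate, well=w, replicate=rep,
                fish_total_intensity=ratio * cells, cell_count=cells,
                fields_of_view=1,
            )
        )
    return out


class TestNormalizePlate:
    def test_injected_effect_recovered_exactly(self):
        # score multiset constructed with median 0 and unit robust scale,
        # so the +3 / -3 wells must come back as exactly +/-3
        scores = make_unit_spread_scores(extra=(3.0, -3.0))
        readouts = _plate_from_scores(scores)
        normalized = normalize_plate(readouts)
        by_well = {w.well: w for w in normalized}
        for r, z in zip(readouts, scores):
            assert by_well[r.well].robust_z_wolbachia == pytest.approx(z, abs=1e-6)

    def test_all_equal_plate_is_degenerate(self):
        readouts = _plate_from_scores([0.0] * 12, slope=0.0)
        with pytest.raises(DegeneratePlateError):
            normalize_plate(readouts)

    def test_too_few_wells_rejected(self):
        readouts = _plate_from_scores([0.0, 1.0, -1.0, 0.5])
        with pytest.raises(InsufficientWellsError):
            normalize_plate(readouts)

    def test_controls_scored_but_excluded_from_reference(self):
        scores = make_unit_spread_scores(extra=())
        wells = [w for w in PLATE_WELLS if w not in ("A1", "A2")][: len(scores)]
        readouts = _plate_from_scores(scores, wells=wells)
        # a strong control well must not move the experimental reference
        control = _plate_from_scores([8.0], wells=["A2"])
        normalized = normalize_plate(readouts + control, control_wells={"A2"})
        by_well = {w.well: w for w in normalized}
        assert by_well["A2"].excluded_from_stats
        assert by_well["A2"].robust_z_wolbachia == pytest.approx(8.0, abs=1e-6)
        for r, z in zip(readouts, scores):
            assert by_well[r.well].robust_z_wolbachia == pytest.approx(z, abs=1e-6)

    def test_failed_well_propagates_as_missing(self):
        scores = make_unit_spread_scores(extra=())
        readouts = _plate_from_scores(scores)
        readouts.append(
            WellReadout(plate=1, well="P24", replicate=1,
                        fish_total_intensity=0.0, cell_count=0, fields_of_view=1)
        )
        normalized = normalize_plate(readouts)
        failed = [w for w in normalized if w.failed]
        assert len(failed) == 1 and failed[0].well == "P24"
        assert math.isnan(failed[0].robust_z_wolbachia)


class TestScreenInvariants:
    def test_per_plate_median_zero_and_unit_scale(self, small_screen):
        _, _, normalized = small_screen
        reps = {(w.plate, w.replicate) for w in normalized}
        for plate, rep in reps:
            z = np.array([
                w.robust_z_wolbachia for w in normalized
                if w.plate == plate and w.replicate == rep
                and not w.excluded_from_stats and not w.failed
            ])
            assert abs(np.median(z)) < 1e-9
            assert abs(1.4826 * np.median(np.abs(z - np.median(z))) - 1.0) < 1e-9
            zp = np.array([
                w.robust_z_proliferation for w in normalized
                if w.plate == plate and w.replicate == rep
                and not w.excluded_from_stats and not w.failed
            ])
            assert abs(np.median(zp)) < 1e-9

    def test_increase_control_recovers_designed_effect(self):
        # ten-plate simulated screen: increase-control median within 0.3 of 2.2
        from titerscreen.synthetic_data import (
            ScreenSimConfig, default_control_layout, generate_library, generate_screen,
        )

        cfg = ScreenSimConfig(n_genes=2800, amplicons_per_gene={1: 1.0},
                              n_plates=10, seed=5)
        manifest = generate_library(cfg)
        readouts = generate_screen(manifest, cfg)
        normalized = normalize_screen(readouts, control_wells=list(default_control_layout()))
        med = np.median([w.robust_z_wolbachia for w in normalized if w.control == "rpl40"])
        assert med == pytest.approx(2.2, abs=0.3)

    def test_a1_artifact_is_low_and_noisy(self, small_screen):
        _, _, normalized = small_screen
        a1 = [w.robust_z_wolbachia for w in normalized if w.well == "A1"]
        others = [w.robust_z_wolbachia for w in normalized
                  if not w.excluded_from_stats and not w.failed]
        assert np.median(a1) < -2.0
        assert np.std(a1) > np.std(others)
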