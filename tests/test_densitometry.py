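"""Gel densitometry: ladder calibration, band detection, isoform arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hcsplice as h
from hcsplice.densitometry import (
    Band,
    DEFAULT_LADDER_SIZES,
    REPORTER_AMPLICONS,
    bands_table,
    default_ladder,
)


@pytest.fixture(scope="module")
def cal() -> h.LadderCalibration:
    return default_ladder()


class TestCalibrateLadder:
    def test_exact_log_linear_law_is_interpolated_exactly(self):
        sizes = np.array([100.0, 300.0, 650.0, 1000.0])
        positions = -400.0 * np.log10(sizes) + 1400.0
        cal = h.calibrate_ladder(np.sort(positions), sizes[np.argsort(positions)])
        for p, s in zip(positions, sizes):
            assert cal.predict_size(p) == pytest.approx(s, rel=1e-9)
        assert cal.slope < 0

    def test_too_few_rungs_rejected(self):
        with pytest.raises(h.CalibrationError):
            h.calibrate_ladder([10.0, 20.0], [1000.0, 500.0])

    def test_non_monotone_positions_rejected(self):
        with pytest.raises(h.CalibrationError):
            h.calibrate_ladder([10.0, 30.0, 20.0], [1000.0, 500.0, 300.0])

    def test_held_out_rung_predicted_within_5_percent(self):
        rng = np.random.default_rng(0)
        sizes = np.array([100.0, 200.0, 400.0, 650.0, 1000.0])
        positions = -400.0 * np.log10(sizes) + 1400.0 + rng.normal(0, 1.5, sizes.size)
        positions = np.sort(positions)[::-1]  # larger sizes migrate less
        for hold in range(sizes.size):
            keep = np.arange(sizes.size) != hold
            cal = h.calibrate_ladder(positions[keep][::-1], sizes[keep][::-1])
            predicted = cal.predict_size(positions[hold])
            assert predicted == pytest.approx(sizes[hold], rel=0.05)


class TestDetectBands:
    def test_flat_profile_has_no_bands(self):
        profile = h.LaneProfile("flat", np.arange(300.0), np.full(300, 20.0))
        assert h.detect_bands(profile) == []

    def test_single_gaussian_area_recovered(self):
        x = np.arange(400.0)
        area, sigma, center = 5000.0, 5.0, 200.0
        y = 30.0 + area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((x - center) / sigma) ** 2)
        bands = h.detect_bands(h.LaneProfile("g", x, y))
        assert len(bands) == 1
        assert bands[0].center == pytest.approx(center, abs=1.0)
        assert bands[0].area == pytest.approx(area, rel=0.05)

    def test_two_separated_gaussians(self):
        x = np.arange(500.0)
        y = np.full(500, 10.0)
        for c in (150.0, 350.0):
            y = y + 3000.0 / (4.0 * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((x - c) / 4.0) ** 2)
        bands = h.detect_bands(h.LaneProfile("two", x, y))
        assert len(bands) == 2
        assert bands[0].center == pytest.approx(150.0, abs=1.0)
        assert bands[1].center == pytest.approx(350.0, abs=1.0)

    def test_window_larger_than_profile_rejected(self):
        profile = h.LaneProfile("short", np.arange(30.0), np.full(30, 5.0))
        with pytest.raises(h.ConfigError):
            h.detect_bands(profile, baseline_window=40)


class TestAssignBands:
    def _bands_at(self, cal, sizes):
        return [Band(center=cal.predict_position(s), area=100.0) for s in sizes]

    def test_assignment_to_reporter_amplicons(self, cal):
        bands = h.assign_bands(self._bands_at(cal, [298.0, 209.0, 655.0]), cal)
        names = {b.assignment for b in bands}
        assert names == {"E10plus", "E10minus", "actin"}

    def test_missing_actin_raises(self, cal):
        with pytest.raises(h.BandAssignmentError, match="actin"):
            h.assign_bands(self._bands_at(cal, [300.0, 207.0]), cal)

    def test_far_off_band_stays_unassigned(self, cal):
        bands = h.assign_bands(self._bands_at(cal, [300.0, 207.0, 650.0, 500.0]), cal)
        assert sum(b.assignment == "unassigned" for b in bands) == 1

    def test_competing_bands_raise_listing_candidates(self, cal):
        with pytest.raises(h.BandAssignmentError, match="compete"):
            h.assign_bands(self._bands_at(cal, [295.0, 305.0, 650.0]), cal)

    def test_endogenous_primer_set(self, cal):
        bands = h.assign_bands(
            self._bands_at(cal, [368.0, 275.0, 650.0]), cal, h.ENDOGENOUS_AMPLICONS
        )
        assert {b.assignment for b in bands} == {"E10plus", "E10minus", "actin"}


def quant(e10p, e10m, actin=2.0, lane="L"):
    bands = [
        Band(0, e10p, assignment="E10plus"),
        Band(0, e10m, assignment="E10minus"),
        Band(0, actin, assignment="actin"),
    ]
    return h.isoform_percent(bands, lane_id=lane)


class TestIsoformPercent:
    def test_equal_areas_give_fifty_percent(self):
        assert quant(3.0, 3.0).pct_e10plus == pytest.approx(50.0)

    def test_zero_inclusion(self):
        assert quant(0.0, 3.0).pct_e10plus == pytest.approx(0.0)

    def test_85_15_split(self):
        assert quant(8.5, 1.5).pct_e10plus == pytest.approx(85.0)

    def test_zero_actin_raises(self):
        with pytest.raises(h.DataError):
            quant(1.0, 1.0, actin=0.0)

    def test_missing_band_raises(self):
        with pytest.raises(h.DataError, match="actin"):
            h.isoform_percent([Band(0, 1.0, assignment="E10plus"),
                               Band(0, 1.0, assignment="E10minus")])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(scale=st.floats(0.01, 1e3), p=st.floats(0.1, 10), m=st.floats(0.1, 10))
    def test_within_lane_percent_invariant_to_lane_scaling(self, scale, p, m):
        base = quant(p, m, actin=2.0).pct_e10plus
        scaled = quant(p * scale, m * scale, actin=2.0 * scale).pct_e10plus
        assert scaled == pytest.approx(base, rel=1e-9)
        assert 0.0 <= base <= 100.0


class TestFoldChange:
    def test_identity(self):
        q = quant(2.0, 1.0)
        assert h.fold_change(q, q) == pytest.approx(1.0)

    def test_mutant_vs_wt_inclusion_levels(self):
        # actin-normalised E10+ levels 0.85 vs 0.35 -> ~2.43-fold increase
        mut = quant(0.85, 0.15, actin=1.0)
        wt = quant(0.35, 0.65, actin=1.0)
        assert h.fold_change(mut, wt) == pytest.approx(0.85 / 0.35, rel=1e-9)
        assert h.fold_change(mut, wt) == pytest.approx(2.43, abs=0.01)

    def test_normalization_invariance(self):
        a, b = quant(3.0, 1.0, actin=2.0), quant(1.0, 1.0, actin=2.0)
        a2, b2 = quant(6.0, 2.0, actin=4.0), quant(2.0, 2.0, actin=4.0)
        assert h.fold_change(a2, b2) == pytest.approx(h.fold_change(a, b))

    def test_reciprocal_product_is_one(self):
        a, b = quant(3.0, 1.0), quant(1.5, 2.0)
        assert h.fold_change(a, b) * h.fold_change(b, a) == pytest.approx(1.0)

    def test_zero_reference_raises(self):
        with pytest.raises(h.DataError):
            h.fold_change(quant(1.0, 1.0), quant(0.0, 1.0))


class TestSynthGel:
    def test_empty_spec_gives_baseline_only(self, cal):
        profile = h.synth_gel([], cal, noise_sd=0.0, seed=0)
        assert h.detect_bands(profile) == []

    def test_same_seed_is_identical(self, cal):
        a = h.synth_gel([(300.0, 4000.0)], cal, seed=5)
        b = h.synth_gel([(300.0, 4000.0)], cal, seed=5)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_out_of_range_size_rejected(self, cal):
        with pytest.raises(h.ConfigError):
            h.synth_gel([(5000.0, 100.0)], cal)

    def test_round_trip_recovers_areas_within_5_percent(self, cal):
        spec = [(300.0, 6000.0), (207.0, 2500.0), (650.0, 4000.0)]
        profile = h.synth_gel(spec, cal, noise_sd=1.0, seed=3)
        bands = h.assign_bands(h.detect_bands(profile), cal)
        by_name = {b.assignment: b for b in bands}
        assert by_name["E10plus"].area == pytest.approx(6000.0, rel=0.05)
        assert by_name["E10minus"].area == pytest.approx(2500.0, rel=0.05)
        assert by_name["actin"].area == pytest.approx(4000.0, rel=0.05)

    def test_round_trip_isoform_percent_within_2_points(self, cal):
        for pct in (20.0, 50.0, 85.0):
            total = 8000.0
            spec = [(300.0, total * pct / 100), (207.0, total * (1 - pct / 100)),
                    (650.0, 5000.0)]
            profile = h.synth_gel(spec, cal, noise_sd=1.0, seed=int(pct))
            q = h.isoform_percent(h.assign_bands(h.detect_bands(profile), cal))
            assert q.pct_e10plus == pytest.approx(pct, abs=2.0)

    def test_bands_table_shape(self, cal):
        profile = h.synth_gel([(300.0, 4000.0), (650.0, 3000.0)], cal, seed=1)
        table = bands_table(h.detect_bands(profile))
        assert list(table.columns) == ["center", "area", "size_bp", "assignment"]
        assert len(table) == 2
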