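"""Synthetic plate generator: determinism, signal model, ground-truth contracts."""

import numpy as np
import pandas as pd
import pytest

import hcsplice as h
from hcsplice.synth import TRUTH_COLUMNS


def _spec(**kw):
    defaults = dict(name="c", cells_per_field=30)
    defaults.update(kw)
    return h.ConditionSpec(**defaults)


class TestSampleConditionCells:
    def test_zero_cells_gives_empty_table(self, small_optics):
        df = h.sample_condition_cells(_spec(cells_per_field=0), 2, small_optics, seed=0)
        assert len(df) == 0
        assert tuple(df.columns) == TRUTH_COLUMNS

    def test_zero_transfection_rate_flags_all_false(self, small_optics):
        df = h.sample_condition_cells(_spec(transfection_rate=0.0), 2, small_optics, seed=1)
        assert not df["transfected"].any()

    def test_same_seed_is_byte_identical(self, small_optics):
        a = h.sample_condition_cells(_spec(), 3, small_optics, seed=5)
        b = h.sample_condition_cells(_spec(), 3, small_optics, seed=5)
        pd.testing.assert_frame_equal(a, b)
        assert a.to_csv() == b.to_csv()

    def test_nuclei_do_not_overlap(self, small_optics):
        df = h.sample_condition_cells(_spec(cells_per_field=60), 1, small_optics, seed=2)
        pts = df[["y", "x"]].to_numpy()
        rad = df["nucleus_radius"].to_numpy()
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert (d >= rad[:, None] + rad[None, :]).all()

    def test_truth_invariants(self, small_optics):
        df = h.sample_condition_cells(_spec(inclusion_mean=0.7), 2, small_optics, seed=3)
        assert ((df["psi"] >= 0) & (df["psi"] <= 1)).all()
        assert (df["cell_radius"] >= df["nucleus_radius"]).all()
        assert (df["expression"] > 0).all()

    @pytest.mark.parametrize("mean,value", [(0.0, 0.0), (1.0, 1.0)])
    def test_degenerate_inclusion_mean(self, small_optics, mean, value):
        df = h.sample_condition_cells(_spec(inclusion_mean=mean), 1, small_optics, seed=4)
        assert (df["psi"] == value).all()

    def test_overcrowded_field_raises_placement_error(self):
        tiny = h.OpticsSpec(field_shape=(64, 64))
        with pytest.raises(h.PlacementError):
            h.sample_condition_cells(_spec(cells_per_field=200), 1, tiny, seed=0)

    def test_invalid_spec_rejected(self):
        with pytest.raises(h.ConfigError):
            h.ConditionSpec(name="bad", transfection_rate=1.5)
        with pytest.raises(h.ConfigError):
            h.ConditionSpec(name="bad", inclusion_concentration=0.0)


class TestRenderField:
    def test_empty_table_mean_matches_background(self):
        optics = h.OpticsSpec(field_shape=(120, 120), background_gradient_amplitude=0.0)
        img = h.render_field(pd.DataFrame(columns=list(TRUTH_COLUMNS)), optics, seed=0)
        n = img.gfp.size
        for ch in h.CHANNELS:
            level = optics.background_level[ch]
            assert abs(img.channel(ch).mean() - level) <= 3 * optics.noise_sd / np.sqrt(n) + 0.5

    def test_full_inclusion_puts_signal_only_in_rfp(self, flat_optics):
        cells = pd.DataFrame(
            [[0, 0, 100.0, 100.0, 5.0, 9.0, True, 1.0, 800.0]], columns=list(TRUTH_COLUMNS)
        )
        img = h.render_field(cells, flat_optics, seed=0)
        bg_g = flat_optics.background_level["gfp"]
        af_g = flat_optics.autofluorescence["gfp"]
        assert img.gfp.max() <= bg_g + af_g + 1  # no reporter leak into GFP
        assert img.rfp.max() > flat_optics.background_level["rfp"] + 500

    def test_reporter_signal_conserved_across_psi(self, flat_optics):
        """GFP + RFP reporter signal equals expression regardless of the split."""
        for psi in (0.0, 0.3, 0.8, 1.0):
            cells = pd.DataFrame(
                [[0, 0, 100.0, 100.0, 5.0, 9.0, True, psi, 600.0]],
                columns=list(TRUTH_COLUMNS),
            )
            img = h.render_field(cells, flat_optics, seed=0)
            cy, cx = 100, 100
            g = float(img.gfp[cy, cx]) - flat_optics.background_level["gfp"] - flat_optics.autofluorescence["gfp"]
            r = float(img.rfp[cy, cx]) - flat_optics.background_level["rfp"] - flat_optics.autofluorescence["rfp"]
            assert g + r == pytest.approx(600.0, abs=2.0)

    def test_noise_free_truth_centroids_match_segmentation(self, flat_optics):
        spec = _spec(cells_per_field=30)
        truth = h.sample_condition_cells(spec, 1, flat_optics, seed=9)
        img = h.render_field(truth, flat_optics, seed=9)
        mask = h.find_nuclei(img.hoechst)
        assert mask.n_objects == len(truth)
        det = mask.table[["centroid_y", "centroid_x"]].to_numpy()
        tru = truth[["y", "x"]].to_numpy()
        d = np.linalg.norm(tru[:, None] - det[None, :], axis=2).min(axis=1)
        assert (d <= 1.0).all()

    def test_cells_outside_field_rejected(self, flat_optics):
        cells = pd.DataFrame(
            [[0, 0, 199.0, 199.0, 5.0, 9.0, True, 0.5, 100.0]], columns=list(TRUTH_COLUMNS)
        )
        with pytest.raises(h.ConfigError):
            h.render_field(cells, flat_optics, seed=0)


class TestSignalMonotonicity:
    def test_truth_rfp_signal_increases_with_inclusion_mean(self, small_optics):
        means = [0.2, 0.5, 0.8]
        rfp_means, gfp_means = [], []
        for m in means:
            df = h.sample_condition_cells(
                _spec(inclusion_mean=m, transfection_rate=1.0, cells_per_field=200),
                1,
                h.OpticsSpec(field_shape=(600, 600)),
                seed=11,
            )
            rfp_means.append((df["expression"] * df["psi"]).mean())
            gfp_means.append((df["expression"] * (1 - df["psi"])).mean())
        assert rfp_means[0] < rfp_means[1] < rfp_means[2]
        assert gfp_means[0] > gfp_means[1] > gfp_means[2]


class TestGeneratePlate:
    def test_field_count_and_truth_conservation(self, three_well_layout, small_optics):
        ds = h.generate_plate(three_well_layout, small_optics, seed=2)
        assert ds.n_fields() == 3 * three_well_layout.min_fields
        for wid, wd in ds.wells.items():
            spec = three_well_layout.conditions[wd.condition]
            assert len(wd.truth) == spec.cells_per_field * three_well_layout.min_fields

    def test_same_seed_gives_identical_dataset(self, three_well_layout, small_optics):
        a = h.generate_plate(three_well_layout, small_optics, seed=3)
        b = h.generate_plate(three_well_layout, small_optics, seed=3)
        pd.testing.assert_frame_equal(a.truth_table(), b.truth_table())
        for wid in a.wells:
            for fa, fb in zip(a.wells[wid].fields, b.wells[wid].fields):
                for ch in h.CHANNELS:
                    np.testing.assert_array_equal(fa.channel(ch), fb.channel(ch))

    def test_different_seed_differs(self, three_well_layout, small_optics):
        a = h.generate_plate(three_well_layout, small_optics, seed=3)
        b = h.generate_plate(three_well_layout, small_optics, seed=4)
        assert not np.array_equal(
            a.wells["A1"].fields[0].hoechst, b.wells["A1"].fields[0].hoechst
        )

    def test_dataset_roundtrip_through_tiffs(self, tmp_path, three_well_layout, small_optics):
        ds = h.generate_plate(three_well_layout, small_optics, seed=5, n_fields=1)
        h.write_dataset(ds, tmp_path)
        from hcsplice.synth import read_fields

        fields = read_fields(tmp_path, "A1", 1)
        np.testing.assert_array_equal(fields[0].gfp, ds.wells["A1"].fields[0].gfp)
        truth = pd.read_csv(tmp_path / "truth.csv")
        assert len(truth) == len(ds.truth_table())
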