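"""Synthetic movie generator: determinism, camera model, imposed truths."""

import numpy as np
import pytest

from pkaproz import imaging, pipeline, synthetic, translocation
from pkaproz.synthetic import (MigrationParams, Scenario, load_movie,
                               make_migration_tracks, render_movie,
                               save_movie)


class TestScenarioValidation:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario kind"):
            Scenario(kind="petri_dish")

    @pytest.mark.parametrize("kw", [
        {"n_cells": 0}, {"duration_min": 0.0}, {"noise": -0.5},
    ])
    def test_bad_numbers_rejected(self, kw):
        with pytest.raises(ValueError):
            Scenario(kind="dish_uniform", **kw)

    def test_default_intervals(self):
        assert Scenario(kind="dish_uniform").interval == 1.0
        assert Scenario(kind="fsk_ibmx_saturating").interval == 2.0
        assert Scenario(kind="chip_gradient",
                        frame_interval_min=4.0).interval == 4.0

    def test_time_grid_starts_at_zero(self):
        sc = Scenario(kind="dmso_control", duration_min=10.0)
        assert sc.t_grid[0] == 0.0 and sc.t_grid[-1] == 10.0


class TestDeterminism:
    def test_same_seed_bit_identical_arrays(self):
        sc = Scenario(kind="dish_uniform", dose_nM=20.0, n_cells=3,
                      duration_min=4, seed=11)
        m1, g1 = render_movie(sc)
        m2, g2 = render_movie(sc)
        assert sorted(m1) == sorted(m2)
        for name in m1:
            assert np.array_equal(m1[name], m2[name])
        assert g1.cells == g2.cells

    def test_different_seed_differs(self):
        kw = dict(kind="dish_uniform", dose_nM=20.0, n_cells=3,
                  duration_min=4)
        m1, _ = render_movie(Scenario(seed=1, **kw))
        m2, _ = render_movie(Scenario(seed=2, **kw))
        assert not np.array_equal(m1["YFP"], m2["YFP"])

    def test_saved_files_byte_identical(self, tmp_path):
        sc = Scenario(kind="dmso_control", n_cells=2, duration_min=4, seed=9)
        movie, gt = render_movie(sc)
        save_movie(movie, gt, tmp_path / "a")
        save_movie(movie, gt, tmp_path / "b")
        for name in gt.channels:
            ba = (tmp_path / "a" / f"{name}.tif").read_bytes()
            bb = (tmp_path / "b" / f"{name}.tif").read_bytes()
            assert ba == bb

    def test_save_load_round_trip(self, tmp_path):
        sc = Scenario(kind="dmso_control", n_cells=2, duration_min=4, seed=9)
        movie, gt = render_movie(sc)
        save_movie(movie, gt, tmp_path / "m")
        back, gt2 = load_movie(tmp_path / "m")
        for name in gt.channels:
            assert np.array_equal(back[name],
                                  movie[name].astype(np.float32))
        assert gt2.t_min == gt.t_min
        assert gt2.scenario["kind"] == sc.kind


class TestCameraModel:
    def test_noise_off_background_is_dark_offset(self):
        sc = Scenario(kind="dmso_control", n_cells=1, duration_min=2,
                      noise=0.0, seed=0)
        movie, _ = render_movie(sc)
        corner = movie["YFP"][0, :5, :5]
        assert np.all(corner == synthetic.DARK_OFFSET)

    def test_shot_noise_variance_tracks_mean(self):
        """Inside a cell the pixel variance is close to Poisson + read."""
        kw = dict(kind="dish_uniform", dose_nM=0.0, n_cells=1,
                  duration_min=2, seed=21)
        movie, _ = render_movie(Scenario(**kw))
        ref, _ = render_movie(Scenario(noise=0.0, **kw))
        interior = ref["YFP"][0] > synthetic.DARK_OFFSET
        signal = ref["YFP"][0][interior] - synthetic.DARK_OFFSET
        assert np.ptp(signal) == 0  # uniform within the single cell
        pixels = movie["YFP"][0][interior]
        expected_var = signal[0] + synthetic.READ_NOISE_SD ** 2
        assert pixels.mean() == pytest.approx(
            synthetic.DARK_OFFSET + signal[0], rel=0.02)
        assert pixels.var(ddof=1) == pytest.approx(expected_var, rel=0.15)

    def test_background_read_noise_variance(self):
        sc = Scenario(kind="dmso_control", n_cells=1, duration_min=2,
                      seed=4)
        movie, _ = render_movie(sc)
        corner = movie["CFP"][0, :20, :20].ravel()
        assert corner.var(ddof=1) == pytest.approx(
            synthetic.READ_NOISE_SD ** 2, rel=0.35)


class TestImposedTruths:
    def test_saturating_stimulus_noise_free_exact_dynamic_range(self):
        """Noise-free full-scale movie analyzes to exactly the calibration."""
        sc = Scenario(kind="fsk_ibmx_saturating", n_cells=4,
                      duration_min=10, noise=0.0, seed=2)
        movie, gt = render_movie(sc)
        res = pipeline.analyze_fret_movie(movie, gt.dark_frame,
                                          seg_threshold=250.0)
        dr_pct = translocation.DEFAULT_CALIBRATION.DR * 100
        assert res["max_increase_pct"] == pytest.approx(
            np.full(4, dr_pct), abs=1e-9)
        gt_ratio = np.array([c["ratio"] for c in gt.cells])
        rec = res["ratio_series"][res["kept_ids"]]
        assert np.sqrt(np.mean((rec - gt_ratio) ** 2)) < 1e-9

    def test_control_movie_flat_ratio(self):
        sc = Scenario(kind="dmso_control", n_cells=3, duration_min=6,
                      noise=0.0, seed=2)
        movie, gt = render_movie(sc)
        res = pipeline.analyze_fret_movie(movie, gt.dark_frame,
                                          seg_threshold=250.0)
        assert np.allclose(res["max_increase_pct"], 0.0, atol=1e-9)

    def test_dye_channel_encodes_linear_gradient(self):
        """Dye intensity decodes to a 0.08 nM/µm profile on the chip."""
        sc = Scenario(kind="chip_gradient", c_source=20.0, c_sink=0.0,
                      n_cells=2, duration_min=2, noise=0.0, seed=0)
        movie, gt = render_movie(sc)
        dye = movie["dye"][0][:, 0]
        conc = (dye - synthetic.DARK_OFFSET
                - synthetic.I_DYE_BASE) / synthetic.I_DYE_GAIN
        H = dye.size
        y_um = 250.0 - np.arange(H) * gt.pixel_size
        inside = y_um >= 0  # the last pixel row sits just past the sink wall
        slope = np.polyfit(y_um[inside], conc[inside], 1)[0]
        assert slope == pytest.approx(0.08, rel=1e-9)
        assert conc[0] == pytest.approx(20.0, abs=1e-9)  # row 0 = source

    def test_cytoplasmic_depletion_matches_dose_model(self):
        """Noise-free 100 nM movie: measured drop equals R_x / R_total."""
        sc = Scenario(kind="dish_uniform", dose_nM=100.0, n_cells=3,
                      duration_min=8, noise=0.0, seed=6)
        movie, gt = render_movie(sc)
        res = pipeline.analyze_cytoplasm(movie, gt.dark_frame,
                                         seg_threshold=250.0)
        p = translocation.DEFAULT_TRANSLOCATION
        rx = translocation.membrane_R_timecourse(
            100.0, np.asarray(gt.t_min)).value
        expected = 1.0 - rx / p.R_cyto_total
        for series in res["series"].values():
            assert not series.excluded
            assert series.series == pytest.approx(expected, abs=1e-9)

    def test_no_anchor_control_chip_ratio_flat(self):
        sc = Scenario(kind="no_membrane_anchor_control", c_source=20.0,
                      c_sink=0.0, n_cells=2, duration_min=8, noise=0.0,
                      seed=1)
        movie, gt = render_movie(sc)
        for cell in gt.cells:
            assert np.allclose(cell["ratio_mean"], synthetic.BASE_RATIO)
        profiles = pipeline.analyze_chip_profiles(movie, gt.dark_frame,
                                                  seg_threshold=250.0)
        assert profiles
        for _, prof in profiles:
            filled = prof.means[~prof.empty]
            assert filled == pytest.approx(
                np.full(filled.size, synthetic.BASE_RATIO), abs=1e-9)

    def test_chip_nuclear_rows_recovered(self, chip_movie):
        sc, movie, gt = chip_movie
        tracks = pipeline.track_chip_nuclei(movie, sc.n_cells, 700.0,
                                            gt.dark_frame,
                                            t_min=np.asarray(gt.t_min))
        gt_rows = np.array([c["nuclear_row"] for c in gt.cells], float)
        rec = np.stack([tr.y_px for tr in tracks])
        assert np.nanmax(np.abs(rec - gt_rows)) <= 1.0


class TestMigration:
    def test_zero_speed_zero_noise_is_static(self):
        sc = Scenario(kind="dmso_control", n_cells=4, duration_min=20,
                      seed=3)
        mp = MigrationParams(v0=0.0, sigma_step=0.0)
        tracks = make_migration_tracks(sc, mp)
        assert np.all(tracks.displacement_um == 0.0)

    def test_persistent_cells_move_steadily_toward_source(self):
        sc = Scenario(kind="no_membrane_anchor_control", c_source=20.0,
                      n_cells=5, duration_min=40, frame_interval_min=4,
                      seed=8)
        mp = MigrationParams(v0=0.3, sigma_step=0.0, p_up_init=1.0)
        tracks = make_migration_tracks(sc, mp)
        assert np.all(np.diff(tracks.y_um, axis=1) > 0)
        assert np.all(np.isnan(tracks.reversal_time))
        assert tracks.displacement_um[:, -1] == pytest.approx(
            np.full(5, 0.3 * 40.0))

    def test_gradient_cells_reverse_within_window(self):
        sc = Scenario(kind="chip_gradient", c_source=20.0, c_sink=0.0,
                      n_cells=20, duration_min=120, frame_interval_min=4,
                      seed=12)
        tracks = make_migration_tracks(sc)
        assert np.all(np.isfinite(tracks.reversal_time))
        assert np.all(tracks.reversal_time >= 15.0)
        assert np.all(tracks.reversal_time <= 60.0)
        # after every reversal window has elapsed, all polarities point down
        late = tracks.t_min > 60.0
        assert np.all(tracks.polarity[:, late] == -1.0)

    def test_population_rises_then_falls_in_steep_gradient(self):
        sc = Scenario(kind="chip_gradient", c_source=20.0, c_sink=0.0,
                      n_cells=24, duration_min=240, frame_interval_min=4,
                      seed=1)
        tracks = make_migration_tracks(sc)
        mean = tracks.displacement_um.mean(axis=0)
        i_peak = int(np.argmax(mean))
        t_peak = tracks.t_min[i_peak]
        assert 0 < t_peak <= 60.0
        assert mean[i_peak] > 0
        assert mean[-1] < 0

    def test_saturating_uniform_dose_randomizes_direction(self):
        sc = Scenario(kind="chip_uniform", dose_nM=100.0, n_cells=40,
                      duration_min=240, frame_interval_min=4, seed=17)
        tracks = make_migration_tracks(sc)
        final = tracks.displacement_um[:, -1]
        # direction scrambling: both signs present, symmetric around zero
        assert (final > 0).any() and (final < 0).any()
        _, p = imaging.two_sample_ttest(final, -final)
        assert p > 0.05

    def test_reflecting_boundaries_respected(self):
        sc = Scenario(kind="chip_uniform", dose_nM=0.0, n_cells=10,
                      duration_min=400, frame_interval_min=4, seed=5)
        mp = MigrationParams(v0=0.5, sigma_step=2.0, p_up_init=1.0)
        tracks = make_migration_tracks(sc, mp)
        assert np.all(tracks.y_um >= 25.0)
        assert np.all(tracks.y_um <= 225.0)


class TestFixtureSuite:
    def test_manifest_consistency(self, fixtures):
        man = fixtures["manifest"]
        assert (fixtures["disk"] > 0).sum() == man["disk_area_px"]
        assert fixtures["translated_nucleus"].shape[0] == 6
        assert man["nucleus_displacement_um_frame5"] == pytest.approx(
            15 * imaging.DEFAULT_PIXEL_SIZE_UM)

    def test_ramp_ratio_structure(self, fixtures):
        ratio = fixtures["ramp_fret"] / fixtures["ramp_cfp"]
        rows = np.arange(ratio.shape[0])
        assert ratio[:, 0] == pytest.approx(1.0 + 0.01 * rows)
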