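"""Generator correctness: speed statistics, motion model, rendering, ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crrc.simulate import (
    ConfigurationError,
    GroundTruth,
    SimulationConfig,
    SpeedDistribution,
    render_frames,
    sample_speeds,
    simulate_timelapse,
    step_positions,
    write_ground_truth,
    read_ground_truth,
)

from oracles import disk_area_px


class TestSampleSpeeds:
    def test_mode_and_iqr_match_configuration(self):
        """1e5 draws reproduce the configured peak (~150 um/h) and IQR (40 um/h)."""
        rng = np.random.default_rng(0)
        s = sample_speeds(SpeedDistribution(150.0, 40.0, 450.0), 100_000, rng)
        counts, edges = np.histogram(s, bins=150)
        empirical_mode = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
        assert abs(empirical_mode - 150.0) < 15.0
        iqr = np.percentile(s, 75) - np.percentile(s, 25)
        assert abs(iqr - 40.0) < 8.0
        assert s.max() <= 450.0 and s.min() > 0

    def test_point_mass_limit(self):
        rng = np.random.default_rng(0)
        assert sample_speeds(SpeedDistribution(150.0, 0.0, 450.0), 1, rng)[0] == 150.0

    def test_quantiles_match_closed_form(self):
        """Empirical quantiles of 1e6 draws agree with the log-normal ppf."""
        dist = SpeedDistribution(150.0, 40.0, 10_000.0)  # truncation far out
        rng = np.random.default_rng(1)
        s = sample_speeds(dist, 1_000_000, rng)
        qs = np.linspace(0.01, 0.99, 25)
        emp = np.quantile(s, qs)
        theory = dist.frozen().ppf(qs)
        scale = dist.frozen().median()
        assert np.max(np.abs(emp - theory)) < 0.01 * scale

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            SpeedDistribution(-5.0, 40.0, 400.0)
        with pytest.raises(ConfigurationError):
            SpeedDistribution(150.0, -1.0, 400.0)
        with pytest.raises(ConfigurationError):
            SpeedDistribution(150.0, 40.0, 100.0)  # max below mode


class TestStepPositions:
    FIELD = (10_000.0, 10_000.0)

    def test_ballistic_limit(self):
        """Persistence 1: straight-line path with length speed * T."""
        rng = np.random.default_rng(0)
        pos = np.array([[5000.0, 5000.0]])
        hdg = np.array([0.3])
        path = [pos[0].copy()]
        for _ in range(20):
            pos, hdg = step_positions(pos, hdg, np.array([120.0]), 1.0, 60.0, self.FIELD, rng)
            path.append(pos[0].copy())
        path = np.array(path)
        steps = np.diff(path, axis=0)
        assert np.allclose(np.hypot(*steps.T), 120.0 * 60.0 / 3600.0, rtol=1e-12)
        directions = steps / np.hypot(*steps.T)[:, None]
        assert np.allclose(directions, directions[0], atol=1e-12)

    def test_zero_speed_stationary(self):
        rng = np.random.default_rng(0)
        pos = np.array([[10.0, 20.0], [30.0, 40.0]])
        new, _ = step_positions(pos, np.zeros(2), np.zeros(2), 0.5, 60.0, self.FIELD, rng)
        assert np.array_equal(new, pos)

    def test_msd_linear_at_zero_persistence(self):
        """Uncorrelated walk: MSD(n) = n * L^2 within 10% (ensemble of walks)."""
        rng = np.random.default_rng(5)
        n_walks, n_steps, speed, dt = 600, 64, 150.0, 60.0
        L = speed * dt / 3600.0
        disp2 = np.zeros(n_steps)
        for _ in range(n_walks):
            pos = np.array([[5000.0, 5000.0]])
            hdg = rng.uniform(-np.pi, np.pi, 1)
            start = pos[0].copy()
            for s in range(n_steps):
                pos, hdg = step_positions(pos, hdg, np.array([speed]), 0.0, dt, self.FIELD, rng)
                disp2[s] += np.sum((pos[0] - start) ** 2)
        disp2 /= n_walks
        lags = np.arange(1, n_steps + 1)
        slope = np.sum(lags * disp2) / np.sum(lags * lags)  # through-origin fit
        assert abs(slope - L**2) < 0.10 * L**2

    def test_dt_must_be_positive(self):
        with pytest.raises(ValueError):
            step_positions(np.zeros((1, 2)), np.zeros(1), np.ones(1), 0.5, 0.0, self.FIELD,
                           np.random.default_rng(0))


class TestRendering:
    def test_noiseless_decay_ratio_exact(self):
        """Immobile, noise-free: frame-to-frame total fluorescence ratio is exp(-k t2)."""
        cfg = SimulationConfig(
            n_cells=5,
            field_size=(128, 128),
            n_frames=6,
            speed=SpeedDistribution(0.0, 0.0),
            noise_sd=0.0,
            background_level=0.0,
            intensity_offset=0.0,
            min_separation_um=10.0,
            rng_seed=2,
        )
        sim = simulate_timelapse(cfg)
        k = sim.ground_truth.cells["k_per_min"].to_numpy()
        masks = sim.ground_truth.label_masks
        fl = sim.fluorescence.frames
        for i in range(cfg.n_cells):
            region = masks[0] == i + 1
            # sum over a dilated fixed window catching the whole AA footprint
            rows, cols = np.where(region)
            sl = (slice(rows.min() - 3, rows.max() + 4), slice(cols.min() - 3, cols.max() + 4))
            totals = np.array([fl[j][sl].sum() for j in range(cfg.n_frames)])
            ratios = totals[1:] / totals[:-1]
            assert np.allclose(ratios, np.exp(-k[i] * 1.0), rtol=1e-9)

    def test_zero_motility_transmitted_frames_identical(self):
        cfg = SimulationConfig(
            n_cells=4, field_size=(96, 96), n_frames=4,
            speed=SpeedDistribution(0.0, 0.0), noise_sd=0.0, rng_seed=3,
        )
        sim = simulate_timelapse(cfg)
        tl = sim.transmitted.frames
        assert all(np.array_equal(tl[0], tl[j]) for j in range(1, 4))

    def test_total_fluorescence_matches_analytic_area(self, small_noiseless_sim):
        """Noise off: rendered per-cell total = A exp(-k t) * pi r^2 within 1%."""
        sim = small_noiseless_sim
        cfg = sim.config
        gt = sim.ground_truth
        t_fl = sim.fluorescence.timestamps
        fl = sim.fluorescence.frames
        for j in (0, cfg.n_frames - 1):
            for i in range(cfg.n_cells):
                pos = gt.tracks.query("frame == @j and cell_id == @i")
                r_px = gt.cells["radius_um"][i] / cfg.pixel_size
                cr, cc = pos["row_fl_um"].iloc[0] / cfg.pixel_size, pos["col_fl_um"].iloc[0] / cfg.pixel_size
                sl = (
                    slice(max(int(cr - r_px - 4), 0), int(cr + r_px + 5)),
                    slice(max(int(cc - r_px - 4), 0), int(cc + r_px + 5)),
                )
                total = fl[j][sl].sum()
                expected = (
                    cfg.initial_intensity
                    * np.exp(-gt.cells["k_per_min"][i] * t_fl[j] / 60.0)
                    * disk_area_px(gt.cells["radius_um"][i], cfg.pixel_size)
                )
                assert total == pytest.approx(expected, rel=0.01)

    def test_timestamp_offset_is_channel_gap(self, small_motile_sim):
        sim = small_motile_sim
        gap = sim.fluorescence.timestamps - sim.transmitted.timestamps
        assert np.allclose(gap, sim.config.channel_gap_s)

    def test_oversized_cell_rejected(self):
        cfg = SimulationConfig(n_cells=1, field_size=(64, 64), n_frames=2, rng_seed=0)
        rng = np.random.default_rng(0)
        pos = np.full((2, 1, 2), 20.0)
        with pytest.raises(ConfigurationError):
            render_frames(cfg, pos, pos, np.array([50.0]), np.array([0.05]), rng)


class TestGroundTruthAndDeterminism:
    def test_determinism(self):
        cfg = SimulationConfig(n_cells=8, field_size=(128, 128), n_frames=4, rng_seed=42)
        a, b = simulate_timelapse(cfg), simulate_timelapse(cfg)
        assert np.array_equal(a.transmitted.frames, b.transmitted.frames)
        assert np.array_equal(a.fluorescence.frames, b.fluorescence.frames)
        assert a.ground_truth.cells.equals(b.ground_truth.cells)
        assert np.array_equal(a.ground_truth.label_masks, b.ground_truth.label_masks)

    def test_mask_pixel_counts_match_analytic_areas(self, small_motile_sim):
        """Ground-truth label-mask areas agree with pi r^2 (1% on average)."""
        sim = small_motile_sim
        gt = sim.ground_truth
        counts = np.bincount(gt.label_masks[0].ravel(), minlength=sim.config.n_cells + 1)[1:]
        expected = np.array(
            [disk_area_px(r, sim.config.pixel_size) for r in gt.cells["radius_um"]]
        )
        rel = np.abs(counts - expected) / expected
        assert rel.mean() < 0.01

    def test_ground_truth_roundtrip(self, tmp_path, small_motile_sim):
        gt = small_motile_sim.ground_truth
        write_ground_truth(gt, tmp_path)
        back = read_ground_truth(tmp_path)
        pd.testing.assert_frame_equal(gt.cells, back.cells, rtol=1e-12)
        pd.testing.assert_frame_equal(gt.tracks, back.tracks, rtol=1e-12)
        assert np.array_equal(gt.label_masks, back.label_masks)

    def test_empty_population_writes_headers_only(self, tmp_path):
        gt = GroundTruth(
            cells=pd.DataFrame(columns=["cell_id", "k_per_min", "radius_um", "speed_um_per_h"]),
            tracks=pd.DataFrame(columns=["cell_id", "frame", "row_um", "col_um"]),
            label_masks=np.zeros((1, 8, 8), dtype=np.uint16),
        )
        paths = write_ground_truth(gt, tmp_path)
        lines = paths["cells"].read_text().strip().splitlines()
        assert len(lines) == 2  # schema comment + header
        assert "k_per_min" in lines[1]

    def test_speed_recovered_from_true_centroids(self, small_motile_sim):
        """Per-cell track speed from ground-truth centroids within 5% of the draw."""
        sim = small_motile_sim
        gt = sim.ground_truth
        t = sim.transmitted.timestamps
        errs = []
        for cid, sub in gt.tracks.groupby("cell_id"):
            sub = sub.sort_values("frame")
            pos = sub[["row_um", "col_um"]].to_numpy()
            path = np.sum(np.hypot(*np.diff(pos, axis=0).T))
            v = path / ((t[-1] - t[0]) / 3600.0)
            v_true = gt.cells["speed_um_per_h"][cid]
            errs.append(abs(v - v_true) / v_true)
        errs = np.array(errs)
        assert np.median(errs) < 0.05
        assert np.mean(errs < 0.05) >= 0.9

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_cells=0)
        with pytest.raises(ConfigurationError):
            SimulationConfig(channel_gap_s=60.0, frame_interval_s=60.0)
        with pytest.raises(ConfigurationError):
            SimulationConfig(pixel_size=0.0)
        with pytest.raises(ConfigurationError):
            SimulationConfig(motion_persistence=1.5)

    def test_initial_placement_has_no_overlap(self, small_motile_sim):
        gt = small_motile_sim.ground_truth
        f0 = gt.tracks.query("frame == 0").sort_values("cell_id")
        pos = f0[["row_um", "col_um"]].to_numpy()
        radii = gt.cells["radius_um"].to_numpy()
        d = np.hypot(*(pos[:, None, :] - pos[None, :, :]).transpose(2, 0, 1))
        np.fill_diagonal(d, np.inf)
        assert np.all(d > radii[:, None] + radii[None, :])
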