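"""Generator correctness: closed-form heights, schedules, invariants."""

from __future__ import annotations

import numpy as np
import pytest

from biovsi import generate_experiment, schedule_detachments
from biovsi.config import ExperimentConfig
from biovsi.metrics import fit_rate, retreat_series
from biovsi.synthetic import PlacementError

from conftest import small_config


class TestConfigValidation:
    def test_non_integer_grid_rejected(self):
        with pytest.raises(ValueError, match="integer multiple"):
            ExperimentConfig(field_width_um=100.3, pixel_size_um=0.4).validate()

    def test_duration_not_multiple_of_interval_rejected(self):
        with pytest.raises(ValueError, match="integer multiple"):
            ExperimentConfig(duration_h=1.02, frame_interval_min=5).validate()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"inhibition_factor": 1.5},
            {"retreat_rate_um_per_d": -1.0},
            {"detachment_mode": "uniform", "detachment_rate_cells_mm2_h": 0.0},
            {"detachment_mode": "sideways"},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ExperimentConfig(**kwargs).validate()


class TestHeightModel:
    def test_static_identity_case(self):
        """R = 0, f irrelevant, no noise, no cells: every frame identical,
        retreat series identically zero."""
        cfg = small_config(retreat_rate_um_per_d=0.0, duration_h=1.0)
        stack, _ = generate_experiment(cfg)
        for k in range(1, stack.n_frames):
            np.testing.assert_array_equal(stack.heights[k], stack.heights[0])
        _, series, _ = retreat_series(stack)
        np.testing.assert_allclose(series, 0.0, atol=1e-9)

    def test_closed_form_retreat(self):
        """z(t) = z0 - R t: a 24 h run at 10.3 µm/d lowers calcite by
        10300 nm relative to quartz."""
        cfg = small_config(retreat_rate_um_per_d=10.3, duration_h=24.0)
        stack, _ = generate_experiment(cfg)
        final = stack.heights[-1]
        diff = final[stack.quartz_mask].mean() - final[stack.calcite_mask].mean()
        assert diff == pytest.approx(10300.0, rel=1e-9)

    def test_under_cell_relief_after_four_hours(self):
        """A cell resident exactly 4.0 h on calcite retreating at
        10.3 µm/d with 20% inhibition leaves a 0.34 µm high."""
        cfg = small_config(
            retreat_rate_um_per_d=10.3,
            inhibition_factor=0.8,
            duration_h=24.0,
            n_cells_initial=1,
            detachment_mode="uniform",
            detachment_rate_cells_mm2_h=1.0,
        )
        stack, truth = generate_experiment(cfg, detach_times=np.array([4.0]))
        rr, cc = truth.footprints[0]
        covered = truth.final_height_true_nm[rr[0], cc[0]]
        background = truth.final_height_true_nm[
            stack.calcite_mask & (truth.residence_map_h == 0)
        ][0]
        relief_um = (covered - background) / 1000.0
        assert truth.residence_map_h[rr[0], cc[0]] == pytest.approx(4.0)
        assert round(relief_um, 2) == 0.34
        assert relief_um == pytest.approx(0.2 * 10.3 * 4.0 / 24.0, rel=1e-9)

    def test_quartz_bit_identical_without_noise(self):
        cfg = small_config(n_cells_initial=5, duration_h=1.0)
        stack, _ = generate_experiment(cfg)
        q = stack.quartz_mask
        for k in range(stack.n_frames):
            np.testing.assert_array_equal(stack.heights[k][q], stack.heights[0][q])

    def test_apparent_height_is_true_minus_depression(self):
        """Noise-free: covered pixels differ from the cell-free surface by
        exactly the configured optical depression."""
        cfg = small_config(n_cells_initial=8, duration_h=0.5, inhibition_factor=0.9)
        stack, truth = generate_experiment(cfg)
        mask = truth.mask(stack.n_frames - 1)
        # reconstruct the true final surface from truth and compare
        diff = truth.final_height_true_nm - stack.heights[-1]
        np.testing.assert_allclose(diff[mask], cfg.cell_depression_nm, atol=1e-3)
        np.testing.assert_allclose(diff[~mask], 0.0, atol=1e-3)

    def test_noiseless_rate_recovery_is_exact(self):
        cfg = small_config(retreat_rate_um_per_d=7.7, duration_h=6.0)
        stack, _ = generate_experiment(cfg)
        t, y, _ = retreat_series(stack)
        fit = fit_rate(y, t)
        assert fit.slope_um_per_d == pytest.approx(7.7, rel=1e-6)


class TestGroundTruthConsistency:
    def test_residence_totals_match_cell_bookkeeping(self, protective_run):
        """Summed residence equals sum over cells of footprint size times
        (frame-quantised) attached duration."""
        cfg, stack, truth = protective_run
        dt = cfg.frame_interval_h
        expected = 0.0
        n_intervals = truth.n_frames - 1
        for cid, cell in truth.cells.iterrows():
            n_present = min(
                int(np.ceil(cell.detach_h / dt - 1e-12)) if np.isfinite(cell.detach_h) else n_intervals,
                n_intervals,
            )
            expected += cell.n_pixels * n_present * dt
        assert truth.residence_map_h.sum() == pytest.approx(expected, rel=1e-9)

    def test_residence_bounded_by_duration(self, protective_run):
        cfg, _, truth = protective_run
        assert truth.residence_map_h.min() >= 0
        assert truth.residence_map_h.max() <= cfg.duration_h + 1e-9

    def test_placement_failure_raises(self):
        with pytest.raises(PlacementError):
            generate_experiment(
                small_config(field_width_um=20, field_height_um=20, n_cells_initial=100)
            )


class TestDetachmentSchedules:
    def test_mode_none_keeps_coverage_constant(self):
        cfg = small_config(n_cells_initial=10, duration_h=1.0)
        _, truth = generate_experiment(cfg)
        counts = truth.coverage_counts()
        assert np.all(counts == 10)

    def test_uniform_schedule_slope_matches_nominal_rate(self):
        """Uniform detach times on [0, N0/(dA)] make the expected coverage
        decline linearly at d cells/mm²/h; empirical slope over 20 seeds
        is within 10% of -d·A."""
        cfg = ExperimentConfig(
            field_width_um=400.0,
            field_height_um=400.0,
            quartz_fraction=0.0,
            n_cells_initial=500,
            detachment_mode="uniform",
            detachment_rate_cells_mm2_h=1298.0,
            duration_h=2.0,
        )
        area = cfg.calcite_area_mm2
        assert area == pytest.approx(0.16)
        t_grid = np.arange(0, 2.0, cfg.frame_interval_h)
        slopes = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            detach = schedule_detachments(cfg, rng)
            counts = np.array([(detach > t).sum() for t in t_grid], dtype=float)
            slopes.append(fit_rate(counts, t_grid).slope)
        mean_slope = np.mean(slopes)
        assert mean_slope == pytest.approx(-1298.0 * area, rel=0.10)

    def test_exponential_mean_waiting_time(self):
        """Mean of 10000 exponential waits recovers 1/λ within 3 sd."""
        cfg = ExperimentConfig(
            n_cells_initial=10_000,
            detachment_mode="exponential",
            detachment_rate_cells_mm2_h=500.0,
            quartz_fraction=0.0,
            rng_seed=5,
        )
        lam = 500.0 * cfg.calcite_area_mm2 / 10_000
        draws = schedule_detachments(cfg)
        se = (1 / lam) / np.sqrt(10_000)
        assert abs(draws.mean() - 1 / lam) < 3 * se
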