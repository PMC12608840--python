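import numpy as np
import pandas as pd
import pytest

from sipcop import (
    ItRegion,
    SipCopSeries,
    TrialCondition,
    align_streams,
    bland_altman,
    cop_from_forces,
    cop_threshold,
    fit_sine,
    fit_sip_cop_line,
    normalize_and_rezero,
    select_it_regions,
    simulate_trial,
    tare,
    theoretical_sine_coefficient,
    truncate_to_95,
)
from sipcop.errors import (
    DegenerateInputError,
    NoReductionError,
    ValidationError,
)
from sipcop.trial_pipeline import IMU_CHANNELS

REGION = ItRegion(left=(9, 4), right=(9, 10))


def make_series(cop_mag, prop, pitch=None, normalized=True):
    """Minimal SipCopSeries from arrays (both ITs carry ``prop``)."""
    n = len(cop_mag)
    cop_mag = np.asarray(cop_mag, dtype=float)
    data = {
        "t_s": np.arange(n) / 15.0,
        "cop_x": np.zeros(n),
        "cop_y": cop_mag,
        "cop_mag": cop_mag,
        "cop_angle_deg": np.full(n, 90.0),
        "prop_left": np.asarray(prop, dtype=float),
        "prop_right": np.asarray(prop, dtype=float),
    }
    for col in IMU_CHANNELS:
        data[col] = np.zeros(n)
    if pitch is not None:
        data["sternum_pitch"] = np.asarray(pitch, dtype=float)
    data["gap_lc_s"] = np.zeros(n)
    data["gap_imu_s"] = np.zeros(n)
    data["excluded"] = np.zeros(n, dtype=bool)
    return SipCopSeries(
        data=pd.DataFrame(data),
        cop_origin=np.zeros(2),
        condition=None,
        normalized=normalized,
        rezero_index=0,
    )


class TestCopFromForces:
    def test_equal_forces_center(self, geom):
        np.testing.assert_allclose(
            cop_from_forces(np.array([50.0, 50, 50, 50]), geom), [0.0, 0.0]
        )

    def test_front_pair_edge(self, geom):
        cop = cop_from_forces(np.array([0.0, 0.0, 80.0, 80.0]), geom)
        np.testing.assert_allclose(cop, [0.0, geom.depth / 2])

    def test_worked_corner_example(self, geom):
        cop = cop_from_forces(np.array([10.0, 30.0, 10.0, 30.0]), geom)
        np.testing.assert_allclose(cop, [10.0, 0.0])

    def test_equals_force_weighted_centroid(self, geom):
        """Oracle: weighted average of the four corner coordinates."""
        corners = np.array(
            [
                [-geom.width / 2, -geom.depth / 2],
                [geom.width / 2, -geom.depth / 2],
                [-geom.width / 2, geom.depth / 2],
                [geom.width / 2, geom.depth / 2],
            ]
        )
        rng = np.random.default_rng(4)
        for _ in range(200):
            f = rng.uniform(0, 100, 4)
            centroid = (f[:, None] * corners).sum(axis=0) / f.sum()
            np.testing.assert_allclose(cop_from_forces(f, geom), centroid, atol=1e-12)

    def test_nonpositive_sum_rejected(self, geom):
        with pytest.raises(DegenerateInputError):
            cop_from_forces(np.zeros(4), geom)


class TestTare:
    def test_zero_tare_is_identity(self):
        series = np.arange(20.0).reshape(5, 4)
        np.testing.assert_array_equal(tare(series, np.zeros((3, 4))), series)

    def test_constant_series_zeroed(self):
        frame = np.array([[1.0, 2.0, 3.0, 4.0]])
        series = np.tile(frame, (10, 1))
        np.testing.assert_array_equal(tare(series, series[:4]), np.zeros((10, 4)))

    def test_removes_simulated_cushion_weight(self, exact_cfg):
        trial = simulate_trial(exact_cfg, TrialCondition("P01", "forward", start_position="situp"))
        tared = tare(trial.loadcell_forces, trial.tare_frames)
        drop = trial.loadcell_forces.sum(axis=1) - tared.sum(axis=1)
        np.testing.assert_allclose(drop, exact_cfg.tare_weight_n, rtol=1e-9)


class TestAlignStreams:
    def test_commensurate_clocks_pair_exactly(self, exact_cfg, geom):
        trial = simulate_trial(exact_cfg, TrialCondition("P01", "forward", start_position="situp"))
        series = align_streams(trial, geom, REGION)
        assert series.data["gap_lc_s"].max() == 0.0
        assert series.data["gap_imu_s"].max() == 0.0
        assert len(series.data) == len(trial.mat_t)

    def test_nominal_rates_gap_bound(self, anthro, geom):
        """15 Hz mat against a 125 Hz load cell: the nearest sample is never
        more than half the 8 ms load-cell period away."""
        from sipcop import SimulationConfig, noiseless

        cfg = noiseless(SimulationConfig(anthropometry=anthro, geometry=geom, seed=1))
        trial = simulate_trial(cfg, TrialCondition("P01", "forward", start_position="situp"))
        series = align_streams(trial, geom, REGION)
        assert series.data["gap_lc_s"].max() <= 0.004 + 1e-12

    def test_mat_frame_outside_overlap_dropped(self, exact_cfg, geom):
        trial = simulate_trial(exact_cfg, TrialCondition("P01", "forward", start_position="situp"))
        early = trial.mat_t - 1.0  # first mat frames precede load-cell start
        shifted = type(trial)(
            condition=trial.condition,
            loadcell_t=trial.loadcell_t,
            loadcell_forces=trial.loadcell_forces,
            tare_frames=trial.tare_frames,
            mat_t=early,
            mat_frames=trial.mat_frames,
            imu_t=trial.imu_t,
            imu=trial.imu,
        )
        with pytest.warns(UserWarning, match="dropped"):
            series = align_streams(shifted, geom, REGION, max_gap_s=0.02)
        assert len(series.data) < len(early)


class TestSelectItRegions:
    def test_clear_hot_blocks_found(self):
        frame = np.full((16, 16), 1.0)
        frame[9:11, 4:6] = 50.0
        frame[8:10, 11:13] = 60.0
        region = select_it_regions(frame)
        assert region.left == (9, 4)
        assert region.right == (8, 11)

    def test_equals_exhaustive_window_search(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            frame = rng.uniform(0, 10, (16, 16))
            region = select_it_regions(frame)
            for side, (lo, hi) in (("left", (0, 8)), ("right", (8, 16))):
                best = max(
                    (frame[r : r + 2, c : c + 2].sum(), (r, c))
                    for r in range(15)
                    for c in range(lo, hi - 1)
                )
                assert getattr(region, side) == best[1]

    def test_uniform_frame_tie_breaks_low(self):
        region = select_it_regions(np.ones((16, 16)))
        assert region.left == (0, 0)
        assert region.right == (0, 8)

    def test_persistence_fallback_resolves_tie(self):
        static = np.zeros((16, 16))
        static[2:4, 2:4] = 5.0
        static[10:12, 2:4] = 5.0  # tie on the left half
        static[9:11, 10:12] = 7.0
        # during the forward trial the lower block stays high longer
        frames = np.tile(static, (10, 1, 1))
        frames[5:, 2:4, 2:4] = 0.1
        region = select_it_regions(static, fallback_forward_frames=frames)
        assert region.left == (10, 2)

    def test_empty_half_rejected(self):
        frame = np.zeros((16, 16))
        frame[9:11, 10:12] = 5.0
        with pytest.raises(DegenerateInputError):
            select_it_regions(frame)

    def test_region_invariants(self):
        with pytest.raises(ValidationError):
            ItRegion(left=(9, 10), right=(9, 4))


class TestNormalizeAndRezero:
    def test_peak_at_start_keeps_origin(self, exact_cfg, geom):
        trial = simulate_trial(exact_cfg, TrialCondition("P01", "forward", start_position="situp"))
        series = normalize_and_rezero(align_streams(trial, geom, REGION))
        assert series.rezero_index == 0
        assert not series.data["excluded"].any()

    def test_peak_sample_is_reference(self, exact_cfg, geom):
        trial = simulate_trial(exact_cfg, TrialCondition("P01", "forward", start_position="backrest"))
        series = normalize_and_rezero(align_streams(trial, geom, REGION))
        k = series.rezero_index
        assert series.data["cop_mag"].iloc[k] == 0.0
        mean_prop = (
            series.data["prop_left"].iloc[k] + series.data["prop_right"].iloc[k]
        ) / 2
        assert mean_prop == pytest.approx(1.0)

    def test_backrest_start_rezeros_at_upright(self, exact_cfg, geom):
        """The injected pressure peak sits at the end of the backrest
        phase; re-zeroing must land there."""
        trial = simulate_trial(exact_cfg, TrialCondition("P01", "forward", start_position="backrest"))
        series = normalize_and_rezero(align_streams(trial, geom, REGION))
        t_peak = series.data["t_s"].iloc[series.rezero_index]
        # the peak is located on a 0.5-s moving average, so it may sit up to
        # half a window past the backrest-to-upright junction
        assert t_peak == pytest.approx(exact_cfg.backrest_pre_s, abs=0.25 + 1 / 12.5)
        assert series.data["prop_left"].iloc[series.rezero_index] == pytest.approx(1.0)
        assert series.data["excluded"].iloc[: series.rezero_index].all()

    def test_idempotent(self, exact_cfg, geom):
        trial = simulate_trial(exact_cfg, TrialCondition("P01", "forward", start_position="backrest"))
        once = normalize_and_rezero(align_streams(trial, geom, REGION))
        twice = normalize_and_rezero(once)
        pd.testing.assert_frame_equal(once.data, twice.data)
        assert twice.rezero_index == once.rezero_index


class TestTruncateTo95:
    def test_linear_decay_keeps_96_of_101(self):
        p = np.linspace(1.0, 0.0, 101)
        series = make_series(np.linspace(0, 10, 101), p)
        out = truncate_to_95(series, direction="forward")
        assert len(out.data) == 96

    def test_constant_pressure_excluded(self):
        series = make_series(np.linspace(0, 10, 50), np.ones(50))
        with pytest.raises(NoReductionError):
            truncate_to_95(series)

    def test_rebound_cuts_at_first_crossing(self):
        # p drops 1 -> 0.5 then rebounds: p_min = 0.5, cutoff at the first
        # crossing of 0.5 + 0.05 * 0.5 = 0.525
        down = np.linspace(1.0, 0.5, 51)
        up = np.linspace(0.5, 0.9, 30)[1:]
        p = np.concatenate([down, up])
        series = make_series(np.linspace(0, 8, len(p)), p)
        out = truncate_to_95(series)
        kept_p = (out.data["prop_left"] + out.data["prop_right"]) / 2
        assert kept_p.iloc[-1] <= 0.525
        assert (kept_p.iloc[:-1] > 0.525).all()

    def test_output_is_contiguous_prefix_from_rezero(self):
        p = np.linspace(1.0, 0.2, 60)
        series = make_series(np.linspace(0, 9, 60), p)
        out = truncate_to_95(series)
        assert out.rezero_index == 0
        np.testing.assert_array_equal(
            out.data["t_s"].to_numpy(), series.data["t_s"].to_numpy()[: len(out.data)]
        )


class TestFits:
    def test_exact_line_recovered(self):
        mag = np.linspace(0, 10, 40)
        series = make_series(mag, 1.0 - 0.07 * mag)
        fit = fit_sip_cop_line(series, direction="forward")
        assert fit.slope == pytest.approx(-0.07, rel=1e-12)
        assert fit.intercept == pytest.approx(1.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_pooling_duplicates_keeps_slope(self):
        mag = np.linspace(0, 10, 40)
        series = make_series(mag, 1.0 - 0.05 * mag + 0.01 * np.sin(mag))
        single = fit_sip_cop_line(series)
        pooled = fit_sip_cop_line([series, series, series])
        assert pooled.slope == pytest.approx(single.slope, rel=1e-12)
        assert pooled.n_samples == 3 * single.n_samples

    def test_zero_cop_variance_rejected(self):
        series = make_series(np.ones(10), np.linspace(1, 0.5, 10))
        with pytest.raises(DegenerateInputError):
            fit_sip_cop_line(series)

    def test_sine_fit_exact(self):
        theta = np.linspace(0, 40, 50)
        series = make_series(
            15.0 * np.sin(np.radians(theta)), np.linspace(1, 0.4, 50), pitch=theta
        )
        b, r2 = fit_sine(series, fraction=1.0)
        assert b == pytest.approx(15.0, rel=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_sine_fit_degenerate_when_flat(self):
        series = make_series(np.linspace(0, 5, 30), np.linspace(1, 0.5, 30))
        with pytest.raises(DegenerateInputError):
            fit_sine(series)

    def test_end_to_end_sine_matches_theory(self, exact_cfg, anthro, geom):
        trial = simulate_trial(exact_cfg, TrialCondition("P01", "forward", start_position="situp"))
        series = normalize_and_rezero(align_streams(trial, geom, REGION))
        b, r2 = fit_sine(series)
        assert b == pytest.approx(theoretical_sine_coefficient(anthro), abs=1e-6)
        assert r2 == pytest.approx(1.0)


class TestThresholds:
    @pytest.mark.parametrize(
        "slope,expected",
        [(-0.0730, 12.33), (-0.1040, 8.65)],
    )
    def test_published_90pct_thresholds(self, slope, expected):
        assert cop_threshold(slope, 0.90) == pytest.approx(expected, abs=0.005)

    def test_zero_reduction(self):
        assert cop_threshold(-0.07, 0.0) == 0.0

    def test_nonnegative_slope_rejected(self):
        with pytest.raises(ValidationError):
            cop_threshold(0.05, 0.9)


class TestBlandAltman:
    def test_identical_pairs(self):
        res = bland_altman([(0.5, 0.5), (0.7, 0.7)])
        assert res.mean_diff == 0.0
        assert res.sd_diff == 0.0

    def test_worked_arithmetic(self):
        res = bland_altman([(1.0, 0.0), (3.0, 2.0)])
        assert res.mean_diff == 1.0
        assert res.sd_diff == 0.0
        assert (res.loa_low, res.loa_high) == (1.0, 1.0)
        np.testing.assert_array_equal(res.means, [0.5, 2.5])

    def test_steeper_fitted_slopes_give_negative_mean_diff(self):
        rng = np.random.default_rng(6)
        theoretical = -rng.uniform(0.03, 0.06, 10)
        fitted = theoretical - rng.uniform(0.01, 0.03, 10)  # steeper (more negative)
        res = bland_altman(np.column_stack([fitted, theoretical]))
        assert res.mean_diff < 0

    def test_single_pair_rejected(self):
        with pytest.raises(ValidationError):
            bland_altman([(1.0, 0.9)])
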