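"""Synthetic-session generator: behavior, population, spikes, fluorescence."""

import numpy as np
import pytest
from scipy import stats

from hippotune import (AnalysisConfig, GroundTruth, NoiseModel, SimParams,
                       render_fluorescence, sample_population,
                       simulate_behavior, simulate_session, simulate_spikes)
from hippotune.behavior_ops import position_bins
from hippotune.synth import _kernel


class TestBehavior:
    def test_same_seed_identical(self, cfg):
        p = SimParams(n_blocks=2, block_s=20)
        b1 = simulate_behavior(p, cfg, np.random.default_rng(4))
        b2 = simulate_behavior(p, cfg, np.random.default_rng(4))
        np.testing.assert_array_equal(b1.position, b2.position)
        np.testing.assert_array_equal(b1.speed, b2.speed)

    def test_zero_pause_probability_keeps_running(self, cfg):
        p = SimParams(n_blocks=2, block_s=60, pause_rate_hz=0.0)
        b = simulate_behavior(p, cfg, np.random.default_rng(1))
        assert np.all(b.speed[~b.recording_gap] > 0)

    def test_occupancy_covers_bins_after_one_lap(self, cfg):
        """Continuous running visits every 5-cm bin at least once per lap."""
        p = SimParams(n_blocks=1, block_s=60, pause_rate_hz=0.0)
        b = simulate_behavior(p, cfg, np.random.default_rng(2))
        unwrapped = np.cumsum(b.speed) * b.dt
        one_lap = unwrapped <= cfg.track_length_cm
        assert unwrapped[-1] > cfg.track_length_cm, "should complete a lap in 60 s"
        # at 10 Hz and < ~40 cm/s the track cannot be crossed in fewer
        # frames than bins, so each bin is entered
        bins = position_bins(b.position[one_lap], cfg.track_length_cm, 5.0)
        assert len(np.unique(bins)) == cfg.n_spatial_bins

    def test_contexts_alternate_and_gaps_separate(self, cfg):
        p = SimParams(n_blocks=4, block_s=30)
        b = simulate_behavior(p, cfg, np.random.default_rng(3))
        nongap = ~b.recording_gap
        assert set(np.unique(b.context_id[nongap])) == {"familiar", "novel"}
        fam = nongap & (b.context_id == "familiar")
        assert fam.sum() == pytest.approx(2 * 30 * cfg.fs_hz, abs=2)

    def test_speed_is_position_derivative(self, cfg):
        p = SimParams(n_blocks=1, block_s=30, pause_rate_hz=0.0)
        b = simulate_behavior(p, cfg, np.random.default_rng(5))
        unwrapped = np.cumsum(b.speed) * b.dt
        np.testing.assert_allclose(np.diff(unwrapped) / b.dt, b.speed[1:])
        np.testing.assert_allclose(np.mod(unwrapped, 400.0), b.position)

    def test_lap_mode_counts_laps(self, cfg):
        p = SimParams(block_mode="laps", n_blocks=2, laps_per_block=3)
        b = simulate_behavior(p, cfg, np.random.default_rng(6))
        for ctx in ("familiar", "novel"):
            sel = ~b.recording_gap & (b.context_id == ctx)
            assert len(np.unique(b.trial_index[sel])) == 3


class TestPopulation:
    def test_pure_positive_mixture(self, cfg):
        p = SimParams(n_cells=50, frac_speed_positive=1.0,
                      frac_speed_negative=0.0, frac_speed_none=0.0)
        gt = sample_population(p, cfg, np.random.default_rng(0))
        assert np.all(gt.speed_slope > 0)

    def test_zero_place_fraction(self, cfg):
        p = SimParams(n_cells=50, place_fraction=0.0)
        gt = sample_population(p, cfg, np.random.default_rng(0))
        assert np.all(gt.field_gain == 0)

    def test_negative_fraction_within_binomial_ci(self, cfg):
        """500 cells at 25% negative: observed fraction inside the 95% CI."""
        p = SimParams(n_cells=500, frac_speed_positive=0.5,
                      frac_speed_negative=0.25, frac_speed_none=0.25)
        gt = sample_population(p, cfg, np.random.default_rng(7))
        frac = np.mean(gt.speed_slope < 0)
        lo, hi = stats.binom.interval(0.95, 500, 0.25)
        assert lo / 500 <= frac <= hi / 500

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimParams(frac_speed_positive=0.5, frac_speed_negative=0.5,
                      frac_speed_none=0.5)


class TestSpikes:
    def _flat_behavior(self, cfg, duration_s, speed=0.0):
        n = int(duration_s * cfg.fs_hz)
        from hippotune import BehaviorTrace
        return BehaviorTrace(
            t=np.arange(n) / cfg.fs_hz, position=np.zeros(n),
            speed=np.full(n, speed), context_id=np.full(n, "familiar"),
            trial_index=np.zeros(n, int), recording_gap=np.zeros(n, bool),
        )

    def _gt(self, baseline, n=1):
        z = np.zeros(n)
        return GroundTruth(baseline_rate=np.full(n, float(baseline)),
                           speed_slope=z.copy(), field_center=z.copy(),
                           field_width=np.full(n, 40.0), field_gain=z.copy(),
                           context_gain=np.ones(n))

    def test_zero_rate_no_spikes(self, cfg):
        beh = self._flat_behavior(cfg, 50)
        gt = simulate_spikes(beh, self._gt(0.0), np.random.default_rng(0))
        assert gt.spike_times[0].size == 0

    def test_constant_rate_poisson_count(self, cfg):
        """Rate 5/s over 100 s: count within [400, 600] (P > 0.99)."""
        beh = self._flat_behavior(cfg, 100)
        gt = simulate_spikes(beh, self._gt(5.0), np.random.default_rng(1))
        assert 400 <= gt.spike_times[0].size <= 600

    def test_zero_context_gain_silences_novel(self, cfg):
        n = 600
        from hippotune import BehaviorTrace
        beh = BehaviorTrace(
            t=np.arange(n) / 10.0, position=np.zeros(n), speed=np.zeros(n),
            context_id=np.array(["familiar"] * 300 + ["novel"] * 300),
            trial_index=np.r_[np.zeros(300, int), np.ones(300, int)],
            recording_gap=np.zeros(n, bool),
        )
        gt = self._gt(5.0)
        gt.context_gain[:] = 0.0
        gt = simulate_spikes(beh, gt, np.random.default_rng(2))
        assert np.all(gt.spike_times[0] < 30.0)

    def test_doubling_duration_halves_rate_error(self, cfg):
        """Sampling error of the empirical rate scales as 1/sqrt(T)."""
        errs = []
        for dur in (100, 400):
            counts = [
                simulate_spikes(self._flat_behavior(cfg, dur), self._gt(2.0),
                                np.random.default_rng(s)).spike_times[0].size / dur
                for s in range(40)
            ]
            errs.append(np.std(counts))
        assert errs[1] == pytest.approx(errs[0] / 2, rel=0.5)


class TestFluorescence:
    def test_no_spikes_no_noise_constant_baseline(self):
        noise = NoiseModel(drift_amplitude=0.0, shot_noise_sd=0.0,
                           photon_baseline=50.0)
        tr = render_fluorescence([np.empty(0)], noise, fs=10.0, n_frames=100,
                                 rng=np.random.default_rng(0))
        np.testing.assert_allclose(tr.raw_f, 50.0)

    def test_single_spike_matches_kernel_closed_form(self):
        """One spike at t=2 s reproduces B*(1 + k(t - 2)) exactly."""
        noise = NoiseModel(drift_amplitude=0.0, shot_noise_sd=0.0,
                           photon_baseline=100.0)
        tr = render_fluorescence([np.array([2.0])], noise, fs=10.0,
                                 n_frames=100, rng=np.random.default_rng(0))
        t = np.arange(100) / 10.0
        expected = 100.0 * (1.0 + _kernel(t - 2.0, 0.1, 0.7))
        np.testing.assert_allclose(tr.raw_f[0], expected, rtol=1e-9, atol=1e-6)
        peak_t = t[np.argmax(tr.raw_f[0])]
        t_star = 0.1 * 0.7 / 0.6 * np.log(7.0)  # analytic kernel peak time
        assert abs(peak_t - 2.0 - t_star) <= 0.1  # within one frame

    def test_same_seed_bit_identical(self):
        noise = NoiseModel()
        spikes = [np.array([1.0, 2.5])]
        a = render_fluorescence(spikes, noise, 10.0, 200, np.random.default_rng(9))
        b = render_fluorescence(spikes, noise, 10.0, 200, np.random.default_rng(9))
        np.testing.assert_array_equal(a.raw_f, b.raw_f)

    def test_kernel_decay_must_exceed_rise(self):
        with pytest.raises(ValueError):
            NoiseModel(kernel_rise=0.7, kernel_decay=0.1)


def test_simulate_session_deterministic(cfg):
    p = SimParams(n_cells=3, n_blocks=2, block_s=20)
    s1, gt1 = simulate_session(p, cfg, seed=42)
    s2, gt2 = simulate_session(p, cfg, seed=42)
    np.testing.assert_array_equal(s1.traces.raw_f, s2.traces.raw_f)
    np.testing.assert_array_equal(gt1.speed_slope, gt2.speed_slope)
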