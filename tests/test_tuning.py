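"""Speed-modulation and spatial-tuning metrics against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from hippotune import (SpatialMap, move_immobile_ratio, spatial_coherence,
                       spatial_information, speed_tuning, vector_tuning,
                       within_session_stability)


def si_oracle(lam, p):
    """Literal per-bin transcription of SI = sum_i lam_i log2(lam_i/lam) p_i."""
    lam_bar = sum(li * pi for li, pi in zip(lam, p))
    total = 0.0
    for li, pi in zip(lam, p):
        if li > 0:
            total += li * math.log2(li / lam_bar) * pi
    return total


def make_map(lam, p=None, circular=True, bin_w=5.0):
    lam = np.asarray(lam, dtype=float)
    n = len(lam)
    p = np.full(n, 1.0 / n) if p is None else np.asarray(p, dtype=float)
    edges = bin_w * np.arange(n + 1)
    lam_bar = float(np.nansum(p * np.nan_to_num(lam)))
    return SpatialMap(bin_edges=edges, lambda_i=lam, p_i=p,
                      lambda_bar=lam_bar, circular=circular)


class TestSpatialInformation:
    def test_uniform_map_zero_information(self):
        assert spatial_information(make_map(np.full(80, 2.5))) == pytest.approx(0.0)

    def test_two_bin_analytic_case(self):
        """p = (1/2, 1/2), lam = (2, 0): lam_bar = 1 and SI = 1 bit."""
        m = make_map([2.0, 0.0], p=[0.5, 0.5])
        assert spatial_information(m) == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**20))
    def test_matches_literal_oracle(self, seed):
        """Pipeline SI equals the brute-force per-bin summation to 1e-10."""
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 81)
        lam = rng.gamma(1.0, 1.0, size=n)
        p = rng.dirichlet(np.ones(n))
        m = make_map(lam, p=p)
        assert spatial_information(m) == pytest.approx(
            si_oracle(lam, p), abs=1e-10)

    def test_nonnegative_and_zero_iff_uniform(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 40))
            m = make_map(rng.gamma(1.0, 2.0, size=n), p=rng.dirichlet(np.ones(n)))
            assert spatial_information(m) >= -1e-12

    def test_rescaling_scales_si_but_not_normalized_si(self, rng):
        lam = rng.gamma(1.0, 1.0, size=40)
        p = rng.dirichlet(np.ones(40))
        si1 = spatial_information(make_map(lam, p=p))
        si3 = spatial_information(make_map(3 * lam, p=p))
        assert si3 == pytest.approx(3 * si1, rel=1e-10)
        n1 = spatial_information(make_map(lam, p=p), normalize=True)
        n3 = spatial_information(make_map(3 * lam, p=p), normalize=True)
        assert n3 == pytest.approx(n1, rel=1e-10)

    def test_inactive_cell_flagged_nan(self):
        assert np.isnan(spatial_information(make_map(np.zeros(10))))

    def test_negative_bin_means_clamped(self):
        m = make_map([-1.0, 2.0, 0.0, 0.0], p=[0.25] * 4)
        clamped = make_map([0.0, 2.0, 0.0, 0.0], p=[0.25] * 4)
        assert spatial_information(m) == pytest.approx(
            spatial_information(clamped))


class TestCoherence:
    def test_smooth_sinusoid_is_coherent(self):
        theta = 2 * np.pi * np.arange(80) / 80
        m = make_map(2.0 + np.cos(theta))
        assert spatial_coherence(m) > 0.95

    def test_iid_noise_is_incoherent(self):
        rs = [spatial_coherence(make_map(np.random.default_rng(s).random(80)))
              for s in range(50)]
        assert abs(np.mean(rs)) < 0.1

    def test_constant_map_undefined(self):
        assert np.isnan(spatial_coherence(make_map(np.ones(80))))

    def test_wraparound_only_on_circular_track(self):
        lam = np.zeros(80)
        lam[0], lam[79] = 5.0, 5.0  # adjacent only through the seam
        assert spatial_coherence(make_map(lam, circular=True)) > \
            spatial_coherence(make_map(lam, circular=False))


class TestVectorTuning:
    def test_single_active_bin(self):
        lam = np.zeros(80)
        lam[20] = 4.0  # bin center 102.5 cm of 400 -> angle ~ pi/2
        length, angle = vector_tuning(make_map(lam))
        assert length == pytest.approx(1.0)
        assert angle == pytest.approx(2 * np.pi * 102.5 / 400)

    def test_uniform_map_zero_length(self):
        length, _ = vector_tuning(make_map(np.full(80, 1.0)))
        assert length == pytest.approx(0.0, abs=1e-12)

    def test_von_mises_length_matches_bessel_ratio(self):
        """Map lam ~ exp(kappa cos) gives resultant length I1(k)/I0(k)."""
        theta = 2 * np.pi * (np.arange(80) + 0.5) / 80
        for kappa in (0.5, 2.0, 5.0):
            lam = np.exp(kappa * np.cos(theta - 1.0))
            length, angle = vector_tuning(make_map(lam))
            assert length == pytest.approx(
                special.i1(kappa) / special.i0(kappa), rel=1e-3)
            assert angle == pytest.approx(1.0, abs=1e-6)

    def test_rotation_shifts_angle_not_length(self, rng):
        lam = rng.gamma(1.0, 1.0, size=80)
        l0, a0 = vector_tuning(make_map(lam))
        shift = 10  # bins = 50 cm = pi/4
        l1, a1 = vector_tuning(make_map(np.roll(lam, shift)))
        assert l1 == pytest.approx(l0, rel=1e-10)
        assert (a1 - a0) % (2 * np.pi) == pytest.approx(2 * np.pi * shift / 80,
                                                        abs=1e-9)

    def test_all_zero_map_undefined(self):
        length, angle = vector_tuning(make_map(np.zeros(80)))
        assert np.isnan(length) and np.isnan(angle)


class TestStability:
    def test_identical_halves_unity(self, rng):
        lam = rng.random(80)
        assert within_session_stability(make_map(lam), make_map(lam)) == \
            pytest.approx(1.0)

    def test_sign_flip_is_minus_one(self, rng):
        lam = rng.random(80)
        flipped = 2 * lam.mean() - lam
        assert within_session_stability(make_map(lam), make_map(flipped)) == \
            pytest.approx(-1.0)

    def test_joint_occupancy_required(self):
        a = make_map(np.r_[np.ones(3), np.full(77, np.nan)],
                     p=np.r_[np.full(3, 1 / 3), np.zeros(77)])
        b = make_map(np.ones(80))
        assert np.isnan(within_session_stability(a, b))


class TestSpeedTuning:
    def test_exact_linear_input(self):
        rng = np.random.default_rng(0)
        speed = rng.uniform(2, 30, size=3000)
        dff = 0.1 * speed
        st_res = speed_tuning(dff, speed, np.ones(3000, bool))
        # binned means sit at in-bin mean speeds, not exactly at centers
        assert st_res.slope == pytest.approx(0.1, rel=1e-2)
        assert st_res.pearson_r == pytest.approx(1.0)
        assert st_res.modulation_class == "positive"

    def test_null_false_positive_rate_near_alpha(self):
        """Speed-independent dF/F is classed 'none' except ~alpha of runs."""
        flagged = 0
        n_rep = 200
        for s in range(n_rep):
            rng = np.random.default_rng(1000 + s)
            speed = rng.uniform(2, 30, size=400)
            dff = rng.standard_normal(400)
            r = speed_tuning(dff, speed, np.ones(400, bool))
            flagged += r.modulation_class != "none"
        lo, hi = stats.binom.interval(0.999, n_rep, 0.05)
        assert lo <= flagged <= hi

    def test_negative_slope_sign_recovered(self):
        rng = np.random.default_rng(2)
        speed = rng.uniform(2, 30, size=2000)
        dff = 1.0 - 0.02 * speed + 0.1 * rng.standard_normal(2000)
        r = speed_tuning(dff, speed, np.ones(2000, bool))
        assert r.modulation_class == "negative"
        assert r.slope == pytest.approx(-0.02, rel=0.2)

    def test_sparse_bins_dropped(self):
        """Speed bins occupied under 1 s do not enter the binned fit."""
        speed = np.r_[np.full(50, 5.2), np.full(50, 9.7), np.full(3, 29.5)]
        dff = np.r_[np.full(50, 1.0), np.full(50, 2.0), np.full(3, 99.0)]
        r = speed_tuning(dff, speed, np.ones(103, bool))
        assert 29.5 not in r.bin_centers
        assert len(r.bin_centers) == 2

    def test_single_occupied_bin_flagged_invalid(self):
        r = speed_tuning(np.ones(50), np.full(50, 10.2), np.ones(50, bool))
        assert not r.valid


class TestMoveImmobileRatio:
    def test_equal_means_unity(self):
        act = np.ones(100)
        m = np.zeros(100, bool)
        m[:50] = True
        assert move_immobile_ratio(act, m, ~m) == pytest.approx(1.0)

    def test_immobility_preferring_cell_below_one(self):
        """Moving mean 2 vs immobile mean 4 gives ratio 0.5."""
        act = np.r_[np.full(50, 2.0), np.full(50, 4.0)]
        m = np.r_[np.ones(50, bool), np.zeros(50, bool)]
        assert move_immobile_ratio(act, m, ~m) == pytest.approx(0.5)

    def test_no_immobile_frames_undefined(self):
        act = np.ones(100)
        assert np.isnan(move_immobile_ratio(act, np.ones(100, bool),
                                            np.zeros(100, bool)))
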