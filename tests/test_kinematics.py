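"""Kinematic metric extraction against analytic and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluokin.kinematics import (Track, count_extreme_jerk_peaks,
                                curvature_and_dispersion, differentiate,
                                jerk_integral, mode_times, pathlength,
                                position_density, straightness_index)
from tests.conftest import make_min_jerk_track, straight_track


def track_from_xyz(t, x, y=None, z=None, mode=None):
    n = len(t)
    zeros = np.zeros(n)
    return Track(
        t_s=t, x_mm=x, y_mm=zeros if y is None else y,
        z_mm=zeros if z is None else z,
        mode=np.zeros(n, int) if mode is None else mode,
    )


# ---------------------------------------------------------------------------
# differentiate
# ---------------------------------------------------------------------------

class TestDifferentiate:
    def test_linear_motion_velocity_exact(self):
        # x = 2t m -> velocity (2, 0, 0) m/s, jerk 0 (polynomial exactness)
        t = np.arange(100) / 50.0
        tr = track_from_xyz(t, 2000.0 * t)
        vel = differentiate(tr, 1)
        assert np.allclose(vel, [[2.0, 0.0, 0.0]], atol=1e-9)
        assert np.allclose(differentiate(tr, 3), 0.0, atol=1e-6)

    def test_quadratic_motion_acceleration_exact(self):
        t = np.arange(100) / 50.0
        tr = track_from_xyz(t, 1000.0 * t**2)
        acc = differentiate(tr, 2)
        assert np.allclose(acc, [[2.0, 0.0, 0.0]], atol=1e-8)

    def test_min_jerk_third_derivative_matches_analytic(self):
        # jerk of D*(10 tau^3 - 15 tau^4 + 6 tau^5) is D/T^3 (60 - 360 tau + 360 tau^2)
        D_m, T, rate = 0.1, 1.0, 100.0
        tr = make_min_jerk_track(100.0, T, rate)
        jerk = differentiate(tr, 3)[:, 0]
        tau = tr.t_s / T
        analytic = D_m / T**3 * (60 - 360 * tau + 360 * tau**2)
        interior = slice(10, -10)
        rel = np.abs(jerk[interior] - analytic[interior]) / np.max(np.abs(analytic))
        assert np.max(rel) < 0.02

    def test_window_larger_than_track_rejected(self):
        tr = straight_track(n=5)
        with pytest.raises(ValueError, match="window"):
            differentiate(tr, 1, window=7)


# ---------------------------------------------------------------------------
# pathlength / straightness
# ---------------------------------------------------------------------------

class TestPathMetrics:
    def test_three_four_five_segment(self):
        tr = track_from_xyz(np.array([0.0, 1.0]), np.array([0.0, 3.0]),
                            y=np.array([0.0, 4.0]))
        assert pathlength(tr) == pytest.approx(0.005)

    def test_closed_square_perimeter_and_zero_displacement(self):
        x = np.array([0.0, 10, 10, 0, 0])
        y = np.array([0.0, 0, 10, 10, 0])
        tr = track_from_xyz(np.arange(5.0), x, y=y)
        assert pathlength(tr) == pytest.approx(0.04)
        assert straightness_index(tr) == pytest.approx(0.0)

    def test_pathlength_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(10, 100)
            pos = rng.normal(size=(n, 3)) * 50
            tr = track_from_xyz(np.arange(n) / 30.0, pos[:, 0], pos[:, 1], pos[:, 2])
            oracle = sum(
                float(np.sqrt(np.sum((pos[i + 1] - pos[i]) ** 2))) / 1000.0
                for i in range(n - 1)
            )
            assert pathlength(tr) == pytest.approx(oracle, rel=1e-12)

    def test_straight_segment_st_is_one(self):
        assert straightness_index(straight_track()) == pytest.approx(1.0)

    def test_semicircle_st_two_over_pi(self):
        theta = np.linspace(0, np.pi, 2000)
        tr = track_from_xyz(theta, 50 * np.cos(theta), y=50 * np.sin(theta))
        assert straightness_index(tr) == pytest.approx(2 / np.pi, rel=1e-5)

    def test_zero_pathlength_reported_missing(self):
        tr = track_from_xyz(np.arange(3.0), np.zeros(3))
        with pytest.warns(UserWarning):
            assert np.isnan(straightness_index(tr))


# ---------------------------------------------------------------------------
# jerk integral and dimensionless core
# ---------------------------------------------------------------------------

class TestJerkIntegral:
    def test_constant_velocity_zero(self):
        j, core = jerk_integral(straight_track(n=200))
        assert j == pytest.approx(0.0, abs=1e-12)
        assert core == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("amplitude,duration", [(50, 0.5), (100, 1.0), (300, 2.0)])
    def test_single_min_jerk_reach_core_is_720(self, amplitude, duration):
        tr = make_min_jerk_track(amplitude, duration, rate_hz=500)
        _, core = jerk_integral(tr)
        assert core == pytest.approx(720.0, rel=0.01)

    def test_two_sequential_reaches_match_numeric_oracle(self):
        # independent oracle: trapezoid over the exact analytic jerk
        tr = make_min_jerk_track(100.0, 1.0, rate_hz=500, n_reaches=2)
        D_m, T = 0.1, 1.0
        t = tr.t_s
        tau = np.where(t <= T, t / T, (t - T) / T)
        analytic_jerk = D_m / T**3 * (60 - 360 * tau + 360 * tau**2)
        oracle_J = np.trapezoid(analytic_jerk**2, t)
        s = 2 * D_m
        dt_total = t[-1] - t[0]
        oracle_core = oracle_J * dt_total**5 / s**2
        _, core = jerk_integral(tr)
        assert core == pytest.approx(oracle_core, rel=0.01)

    @pytest.mark.parametrize("amplitude,duration",
                             [(20, 0.3), (50, 0.7), (100, 1.0), (250, 1.7), (400, 3.0)])
    def test_core_scale_invariance(self, amplitude, duration):
        # dimensionless core of a fixed shape is invariant to spatial and
        # temporal scaling (same number of samples, so the same discretization)
        n_samples = 500
        tr = make_min_jerk_track(amplitude, duration, rate_hz=n_samples / duration)
        _, core = jerk_integral(tr)
        ref = make_min_jerk_track(100.0, 1.0, rate_hz=float(n_samples))
        _, ref_core = jerk_integral(ref)
        assert core == pytest.approx(ref_core, rel=1e-6)

    def test_jerk_integral_matches_brute_force_on_random_tracks(self):
        # brute force: trapezoid over an independently computed Savitzky-Golay
        # derivative obtained by explicit local polynomial fits
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = 60
            t = np.arange(n) / 30.0
            pos = np.cumsum(rng.normal(size=(n, 3)), axis=0) * 5
            tr = track_from_xyz(t, pos[:, 0], pos[:, 1], pos[:, 2])
            jerk = np.empty((n, 3))
            w, half = 7, 3
            dt = 1 / 30.0
            for i in range(n):
                lo = min(max(i - half, 0), n - w)
                idx = np.arange(lo, lo + w)
                for ax in range(3):
                    coef = np.polyfit((idx - i) * dt, pos[idx, ax] / 1000.0, 3)
                    jerk[i, ax] = 6 * coef[0]
            oracle = np.trapezoid(np.sum(jerk**2, axis=1), t)
            got, _ = jerk_integral(tr)
            assert got == pytest.approx(oracle, rel=1e-9)


# ---------------------------------------------------------------------------
# extreme jerk peaks
# ---------------------------------------------------------------------------

class TestExtremeJerkPeaks:
    def test_smooth_slow_track_has_none(self):
        tr = make_min_jerk_track(100, 1.0, rate_hz=100)
        assert count_extreme_jerk_peaks(tr) == 0

    @staticmethod
    def _pulse_track(peak_jerk: float, n: int = 2000, rate: float = 200.0,
                     centers=(2.00125, 5.00125, 8.00125)):
        # synthesize the jerk signal (isolated Gaussian pulses, centres offset
        # a quarter sample so the discrete maximum is not a tied pair) and
        # integrate three times to position: each pulse is one strict peak
        dt = 1.0 / rate
        t = np.arange(n) * dt
        jerk = np.zeros(n)
        for t0 in centers:
            jerk += peak_jerk * np.exp(-((t - t0) ** 2) / (2 * 0.05**2))
        x_m = np.cumsum(np.cumsum(np.cumsum(jerk) * dt) * dt) * dt
        return track_from_xyz(t, x_m * 1000.0)

    def test_injected_jerk_pulses_counted(self):
        tr = self._pulse_track(peak_jerk=3e5)
        assert count_extreme_jerk_peaks(tr) == 3

    def test_sub_threshold_pulses_not_counted(self):
        tr = self._pulse_track(peak_jerk=5e4)  # below the 1e5 m/s^3 default
        assert count_extreme_jerk_peaks(tr) == 0

    def test_plateau_has_no_strict_maximum(self):
        # constant super-threshold jerk (cubic position) is a plateau: no
        # strict local maxima, so the count is zero by the boundary rule
        n, rate = 300, 100.0
        t = np.arange(n) / rate
        c = 2e5 / 6.0  # jerk = 6c = 2e5 m/s^3, constant
        tr = track_from_xyz(t, c * t**3 * 1000.0)
        jerk_mag = np.abs(differentiate(tr, 3)[:, 0])
        assert jerk_mag.min() > 1e5
        assert count_extreme_jerk_peaks(tr) == 0


# ---------------------------------------------------------------------------
# curvature and angular dispersion
# ---------------------------------------------------------------------------

class TestCurvatureDispersion:
    def test_straight_line_zero(self):
        cr, ad = curvature_and_dispersion(straight_track())
        assert cr == pytest.approx(0.0, abs=1e-9)
        assert ad == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("radius_mm", [50.0, 200.0])
    def test_circle_curvature_reciprocal_radius(self, radius_mm):
        theta = np.linspace(0, 2 * np.pi, 3000)
        tr = track_from_xyz(theta, radius_mm * np.cos(theta),
                            y=radius_mm * np.sin(theta))
        cr, _ = curvature_and_dispersion(tr)
        assert cr == pytest.approx(1.0 / (radius_mm / 1000.0), rel=0.01)

    def test_isotropic_walk_dispersion_near_one(self):
        rng = np.random.default_rng(1)
        steps = rng.normal(size=(10_000, 3))
        pos = np.cumsum(steps, axis=0)
        tr = track_from_xyz(np.arange(len(pos)) / 30.0,
                            pos[:, 0], pos[:, 1], pos[:, 2])
        _, ad = curvature_and_dispersion(tr)
        assert ad == pytest.approx(1.0, abs=0.05)


# ---------------------------------------------------------------------------
# times and density
# ---------------------------------------------------------------------------

class TestTimesAndDensity:
    def test_all_firefly_saturates(self):
        n = 50
        tr = track_from_xyz(np.arange(n) / 10.0, np.arange(n, dtype=float),
                            mode=np.ones(n, int))
        t_task, t_ff = mode_times(tr)
        assert t_ff == pytest.approx(t_task)

    def test_no_firefly_zero(self):
        _, t_ff = mode_times(straight_track())
        assert t_ff == 0.0

    def test_alternating_blocks_half(self):
        rate = 30
        n = 10 * rate
        t = np.arange(n) / rate
        mode = (np.floor(t) % 2).astype(int)
        tr = track_from_xyz(t, np.zeros(n) + np.arange(n) * 0.01, mode=mode)
        t_task, t_ff = mode_times(tr)
        assert abs(t_ff - t_task / 2) <= 1.5 / rate

    def test_stationary_track_single_bin(self):
        tr = track_from_xyz(np.arange(10.0), np.full(10, 5.0), y=np.full(10, 5.0))
        dens, _, _ = position_density(tr)
        assert dens.size == 1
        assert dens[0, 0] == pytest.approx(100.0)

    def test_density_sums_to_100(self, cohort40):
        dens, _, _ = position_density(cohort40[0].track)
        assert dens.sum() == pytest.approx(100.0, abs=1e-9)

    def test_uniform_line_across_four_bins(self):
        n = 400
        t = np.arange(n) / 100.0
        x = np.linspace(0, 40, n, endpoint=False)
        tr = track_from_xyz(t, x)
        dens, _, _ = position_density(tr, bin_size_mm=10.0)
        col = dens[:, 0]
        assert dens.shape[0] == 4
        assert np.all(np.abs(col - 25.0) <= 100.0 / n + 1e-9)


# ---------------------------------------------------------------------------
# invariants (property tests)
# ---------------------------------------------------------------------------

@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1), n=st.integers(10, 200))
def test_st_and_ad_within_bounds_on_random_tracks(seed, n):
    rng = np.random.default_rng(seed)
    pos = np.cumsum(rng.normal(size=(n, 3)), axis=0) * 10
    tr = track_from_xyz(np.arange(n) / 30.0, pos[:, 0], pos[:, 1], pos[:, 2])
    st_idx = straightness_index(tr)
    _, ad = curvature_and_dispersion(tr)
    assert 0 < st_idx <= 1 + 1e-12
    assert -1e-12 <= ad <= 1 + 1e-12


def test_track_rejects_duplicate_timestamps():
    with pytest.raises(ValueError, match="strictly increasing"):
        Track(t_s=[0.0, 1.0, 1.0], x_mm=[0, 1, 2], y_mm=[0, 0, 0],
              z_mm=[0, 0, 0], mode=[0, 0, 0])
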