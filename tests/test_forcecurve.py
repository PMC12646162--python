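import math

import numpy as np
import pytest
from scipy import integrate

from trichomech import forcecurve as fc
from trichomech import synthio
from trichomech.trajectory import TrackedTrajectory


def brute_force_changepoint(t, s, min_seg=5):
    """Independent oracle: naive polyfit at every split, no prefix sums."""
    best = (None, np.inf)
    for b in range(min_seg, len(t) - min_seg + 1):
        sse = 0.0
        for sl in (slice(0, b), slice(b, len(t))):
            coef = np.polyfit(t[sl], s[sl], 1)
            sse += float(np.sum((s[sl] - np.polyval(coef, t[sl])) ** 2))
        if sse < best[1] - 1e-12:
            best = (b, sse)
    return best


class TestSegmentation:
    def test_zero_noise_breakpoint_exact(self, noiseless_scenario):
        traj, truth = synthio.gen_rupture_trajectory(noiseless_scenario)
        seg = fc.segment_trajectory(traj)
        assert seg.t_contact == truth.t_contact
        assert seg.free_slope == pytest.approx(33.0, rel=1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for trial in range(10):
            n = 200
            t = np.arange(n) * 0.02
            b_true = rng.integers(40, 160)
            s = np.where(np.arange(n) < b_true, 30.0 * t,
                         30.0 * t[b_true] + 12.0 * (t - t[b_true]))
            s = s + rng.normal(0, 0.1, n)
            traj = TrackedTrajectory(t, s, np.zeros(n))
            seg = fc.segment_trajectory(traj, truncate_at_rupture=False)
            b_oracle, sse_oracle = brute_force_changepoint(t, s)
            assert seg.idx_contact == b_oracle
            assert seg.sse == pytest.approx(sse_oracle, rel=1e-6, abs=1e-9)

    def test_contact_within_2_frames_under_noise(self):
        """Tracking noise 0.1 μm on a representative measurement (soft
        pipette, mid-range rupture force): contact onset lands within 2
        frames of the generator's in at least 95% of 200 seeded noise
        realizations."""
        hits = 0
        for seed in range(200):
            sc = synthio.RuptureScenario(k_true=0.1, F_r_true=6.0, seed=seed,
                                         noise_sd=0.1)
            traj, truth = synthio.gen_rupture_trajectory(sc)
            seg = fc.segment_trajectory(traj)
            dt = 1.0 / sc.frame_rate
            hits += abs(seg.t_contact - truth.t_contact) <= 2 * dt + 1e-12
        assert hits >= 0.95 * 200

    def test_no_contact_raises(self):
        t = np.arange(100) * 0.02
        traj = TrackedTrajectory(t, 33.0 * t + np.random.default_rng(1).normal(0, 0.05, 100),
                                 np.zeros(100))
        with pytest.raises(fc.NoContactError):
            fc.segment_trajectory(traj)


class TestForceSeries:
    def test_force_is_k_times_deficit(self, noiseless_scenario):
        traj, truth = synthio.gen_rupture_trajectory(noiseless_scenario)
        seg = fc.segment_trajectory(traj)
        curve = fc.force_series(traj, seg, 0.04)
        # Δx = 25 μm → F = 1 μN at k = 0.04
        i = int(np.argmin(np.abs(curve.force / 0.04 - 25.0)))
        assert curve.force[i] == pytest.approx(0.04 * 25.0, rel=1e-6)

    def test_zero_deficit_gives_zero_force(self):
        t = np.arange(200) * 0.02
        x = 33.0 * t.copy()
        x[100:] = 33.0 * t[100] + 10.0 * (t[100:] - t[100])  # pure two-slope
        traj = TrackedTrajectory(t, x, np.zeros(200))
        seg = fc.segment_trajectory(traj, truncate_at_rupture=False)
        curve = fc.force_series(traj, seg, 1.0)
        assert curve.force[0] == pytest.approx(0.0, abs=1e-9)

    def test_round_trip_at_top_of_force_range(self):
        sc = synthio.RuptureScenario(k_true=0.5, F_r_true=24.0, noise_sd=0.0, seed=0)
        traj, truth = synthio.gen_rupture_trajectory(sc)
        curve = fc.analyze_trajectory(traj, sc.k_true)
        assert curve.F_r == pytest.approx(truth.F_r, rel=1e-9)
        assert truth.F_r == pytest.approx(24.0, rel=0.05)  # grid-snapped draw


class TestRuptureDetection:
    def _sawtooth(self, peak=6.0, residual=0.0):
        t = np.arange(60) * 0.1
        F = np.concatenate([np.linspace(0, peak, 40),
                            np.full(20, residual)])
        return fc.ForceCurve(times=t, force=F, t_contact=0.0, k_used=1.0,
                             free_slope=33.0)

    def test_sawtooth_apex(self):
        curve = fc.detect_rupture(self._sawtooth(peak=6.0))
        assert curve.F_r == pytest.approx(6.0)
        assert curve.i_r == 39

    def test_residual_sticking_force_tolerated(self):
        curve = fc.detect_rupture(self._sawtooth(peak=6.0, residual=0.3))
        assert curve.F_r == pytest.approx(6.0)

    def test_no_drop_raises(self):
        t = np.arange(50) * 0.1
        curve = fc.ForceCurve(times=t, force=np.linspace(0, 5, 50),
                              t_contact=0.0, k_used=1.0, free_slope=33.0)
        with pytest.raises(fc.NoRuptureError):
            fc.detect_rupture(curve)

    def test_recovery_error_under_noise(self):
        """Across the manufactured k range and observed force range, mean
        absolute relative rupture-force error < 5% at 0.1 μm tracking noise."""
        errs = []
        for seed in range(200):
            sc = synthio.RuptureScenario(seed=seed, noise_sd=0.1)
            traj, truth = synthio.gen_rupture_trajectory(sc)
            curve = fc.analyze_trajectory(traj, sc.k_true)
            errs.append(abs(curve.F_r - truth.F_r) / truth.F_r)
        assert np.mean(errs) < 0.05

    def test_post_slope_matches_free_slope(self):
        """After rupture the tip resumes its free speed: refit post slope
        agrees with the free slope within 3 standard errors."""
        devs = []
        for seed in range(20):
            sc = synthio.RuptureScenario(seed=seed, noise_sd=0.1)
            traj, _ = synthio.gen_rupture_trajectory(sc)
            curve = fc.analyze_trajectory(traj, sc.k_true)
            devs.append(curve.post_slope - curve.free_slope)
        devs = np.array(devs)
        se = devs.std(ddof=1) / math.sqrt(len(devs))
        assert abs(devs.mean()) < 3 * se + 1e-9


class TestRescaleCollapse:
    def test_rupture_point_is_one_one(self, noiseless_scenario):
        traj, _ = synthio.gen_rupture_trajectory(noiseless_scenario)
        curve = fc.analyze_trajectory(traj, noiseless_scenario.k_true)
        ts, fs = fc.rescale_curve(curve)
        assert ts[-1] == 1.0
        assert fs[-1] == 1.0

    def test_linear_loading_rescales_to_identity(self):
        for c in (0.5, 2.0, 7.0):
            t = np.arange(50) * 0.1
            F = np.concatenate([c * t[:45], [0.0] * 5])
            curve = fc.ForceCurve(times=t, force=F, t_contact=0.0, k_used=1.0,
                                  free_slope=33.0)
            fc.detect_rupture(curve)
            ts, fs = fc.rescale_curve(curve)
            assert np.allclose(fs, ts, atol=1e-12)

    def test_different_k_and_rate_collapse_identically(self):
        curves = []
        for k, rate in ((0.1, 1.0), (0.8, 5.0)):
            sc = synthio.RuptureScenario(k_true=k, F_r_true=10.0,
                                         loading_rate=rate, noise_sd=0.0, seed=0)
            traj, _ = synthio.gen_rupture_trajectory(sc)
            curves.append(fc.analyze_trajectory(traj, k))
        grid, mean, sd = fc.collapse_ensemble(curves, n_grid=51)
        assert np.all(sd < 1e-9)

    def test_identical_curves_zero_band(self, noiseless_scenario):
        traj, _ = synthio.gen_rupture_trajectory(noiseless_scenario)
        curve = fc.analyze_trajectory(traj, noiseless_scenario.k_true)
        grid, mean, sd = fc.collapse_ensemble([curve, curve, curve])
        assert np.allclose(sd, 0.0, atol=1e-12)
        assert mean[-1] == pytest.approx(1.0)
        assert sd[-1] == 0.0

    def test_band_width_consistent_with_noise(self):
        curves = []
        for seed in range(30):
            sc = synthio.RuptureScenario(seed=seed, noise_sd=0.1)
            traj, _ = synthio.gen_rupture_trajectory(sc)
            curves.append(fc.analyze_trajectory(traj, sc.k_true))
        grid, mean, sd = fc.collapse_ensemble(curves)
        # loading is linear for every curve, so the mean collapses onto the
        # identity line and the band is narrow
        assert np.max(np.abs(mean - grid)) < 0.1
        assert np.median(sd) < 0.1


class TestTorqueStress:
    def test_perpendicular_lever(self):
        ev = fc.torque_and_stress(6.0, 10.0, math.pi / 2, 5.0)
        assert ev.torque == pytest.approx(60.0)

    def test_parallel_force_no_torque(self):
        ev = fc.torque_and_stress(6.0, 10.0, 0.0, 5.0)
        assert ev.torque == 0.0
        assert ev.critical_stress == 0.0

    def test_unit_stress_case(self):
        ev = fc.torque_and_stress(math.pi / 4 / 10.0, 10.0, math.pi / 2, 1.0)
        assert ev.critical_stress == pytest.approx(1.0, rel=1e-12)

    def test_second_moment_matches_quadrature(self):
        """I_z = πR⁴/4 against 2-D quadrature of ∫ y² dA over the disc."""
        R = 2.0
        val, _ = integrate.dblquad(
            lambda y, x: y * y,
            -R, R,
            lambda x: -math.sqrt(max(R * R - x * x, 0.0)),
            lambda x: math.sqrt(max(R * R - x * x, 0.0)),
        )
        assert fc.second_moment_area(R) == pytest.approx(val, rel=1e-6)
        assert fc.second_moment_area(R) == pytest.approx(4 * math.pi, rel=1e-12)

    def test_stress_cubic_in_radius(self):
        ev1 = fc.torque_and_stress(6.0, 10.0, math.pi / 2, 5.0)
        ev2 = fc.torque_and_stress(6.0, 10.0, math.pi / 2, 10.0)
        assert ev2.critical_stress == pytest.approx(ev1.critical_stress / 8,
                                                    rel=1e-12)

    def test_torque_maximal_at_right_angle(self):
        taus = [fc.torque_and_stress(6.0, 10.0, th, 5.0).torque
                for th in np.linspace(0, math.pi, 31)]
        assert np.argmax(taus) == 15

    def test_zero_radius_rejected(self):
        with pytest.raises(ValueError):
            fc.second_moment_area(0.0)
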