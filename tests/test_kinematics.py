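"""Fusion and behavioral metrics in the wind frame."""

import numpy as np
import pytest

from entotaxis import (
    EncounterSeries,
    Trajectory,
    amplitude_velocity_relation,
    detect_casts,
    fuse,
    intensity_map,
    localization_outcome,
    translational_velocity,
    wind_frame_ratios,
)


def straight_run(speed_mm_s=15.0, heading_deg=180.0, start=(150.0, 0.0),
                 duration=12.0, dt=0.01):
    t = np.arange(0.0, duration + 1e-9, dt)
    h = np.radians(heading_deg)
    x = start[0] + speed_mm_s * t * np.cos(h)
    y = start[1] + speed_mm_s * t * np.sin(h)
    return Trajectory(t, x, y)


class TestFuse:
    def test_on_grid_positions_unchanged(self):
        traj = straight_run(duration=2.0)
        fused = fuse(traj, dt_s=0.01)
        assert fused.x == pytest.approx(traj.x, abs=1e-9)

    def test_intensity_zero_order_hold(self):
        traj = straight_run(duration=10.0)
        enc = EncounterSeries(np.array([5.0]), 0.0, 10.0,
                              amplitudes_mv=np.array([2.0]))
        fused = fuse(traj, enc)
        assert np.all(fused.intensity[fused.t < 5.0] == 0.0)
        assert np.all(fused.intensity[fused.t >= 5.0] == 1.0)
        assert np.all(fused.amplitude_mv[fused.t >= 5.0] == 2.0)

    def test_downsample_refuse_interpolation_error_small(self):
        traj = straight_run(duration=10.0)
        coarse = Trajectory(traj.t[::10], traj.x[::10], traj.y[::10])
        fused = fuse(coarse, dt_s=0.01)
        ref = fuse(traj, dt_s=0.01)
        n = min(len(fused), len(ref))
        err = np.hypot(fused.x[:n] - ref.x[:n], fused.y[:n] - ref.y[:n])
        assert np.max(err) < 0.5

    def test_disjoint_ranges_rejected(self):
        traj = straight_run(duration=2.0)
        enc = EncounterSeries(np.array([50.0]), 50.0, 60.0)
        with pytest.raises(ValueError):
            fuse(traj, enc)


class TestTranslationalVelocity:
    def test_straight_run_speed_recovered(self):
        fused = fuse(straight_run(speed_mm_s=15.0))
        v = translational_velocity(fused)
        assert v == pytest.approx(15.0, abs=0.1)

    def test_stationary_is_zero(self):
        t = np.arange(0.0, 5.0, 0.01)
        fused = fuse(Trajectory(t, np.full_like(t, 30.0),
                                np.full_like(t, -10.0)))
        assert translational_velocity(fused) == pytest.approx(0.0, abs=1e-9)

    def test_circular_path_recovers_rho_omega(self):
        rho, omega = 50.0, 0.4   # mm, rad/s
        t = np.arange(0.0, 20.0, 0.01)
        traj = Trajectory(t, rho * np.cos(omega * t),
                          rho * np.sin(omega * t))
        v = translational_velocity(fuse(traj))
        interior = v[100:-100]
        assert interior == pytest.approx(rho * omega, rel=0.01)


class TestAmplitudeVelocity:
    def test_surge_on_strong_encounters(self):
        # fast straight segment while amplitude 2 mV, slow while 0.5 mV
        t = np.arange(0.0, 20.0, 0.01)
        x = np.where(t < 10.0, 150.0 - 5.0 * t, 100.0 - 25.0 * (t - 10.0))
        traj = Trajectory(t, x, np.zeros_like(t))
        enc = EncounterSeries(np.array([0.0, 10.0]), 0.0, 20.0,
                              amplitudes_mv=np.array([0.5, 2.0]))
        summary = amplitude_velocity_relation(fuse(traj, enc),
                                              threshold_mv=1.0)
        assert summary.mean_speed_above > summary.mean_speed_below

    def test_empty_group_flagged(self):
        traj = straight_run(duration=5.0)
        enc = EncounterSeries(np.array([1.0]), 0.0, 5.0,
                              amplitudes_mv=np.array([0.2]))
        summary = amplitude_velocity_relation(fuse(traj, enc),
                                              threshold_mv=1.0)
        assert summary.empty_group
        assert summary.n_above == 0

    def test_zero_threshold_puts_all_above(self):
        traj = straight_run(duration=5.0)
        enc = EncounterSeries(np.array([0.0]), 0.0, 5.0,
                              amplitudes_mv=np.array([0.5]))
        summary = amplitude_velocity_relation(fuse(traj, enc),
                                              threshold_mv=0.0)
        assert summary.n_below == 0


class TestWindFrameRatios:
    def test_straight_upwind_run(self):
        fused = fuse(straight_run(heading_deg=180.0))
        r = wind_frame_ratios(fused, wind_axis=(1.0, 0.0))
        assert (r.upwind, r.downwind, r.crosswind) == (1.0, 0.0, 0.0)

    def test_perpendicular_motion_is_crosswind(self):
        fused = fuse(straight_run(heading_deg=90.0))
        r = wind_frame_ratios(fused, wind_axis=(1.0, 0.0))
        assert r.crosswind == 1.0

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(5)
        t = np.arange(0.0, 30.0, 0.01)
        x = np.cumsum(rng.normal(0, 0.5, t.size))
        y = np.cumsum(rng.normal(0, 0.5, t.size))
        r = wind_frame_ratios(fuse(Trajectory(t, x, y)))
        assert r.upwind + r.downwind + r.crosswind == pytest.approx(
            1.0, abs=1e-12)

    def test_stationary_rejected(self):
        t = np.arange(0.0, 5.0, 0.01)
        fused = fuse(Trajectory(t, np.zeros_like(t), np.zeros_like(t)))
        with pytest.raises(ValueError):
            wind_frame_ratios(fused)


class TestDetectCasts:
    def test_crosswind_zigzag_flagged(self):
        t = np.arange(0.0, 20.0, 0.01)
        traj = Trajectory(t, np.full_like(t, 100.0),
                          40.0 * np.sin(2 * np.pi * t / 2.5))
        segments, flagged = detect_casts(fuse(traj))
        assert flagged
        assert segments

    def test_straight_upwind_not_flagged(self):
        _, flagged = detect_casts(fuse(straight_run(duration=20.0)))
        assert not flagged


class TestLocalizationOutcome:
    def test_start_inside_disc(self):
        traj = straight_run(start=(5.0, 0.0), duration=1.0)
        out = localization_outcome(traj)
        assert out.success and out.time_to_source_s == 0.0

    def test_straight_run_first_passage_time(self):
        # (150 - 10) mm at 15 mm/s = 9.33 s to the 10 mm disc
        traj = straight_run(speed_mm_s=15.0, duration=12.0)
        out = localization_outcome(traj)
        assert out.success
        assert out.time_to_source_s == pytest.approx(9.3333, abs=0.05)

    def test_timeout_failure(self):
        t = np.arange(0.0, 200.0, 0.1)
        traj = Trajectory(t, np.full_like(t, 400.0), np.zeros_like(t))
        out = localization_outcome(traj, timeout_s=180.0)
        assert not out.success
        assert np.isnan(out.time_to_source_s)
        assert out.end_distance_mm == pytest.approx(400.0)


class TestIntensityMap:
    def test_single_sample_single_bin(self):
        t = np.array([0.0, 0.01])
        traj = Trajectory(t, np.array([33.0, 33.0]),
                          np.array([-7.0, -7.0]))
        enc = EncounterSeries(np.array([0.0]), 0.0, 0.01,
                              amplitudes_mv=np.array([1.0]))
        imap = intensity_map(fuse(traj, enc))
        filled = ~np.isnan(imap.mean_intensity)
        assert filled.sum() == 1
        assert imap.mean_intensity[filled] == pytest.approx(1.0)

    def test_uniform_intensity_everywhere(self):
        traj = straight_run(duration=10.0)
        enc = EncounterSeries(np.array([0.0]), 0.0, 10.0,
                              amplitudes_mv=np.array([1.0]))
        imap = intensity_map(fuse(traj, enc))
        vals = imap.mean_intensity[~np.isnan(imap.mean_intensity)]
        assert vals == pytest.approx(np.ones_like(vals))


class TestFrameInvariance:
    def test_metrics_invariant_under_translation(self):
        rng = np.random.default_rng(9)
        t = np.arange(0.0, 20.0, 0.01)
        x = 150.0 - 4.0 * t + np.cumsum(rng.normal(0, 0.2, t.size))
        y = np.cumsum(rng.normal(0, 0.2, t.size))
        traj = Trajectory(t, x, y)
        shifted = traj.translate(321.0, -77.0)
        r1 = wind_frame_ratios(fuse(traj))
        r2 = wind_frame_ratios(fuse(shifted))
        assert r1.upwind == pytest.approx(r2.upwind, abs=1e-12)
        o1 = localization_outcome(traj, source_mm=(0.0, 0.0))
        o2 = localization_outcome(shifted, source_mm=(321.0, -77.0))
        assert o1.success == o2.success
        assert o1.end_distance_mm == pytest.approx(o2.end_distance_mm,
                                                   abs=1e-9)
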