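"""Tracking ingestion, cleaning, and behavior segmentation."""

import numpy as np
import pandas as pd
import pytest

from bgpipe import kinematics as kin
from bgpipe import synthdata as sd
from bgpipe.errors import (
    DegenerateScaleError,
    MalformedInputError,
    SessionExcludedError,
)


def _table(parts, n=100, fs=30.0, like=0.99):
    cols = {}
    for name, (x, y) in parts.items():
        cols[(name, "x")] = np.asarray(x, dtype=float)
        cols[(name, "y")] = np.asarray(y, dtype=float)
        cols[(name, "likelihood")] = np.full(n, like, dtype=float)
    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(df.columns,
                                           names=["bodyparts", "coords"])
    return kin.TrackingTable(df, np.arange(n) / fs, fs_video=fs)


class TestTrackingIO:
    def test_round_trip(self, tmp_path, base_cfg):
        table, _ = sd.simulate_tracking(base_cfg)
        path = tmp_path / "dlc.csv"
        kin.write_tracking(table, path)
        back = kin.read_tracking(path, fs_video=base_cfg.fs_video)
        np.testing.assert_allclose(back.data.to_numpy(), table.data.to_numpy(),
                                   rtol=1e-9)
        assert back.bodyparts == table.bodyparts

    def test_eight_parts_parse_to_24_columns(self, tmp_path, base_cfg):
        table, _ = sd.simulate_tracking(base_cfg)
        path = tmp_path / "dlc.csv"
        kin.write_tracking(table, path)
        back = kin.read_tracking(path, fs_video=30.0)
        assert back.data.shape[1] == 24

    def test_shuffled_header_rows_rejected(self, tmp_path, base_cfg):
        table, _ = sd.simulate_tracking(base_cfg)
        path = tmp_path / "dlc.csv"
        kin.write_tracking(table, path)
        lines = path.read_text().splitlines()
        lines[1], lines[2] = lines[2], lines[1]  # bodyparts <-> coords
        bad = tmp_path / "bad.csv"
        bad.write_text("\n".join(lines))
        with pytest.raises(MalformedInputError):
            kin.read_tracking(bad, fs_video=30.0)


class TestInterpolation:
    def test_identity_when_all_valid(self):
        t = _table({"a": (np.arange(50.0), np.arange(50.0))}, n=50)
        out = kin.interpolate_low_likelihood(t)
        np.testing.assert_array_equal(out.data.to_numpy(), t.data.to_numpy())

    def test_single_gap_on_line_restored_exactly(self):
        x = np.arange(50.0)
        t = _table({"a": (x, 2.0 * x)}, n=50)
        t.data.loc[25, ("a", "likelihood")] = 0.1
        t.data.loc[25, ("a", "x")] = -999.0
        out = kin.interpolate_low_likelihood(t)
        assert out.data.loc[25, ("a", "x")] == pytest.approx(25.0, abs=1e-9)
        # likelihood preserved for audit
        assert out.data.loc[25, ("a", "likelihood")] == pytest.approx(0.1)

    def test_block_gap_on_quadratic_near_spline_oracle(self):
        from scipy.interpolate import CubicSpline
        i = np.arange(80.0)
        x = 0.02 * i ** 2
        t = _table({"a": (x, x)}, n=80)
        t.data.loc[30:40, ("a", "likelihood")] = 0.2
        out = kin.interpolate_low_likelihood(t)
        valid = np.ones(80, dtype=bool)
        valid[30:41] = False
        oracle = CubicSpline(i[valid], x[valid])(i[~valid])
        # shape-preserving cubic tracks the spline oracle within 1 % of range
        np.testing.assert_allclose(
            out.data.loc[30:40, ("a", "x")].to_numpy(), oracle,
            atol=0.01 * np.ptp(x))


class TestCalibration:
    def test_arena_scale(self):
        t = _table({"a": (np.zeros(10), np.zeros(10))}, n=10)
        out = kin.calibrate_and_upsample(t, 42.0, 420.0, target_fs=None)
        assert out.cm_per_px == pytest.approx(0.1)

    def test_constant_position_preserved_by_upsampling(self):
        t = _table({"a": (np.full(30, 7.0), np.full(30, 3.0))}, n=30)
        out = kin.calibrate_and_upsample(t, 42.0, 420.0, target_fs=100.0)
        assert np.ptp(out.part("a")["x"].to_numpy()) == 0.0

    def test_linear_motion_speed_unchanged_by_upsampling(self):
        n = 60
        x = 50.0 * np.arange(n) / 30.0  # 50 px/s = 5 cm/s at 0.1 cm/px
        t = _table({"body_center": (x, np.zeros(n))}, n=n)
        out = kin.calibrate_and_upsample(t, 42.0, 420.0, target_fs=100.0)
        sp = kin.compute_speed(out, smooth_window_s=0.0)
        np.testing.assert_allclose(sp.speed_cm_s[1:-1], 5.0, rtol=1e-6)


class TestSpeedAndBouts:
    def test_stationary_mouse_zero_speed(self):
        t = _table({"body_center": (np.full(50, 5.0), np.full(50, 5.0))}, n=50)
        cal = kin.calibrate_and_upsample(t, 42.0, 420.0, target_fs=None)
        sp = kin.compute_speed(cal)
        np.testing.assert_allclose(sp.speed_cm_s, 0.0, atol=1e-12)

    def test_trapezoid_profile_peak_recovered(self):
        cfg = sd.SimConfig(seed=1, duration_s=120.0,
                           bout_schedule=[(30.0, 45.0, 8.0)])
        table, _ = sd.simulate_tracking(cfg)
        cal = kin.calibrate_and_upsample(table, sd.ARENA_CM, sd.ARENA_PX,
                                         target_fs=None)
        sp = kin.compute_speed(cal, smooth_window_s=2.0)
        assert np.max(sp.speed_cm_s) == pytest.approx(8.0, rel=0.02)

    def test_zero_speed_yields_no_bouts(self):
        sp = kin.SpeedTrace(np.arange(100) / 30.0, np.zeros(100),
                            np.zeros(100), pd.DataFrame(), 30.0, 2.0)
        assert len(kin.detect_locomotor_bouts(sp)) == 0

    def test_single_trapezoid_extrema_within_one_frame(self):
        # analytic: a centered boxcar of width w starts rising w/2 before the
        # ramp foot and leaves the plateau w/2 before the descent start
        fs, w = 30.0, 2.0
        t = np.arange(int(90 * fs)) / fs
        v = sd.trapezoid_speed(t, [(30.0, 42.0, 8.0)], 0.5, 1.0)
        from bgpipe.photometry import moving_average
        smoothed = moving_average(v, w, fs)
        sp = kin.SpeedTrace(t, smoothed, v, pd.DataFrame(), fs, w)
        ev = kin.detect_locomotor_bouts(sp)
        on, off = ev.pairs("bout")
        assert on.size == 1
        assert on[0] == pytest.approx(30.0 - w / 2, abs=1.01 / fs)
        assert off[0] == pytest.approx(41.0 - w / 2, abs=1.01 / fs)

    def test_two_trapezoids_two_bouts(self):
        fs = 30.0
        t = np.arange(int(120 * fs)) / fs
        v = sd.trapezoid_speed(t, [(20.0, 32.0, 8.0), (60.0, 72.0, 8.0)],
                               0.5, 1.0)
        sp = kin.SpeedTrace(t, v, v, pd.DataFrame(), fs, 0.0)
        on, off = kin.detect_locomotor_bouts(sp).pairs("bout")
        assert on.size == 2

    def test_bout_pairing_invariants(self, base_cfg):
        table, _ = sd.simulate_tracking(base_cfg)
        cal = kin.calibrate_and_upsample(table, sd.ARENA_CM, sd.ARENA_PX,
                                         target_fs=None)
        sp = kin.compute_speed(cal)
        ev = kin.detect_locomotor_bouts(sp)
        on, off = ev.pairs("bout")
        assert np.all(off > on)
        assert np.all(on[1:] >= off[:-1])  # disjoint
        for a, b in zip(on, off):
            sel = (sp.time_s >= a) & (sp.time_s <= b + 1.0)
            assert np.max(sp.speed_cm_s[sel]) > 5.0


class TestJumps:
    def test_triangular_wave_fully_recovered(self):
        cfg = sd.SimConfig(seed=3, duration_s=60.0)
        rod, truth = sd.simulate_rotarod_tracking(cfg, period_s=1.2,
                                                  dropout_fraction=0.0)
        cal = kin.calibrate_and_upsample(rod, sd.ROD_HEIGHT_CM,
                                         sd.ROD_HEIGHT_PX, target_fs=None)
        jumps = kin.detect_jumps(cal)
        t_on = truth.true_jumps.times("jump_onset")
        d_on = jumps.times("jump_onset")
        assert d_on.size == t_on.size
        np.testing.assert_allclose(d_on, t_on, atol=1.01 / cfg.fs_video)
        np.testing.assert_allclose(kin.inter_jump_intervals(jumps), 1.2,
                                   atol=1.01 / cfg.fs_video)

    def test_low_likelihood_session_excluded(self):
        cfg = sd.SimConfig(seed=3, duration_s=30.0)
        rod, _ = sd.simulate_rotarod_tracking(cfg, period_s=1.2,
                                              dropout_fraction=0.6)
        cal = kin.calibrate_and_upsample(rod, sd.ROD_HEIGHT_CM,
                                         sd.ROD_HEIGHT_PX, target_fs=None)
        with pytest.raises(SessionExcludedError):
            kin.detect_jumps(cal)

    def test_flat_y_rejected(self):
        t = _table({"lower_body": (np.zeros(100), np.full(100, 5.0))}, n=100)
        cal = kin.calibrate_and_upsample(t, 3.0, 30.0, target_fs=None)
        with pytest.raises(DegenerateScaleError):
            kin.detect_jumps(cal)


class TestMotorStates:
    def _speed(self, body, parts, fs=30.0):
        n = body.size
        return kin.SpeedTrace(np.arange(n) / fs, body, body,
                              pd.DataFrame(parts), fs, 2.0)

    def test_three_label_rules(self):
        n = 3
        t = _table({"body_center": (np.full(n, 210.0), np.full(n, 210.0))}, n=n)
        cal = kin.calibrate_and_upsample(t, 42.0, 420.0, target_fs=None)
        body = np.array([10.0, 0.0, 2.0])
        parts = {"body_center": body, "snout": np.array([10.0, 0.0, 1.5])}
        states = kin.classify_motor_state(cal, self._speed(body, parts))
        assert list(states.label) == ["locomotion", "motionless",
                                      "other_movement"]

    def test_partition_sums_to_one(self, base_cfg):
        table, _ = sd.simulate_tracking(base_cfg)
        cal = kin.calibrate_and_upsample(table, sd.ARENA_CM, sd.ARENA_PX,
                                         target_fs=None)
        sp = kin.compute_speed(cal)
        states = kin.classify_motor_state(cal, sp)
        f = states.fractions()
        assert sum(f.values()) == pytest.approx(1.0, abs=1e-12)
        z = states.zone_fractions()
        assert sum(z.values()) == pytest.approx(1.0, abs=1e-12)

    def test_periphery_band(self):
        n = 2
        # one frame in the center, one 5 cm from the left wall; y values span
        # the image so the y-up flip reference is the arena edge
        t = _table({"body_center": (np.array([210.0, 50.0]),
                                    np.array([210.0, 420.0]))}, n=n)
        cal = kin.calibrate_and_upsample(t, 42.0, 420.0, target_fs=None)
        body = np.zeros(n)
        states = kin.classify_motor_state(cal, self._speed(body,
                                                           {"body_center": body}))
        assert list(states.zone) == ["center", "periphery"]


class TestRotation:
    def test_quarter_turn(self):
        snout = np.array([[1.0, 0.0], [0.0, 1.0]]) + 5.0
        lower = np.full((2, 2), 5.0)
        rec = kin.rotation_angles(snout, lower, np.array([0.0, 0.1]))
        assert rec.angle_deg[0] == pytest.approx(90.0, abs=1e-9)

    def test_no_motion_no_angle(self):
        snout = np.tile([6.0, 5.0], (5, 1))
        lower = np.full((5, 2), 5.0)
        rec = kin.rotation_angles(snout, lower, np.arange(5) * 0.1)
        np.testing.assert_allclose(rec.angle_deg, 0.0, atol=1e-12)

    def test_full_circle_cumulative(self):
        table = sd.simulate_rotation_trajectory(36.0, 10.0, 30.0)
        rec = kin.rotation_angles(table.xy("snout"), table.xy("lower_body"),
                                  table.time_s)
        assert rec.cumulative_deg[-1] == pytest.approx(360.0, abs=1e-6)

    def test_antisymmetry_under_time_reversal(self):
        table = sd.simulate_rotation_trajectory(24.0, 5.0, 30.0)
        s, l, t = table.xy("snout"), table.xy("lower_body"), table.time_s
        fwd = kin.rotation_angles(s, l, t)
        rev = kin.rotation_angles(s[::-1], l[::-1], t)
        assert rev.cumulative_deg[-1] == pytest.approx(-fwd.cumulative_deg[-1],
                                                       abs=1e-9)

    def test_degenerate_frames_skipped(self):
        snout = np.array([[6.0, 5.0], [5.0, 5.0], [5.0, 6.0]])
        lower = np.full((3, 2), 5.0)
        rec = kin.rotation_angles(snout, lower, np.arange(3) * 0.1)
        np.testing.assert_allclose(rec.angle_deg, 0.0, atol=1e-12)
        assert rec.skipped_frames.tolist() == [1]


class TestRelativeSpeed:
    def _trace(self, v, fs=10.0):
        n = v.size
        return kin.SpeedTrace(np.arange(n) / fs, v, v, pd.DataFrame(), fs, 2.0)

    def test_constant_speed_zeroed(self):
        sp = self._trace(np.full(2000, 4.0))
        rel, mat, kept, dropped = kin.relative_speed(sp, [100.0])
        np.testing.assert_allclose(mat, 0.0, atol=1e-12)
        assert dropped == 0

    def test_step_preserved(self):
        v = np.full(2000, 1.0)
        v[1000:] += 4.0  # step at t = 100 s
        sp = self._trace(v)
        rel, mat, _, _ = kin.relative_speed(sp, [100.0])
        in_stim = (rel > 0.5) & (rel < 20.0)
        np.testing.assert_allclose(mat[0][in_stim], 4.0, atol=1e-9)

    def test_incomplete_baseline_dropped(self):
        sp = self._trace(np.full(2000, 1.0))
        _, mat, kept, dropped = kin.relative_speed(sp, [10.0, 100.0])
        assert dropped == 1
        assert kept.tolist() == [100.0]
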