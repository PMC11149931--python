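"""Windowed kinematics: position means, 5-s-step speed, round trips."""

import numpy as np
import pytest

from swimscore import (TrialDesign, mean_position_x, mean_speed, round_trips,
                       summarize_windows, window_slice)
from swimscore.kinematics import WindowError


def brute_force_round_trips(x, h):
    """Independent oracle: walk the series and count strict straddles of
    +h and -h, divided by two."""
    crossings = 0
    for level in (h, -h):
        for a, b in zip(x[:-1], x[1:]):
            if (a - level) * (b - level) < 0:
                crossings += 1
    return crossings / 2.0


class TestWindowSlice:
    def test_fifteen_minute_slice_sample_count(self, make_traj):
        t = np.arange(0, 3600, 1 / 30)
        traj = make_traj(t, np.zeros_like(t))
        win = window_slice(traj, 10, 25)
        assert len(win) == 27_000

    def test_full_window_is_identity(self, make_traj):
        t = np.arange(0, 3600, 1 / 30)
        traj = make_traj(t, np.sin(t))
        win = window_slice(traj, 0, 60)
        assert len(win) == len(traj)

    def test_disjoint_window_raises(self, make_traj):
        traj = make_traj(np.arange(0, 3600, 1 / 30), np.zeros(108_000))
        with pytest.raises(WindowError):
            window_slice(traj, 61, 62)


class TestMeanPosition:
    def test_parked_at_odor_wall(self, make_traj):
        traj = make_traj(np.arange(100) / 30, np.ones(100))
        assert mean_position_x(traj) == pytest.approx(1.0)

    def test_symmetric_sinusoid_averages_to_zero(self, make_traj):
        t = np.arange(0, 600, 1 / 30)       # whole periods
        traj = make_traj(t, 0.8 * np.sin(2 * np.pi * t / 60))
        assert mean_position_x(traj) == pytest.approx(0.0, abs=1e-6)

    def test_hand_computed_mean(self, make_traj):
        traj = make_traj([0, 1 / 30, 2 / 30], [-0.5, 0.0, 1.0])
        assert mean_position_x(traj) == pytest.approx(1 / 6)


class TestMeanSpeed:
    def test_straight_line_constant_speed(self, make_traj):
        t = np.arange(0, 60, 1 / 30)
        x_cm = 1.0 * t                       # 1 cm/s along x
        traj = make_traj(t, np.zeros_like(t), x_cm=x_cm,
                         y_cm=np.zeros_like(t))
        assert mean_speed(traj) == pytest.approx(1.0, abs=1e-9)

    def test_stationary_fish(self, make_traj):
        t = np.arange(0, 60, 1 / 30)
        traj = make_traj(t, np.zeros_like(t), x_cm=np.full_like(t, 3.0),
                         y_cm=np.full_like(t, 2.0))
        assert mean_speed(traj) == 0.0

    def test_circular_track_matches_chord_formula(self, make_traj):
        # chord displacement over a 5 s step: 2 r sin(omega dt / 2) / dt
        r, omega = 2.0, 0.2
        t = np.arange(0, 900, 1 / 30)
        traj = make_traj(t, np.zeros_like(t),
                         x_cm=5.75 + r * np.cos(omega * t),
                         y_cm=4.25 + r * np.sin(omega * t))
        expected = 2 * r * np.sin(omega * 5 / 2) / 5
        assert mean_speed(traj) == pytest.approx(expected, abs=1e-3)
        assert expected == pytest.approx(0.3836, abs=1e-3)

    def test_rigid_motion_invariance(self, make_traj):
        rng = np.random.default_rng(5)
        t = np.arange(0, 120, 1 / 30)
        x = np.cumsum(rng.normal(0, 0.05, t.size))
        y = np.cumsum(rng.normal(0, 0.05, t.size))
        base = mean_speed(make_traj(t, np.zeros_like(t), x_cm=x, y_cm=y))
        ang = 0.7
        xr = np.cos(ang) * x - np.sin(ang) * y + 3.0
        yr = np.sin(ang) * x + np.cos(ang) * y - 1.5
        rot = mean_speed(make_traj(t, np.zeros_like(t), x_cm=xr, y_cm=yr))
        assert rot == pytest.approx(base, rel=1e-12)

    def test_too_short_window_raises(self, make_traj):
        t = np.arange(0, 3, 1 / 30)
        traj = make_traj(t, np.zeros_like(t))
        with pytest.raises(WindowError):
            mean_speed(traj)


class TestRoundTrips:
    def test_monotone_sweep_is_one_round_trip(self, make_traj):
        x = np.linspace(-1, 1, 200)
        traj = make_traj(np.arange(200) / 30, x)
        assert round_trips(traj, "X") == 1.0

    def test_sinusoid_gives_thirty_in_fifteen_minutes(self, make_traj):
        t = np.arange(0, 900, 1 / 30)
        traj = make_traj(t, 0.9 * np.sin(2 * np.pi * t / 60))
        assert round_trips(traj, "X") == 30.0

    def test_confined_fish_never_crosses(self, make_traj):
        rng = np.random.default_rng(1)
        x = 0.39 * np.sin(np.arange(3000) / 10) + rng.normal(0, 0.001, 3000)
        traj = make_traj(np.arange(3000) / 30, np.clip(x, -0.399, 0.399))
        assert round_trips(traj, "X") == 0.0

    def test_touching_threshold_without_crossing_not_counted(self, make_traj):
        x = np.array([0.0, 0.5, 0.0, 0.5, 0.4])
        traj = make_traj(np.arange(5) / 30, x)
        assert round_trips(traj, "X") == 0.0

    def test_y_threshold_scales_with_half_extent(self, make_traj):
        # oscillation to +/-0.40 crosses 0.5 * 0.74 = 0.37 but not 0.5
        t = np.arange(0, 120, 1 / 30)
        y = 0.40 * np.sin(2 * np.pi * t / 60)
        traj = make_traj(t, np.zeros_like(t), yc=y)
        assert round_trips(traj, "Y") == 4.0           # 2 per period
        assert round_trips(traj, "Y", literal_y_threshold=True) == 0.0

    def test_matches_brute_force_oracle_on_random_walks(self, make_traj):
        rng = np.random.default_rng(42)
        for _ in range(200):
            x = np.clip(np.cumsum(rng.normal(0, 0.2, 250)), -1, 1)
            traj = make_traj(np.arange(250) / 30, x)
            assert round_trips(traj, "X") == brute_force_round_trips(x, 0.5)


class TestSummarizeWindows:
    def _null_track(self, seed=0):
        from swimscore import (baseline_spec, default_geometry, recode,
                               simulate_trajectory)
        spec = baseline_spec(morph="SF", seed=seed)
        raw, _ = simulate_trajectory(spec)
        trial = TrialDesign(fish_id="f", odor_side="right")
        return recode(raw, default_geometry(), trial), trial

    def test_null_simulation_before_after_agree(self):
        from swimscore import change_index, position_change_index
        traj, trial = self._null_track(seed=11)
        kb, ka = summarize_windows(traj, trial)
        assert abs(position_change_index(kb.mean_position_x,
                                         ka.mean_position_x)) < 0.15
        assert abs(change_index(kb.mean_speed, ka.mean_speed)) < 0.15
        assert abs(change_index(kb.round_trips_x + kb.round_trips_y,
                                ka.round_trips_x + ka.round_trips_y)) < 0.15

    def test_short_track_names_missing_window(self, make_traj):
        t = np.arange(0, 1800, 1 / 30)        # only 0-30 min covered
        traj = make_traj(t, np.zeros_like(t))
        trial = TrialDesign(fish_id="f")
        with pytest.raises(WindowError, match="after"):
            summarize_windows(traj, trial)

    def test_attraction_shifts_position_toward_odor(self):
        from swimscore import (attraction_response, baseline_spec,
                               default_geometry, recode, simulate_trajectory)
        spec = baseline_spec(morph="CF", seed=3,
                             response=attraction_response())
        raw, _ = simulate_trajectory(spec)
        trial = TrialDesign(fish_id="f", morph="CF", odor_side="right")
        traj = recode(raw, default_geometry(), trial)
        kb, ka = summarize_windows(traj, trial)
        assert ka.mean_position_x > kb.mean_position_x


class TestUpsamplingInvariance:
    def test_statistics_stable_under_noise_free_upsampling(self, make_traj):
        t = np.arange(0, 900, 1 / 30)
        x = 0.9 * np.sin(2 * np.pi * t / 60)
        x_cm = (x + 1) * 11.5 / 2
        t2 = np.arange(0, 900, 1 / 60)
        x2 = np.interp(t2, t, x)
        a = make_traj(t, x, x_cm=x_cm, y_cm=np.zeros_like(t))
        b = make_traj(t2, x2, x_cm=np.interp(t2, t, x_cm),
                      y_cm=np.zeros_like(t2), frame_rate=60.0)
        assert mean_position_x(b) == pytest.approx(mean_position_x(a),
                                                   abs=1e-3)
        assert mean_speed(b) == pytest.approx(mean_speed(a), abs=1e-3)
        assert round_trips(b, "X") == round_trips(a, "X")
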