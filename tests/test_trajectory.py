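"""Behavioral metrics: turn angle geometry, filtering, rates, window stats."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from larvanet import trajectory as traj
from larvanet import simulate as sim
from larvanet.core import TrackSet, TurnEvent

from conftest import make_track


def bent_spine(d: float = 2.0):
    """Spine with posterior 7 points on the x-axis and a known anterior offset."""
    spine = np.zeros((11, 2))
    # posterior points (indices 4..10) from x=6 (anterior end) down to x=0
    spine[4:, 0] = np.arange(6, -1, -1)
    spine[3] = (6.5, 0.0)
    spine[2] = (7.0, 0.0)
    spine[1] = (7.5, d / 4)
    spine[0] = (8.0, d)
    return spine


class TestTurnAngle:
    def test_hand_geometry_perpendicular_distance(self):
        # posterior TLS line is the x-axis; the most distant anterior point
        # sits at (8, 2), so the perpendicular distance is exactly 2
        d, signed, arc = traj.spine_bend(bent_spine(2.0))
        assert d == pytest.approx(2.0, abs=1e-12)
        _, dist = traj.turn_angle(bent_spine(2.0), return_distance=True)
        assert dist == pytest.approx(2.0, abs=1e-12)

    def test_collinear_spine_is_zero(self):
        spine = np.stack([np.linspace(10, 0, 11), np.zeros(11)], axis=1)
        assert traj.turn_angle(spine) == pytest.approx(0.0, abs=1e-9)

    def test_mirror_symmetry(self):
        spine = bent_spine(1.5)
        mirrored = spine * np.array([1.0, -1.0])
        assert traj.turn_angle(spine) == pytest.approx(traj.turn_angle(mirrored))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        angle=st.floats(0, 2 * np.pi),
        tx=st.floats(-100, 100),
        ty=st.floats(-100, 100),
    )
    def test_rigid_motion_invariance(self, angle, tx, ty):
        spine = bent_spine(1.0)
        R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        moved = spine @ R.T + np.array([tx, ty])
        assert traj.turn_angle(moved) == pytest.approx(traj.turn_angle(spine), abs=1e-6)

    def test_scaling_behavior(self):
        # the raw distance scales linearly; the angle form is scale-invariant
        a1, d1 = traj.turn_angle(bent_spine(1.0), return_distance=True)
        a3, d3 = traj.turn_angle(bent_spine(1.0) * 3.0, return_distance=True)
        assert d3 == pytest.approx(3 * d1)
        assert a3 == pytest.approx(a1)

    def test_degenerate_spine_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            traj.turn_angle(np.ones((11, 2)))


class TestFilterTracks:
    def test_short_track_rejected(self):
        short = make_track(duration=4.9)
        long_ = make_track(duration=10.0)
        kept = traj.filter_tracks(TrackSet([short, long_]))
        assert [tr.larva_id for tr in kept] == [long_.larva_id]

    def test_low_travel_rejected(self):
        slow = make_track(larva_id="slow", duration=10.0, speed=0.2, body_length=4.0)
        assert slow.path_length() < 4.0
        fast = make_track(larva_id="fast", duration=10.0, speed=1.0)
        kept = traj.filter_tracks(TrackSet([slow, fast]))
        assert [tr.larva_id for tr in kept] == ["fast"]

    def test_net_metric_rejects_circling(self):
        # a larva crawling in a tight loop travels far but displaces little
        n = 140
        heading = np.linspace(0, 4 * np.pi, n)
        circler = make_track(duration=10.0, heading=heading, speed=1.0)
        assert len(traj.filter_tracks(TrackSet([circler]), travel_metric="path")) == 1
        assert len(traj.filter_tracks(TrackSet([circler]), travel_metric="net")) == 0

    def test_empty_input(self):
        assert len(traj.filter_tracks(TrackSet([]))) == 0

    def test_invalid_metric(self):
        with pytest.raises(ValueError):
            traj.filter_tracks(TrackSet([]), travel_metric="teleport")


class TestDetectTurns:
    def test_straight_track_has_no_turns(self):
        assert traj.detect_turns(make_track(duration=10.0)) == []

    def test_scripted_bend_episodes_are_counted(self):
        n = 14 * 20
        bend = np.zeros(n)
        for start in (50, 120, 200):  # three 1 s bend episodes
            bend[start : start + 14] = np.deg2rad(60) * np.sin(
                np.pi * np.arange(14) / 14
            )
        track = make_track(duration=20.0, bend=bend)
        events = traj.detect_turns(track, angle_threshold=20.0)
        assert len(events) == 3
        for ev in events:
            assert sum(hs.is_first for hs in ev.head_sweeps) == 1

    def test_threshold_above_max_bend_detects_nothing(self):
        bend = np.zeros(14 * 10)
        bend[40:54] = np.deg2rad(30)
        track = make_track(duration=10.0, bend=bend)
        assert traj.detect_turns(track, angle_threshold=80.0) == []

    def test_nonpositive_threshold_errors(self):
        with pytest.raises(ValueError):
            traj.detect_turns(make_track(duration=6.0), angle_threshold=0.0)


class TestNavigationIndex:
    def test_straight_up_gradient_is_plus_one(self):
        tracks = TrackSet([make_track(heading=0.0), make_track(heading=0.0)])
        assert traj.navigation_index(tracks, (1, 0)) == pytest.approx(1.0, abs=1e-12)

    def test_straight_down_gradient_is_minus_one(self):
        tracks = TrackSet([make_track(heading=np.pi)])
        assert traj.navigation_index(tracks, (1, 0)) == pytest.approx(-1.0, abs=1e-12)

    def test_opposed_pair_cancels(self):
        tracks = TrackSet(
            [make_track(heading=0.0, duration=1.0), make_track(heading=np.pi, duration=1.0)]
        )
        assert traj.navigation_index(tracks, (1, 0)) == pytest.approx(0.0, abs=1e-12)

    def test_zero_speed_errors(self):
        still = make_track(speed=0.0)
        with pytest.raises(ValueError, match="zero total"):
            traj.navigation_index(TrackSet([still]))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            traj.navigation_index(TrackSet([]))


class TestTurnRateByOrientation:
    @staticmethod
    def _events_from_truth(truth, turn_duration=1.0):
        return [
            TurnEvent(larva_id=lid, t_start=float(t0), t_end=float(t0) + turn_duration)
            for lid, times in truth["turn_times"].items()
            for t0 in times
        ]

    def test_unmodulated_turning_is_isotropic(self):
        tracks, truth = sim.simulate_larvae_gradient(
            modulation=0.0, n_larvae=40, duration=120.0, seed=51, return_truth=True
        )
        res = traj.turn_rate_by_orientation(tracks, self._events_from_truth(truth))
        # toward and away rates agree within their counting errors
        assert abs(res.toward_rate - res.away_rate) < 3 * np.hypot(res.toward_se, res.away_se)
        assert res.table["N_turn"].sum() == len(self._events_from_truth(truth))

    def test_positive_modulation_biases_turning_away(self):
        tracks, truth = sim.simulate_larvae_gradient(
            modulation=0.6, n_larvae=40, duration=120.0, seed=52, return_truth=True
        )
        res = traj.turn_rate_by_orientation(tracks, self._events_from_truth(truth))
        assert res.away_rate > res.toward_rate
        assert res.p < 0.05

    def test_rate_arithmetic(self):
        # every bin obeys rate = N_turn / (N_frames * dt) (reported per min)
        tracks, truth = sim.simulate_larvae_gradient(
            modulation=0.0, n_larvae=5, duration=60.0, seed=53, return_truth=True
        )
        res = traj.turn_rate_by_orientation(tracks, self._events_from_truth(truth))
        dt = tracks[0].frame_dt
        tab = res.table[res.table["N_frames"] > 0]
        np.testing.assert_allclose(
            tab["rate_per_min"], tab["N_turn"] / (tab["N_frames"] * dt) * 60.0
        )
        # direct substitution: 2 turns over 28 run frames at dt = 1/14 s
        assert 2 / (28 * (1 / 14.0)) == pytest.approx(1.0)


class TestWindowStats:
    def test_constant_behavior_yields_null_differences(self):
        tracks = TrackSet([make_track(duration=100.0), make_track(duration=100.0)])
        ws = traj.stimulus_window_stats(tracks, light_onsets=[30.0, 75.0],
                                        light_offsets=[45.0, 90.0])
        assert ws.turn_angle_onset == pytest.approx(0.0, abs=1e-9)
        assert ws.turn_angle_offset == pytest.approx(0.0, abs=1e-9)
        assert ws.speed_onset == pytest.approx(1.0, abs=1e-6)
        assert ws.speed_offset == pytest.approx(1.0, abs=1e-6)
        assert ws.n == 2

    def test_step_response_at_onset(self):
        # bend steps up at both light onsets and stays; the onset metric must
        # equal the turn-angle step, pooled over the two pulses
        n = 14 * 100
        t = np.arange(n) / 14.0
        bend = np.zeros(n)
        for onset, dur in ((30.0, 15.0), (75.0, 15.0)):
            bend[(t >= onset) & (t < onset + dur)] = np.deg2rad(40)
        track = make_track(duration=100.0, bend=bend)
        base_angle = 0.0
        from larvanet.trajectory import turn_angle
        from larvanet.simulate import _render_spines

        step_angle = turn_angle(
            _render_spines(np.zeros((1, 2)), np.zeros(1), np.array([np.deg2rad(40)]), 4.0)[0]
        )
        ws = traj.stimulus_window_stats(TrackSet([track]))
        assert ws.turn_angle_onset == pytest.approx(step_angle - base_angle, abs=0.2)

    def test_window_past_track_end_warns(self):
        track = make_track(duration=50.0)
        with pytest.warns(UserWarning, match="truncated"):
            traj.stimulus_window_stats(
                TrackSet([track]), light_onsets=[30.0], light_offsets=[45.0]
            )


class TestWelchZ:
    def test_hand_arithmetic(self):
        z, p = traj.welch_z_test(1.0, 0.6, 10, 0.0, 0.8, 10)
        assert z == pytest.approx(1.0)
        assert p == pytest.approx(0.31731, abs=1e-4)

    def test_identical_groups(self):
        z, p = traj.welch_z_test(0.5, 0.1, 5, 0.5, 0.1, 5)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        ma=st.floats(-5, 5), mb=st.floats(-5, 5),
        sa=st.floats(0.01, 2), sb=st.floats(0.01, 2),
    )
    def test_antisymmetric_under_group_exchange(self, ma, mb, sa, sb):
        z1, p1 = traj.welch_z_test(ma, sa, 5, mb, sb, 5)
        z2, p2 = traj.welch_z_test(mb, sb, 5, ma, sa, 5)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_zero_se_unequal_means_errors(self):
        with pytest.raises(ValueError):
            traj.welch_z_test(1.0, 0.0, 5, 0.0, 0.0, 5)
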