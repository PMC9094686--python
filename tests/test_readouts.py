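"""Behavioral readouts: fishing, path choice, approach task."""

import math

import numpy as np
import pytest

from vrbat import readouts as ro
from vrbat.session import MotionTrack, TaskEvent, default_layout
from vrbat.simulate import CohortConfig, generate_cohort

from conftest import TOUCH_T0, make_events, make_session


def _yaw_towards(pos_xz, target_xz):
    dx, dz = target_xz[0] - pos_xz[0], target_xz[1] - pos_xz[1]
    return math.degrees(math.atan2(-dx, dz))


# ---------------------------------------------------------------------------
# fishing
# ---------------------------------------------------------------------------


class TestFishingDistance:
    def test_stationary_at_origin_closed_form(self):
        """Spider centered on the left plank: distance is the hypotenuse."""
        t = np.arange(0.0, 260.0, 1 / 30)
        pos = np.tile([0.0, 0.95, 0.0], (t.size, 1))
        s = make_session(pelvis_t=t, pelvis_pos=pos)
        want = math.hypot(2.3, 2.15)  # plank center (x=-2.3, z=2.15)
        assert ro.fishing_min_distance(s, "spider") == pytest.approx(want, abs=1e-9)

    def test_symmetric_stationary_readout_zero(self):
        t = np.arange(0.0, 260.0, 1 / 30)
        pos = np.tile([0.0, 0.95, 1.3], (t.size, 1))
        s = make_session(pelvis_t=t, pelvis_pos=pos)
        assert ro.fishing_readout(s) == pytest.approx(0.0, abs=1e-12)

    def test_touching_spider_plank_gives_near_zero(self):
        t = np.arange(0.0, 260.0, 1 / 30)
        pos = np.tile([0.0, 0.95, 1.0], (t.size, 1))
        mid = (t > 40) & (t < 50)
        pos[mid] = [-2.3, 0.95, 2.15]
        s = make_session(pelvis_t=t, pelvis_pos=pos)
        assert ro.fishing_min_distance(s, "spider") == pytest.approx(0.0, abs=1e-9)
        assert ro.fishing_readout(s) < 0  # hugged the spider side

    def test_window_excludes_wait_and_tail(self):
        """Approaches before the 10 s wait ends or after 130 s do not count."""
        t = np.arange(0.0, 260.0, 1 / 30)
        pos = np.tile([0.0, 0.95, 2.15], (t.size, 1))
        pos[t < 9.5] = [-2.3, 0.95, 2.15]
        pos[(t > 135) & (t < 140)] = [-2.3, 0.95, 2.15]
        s = make_session(pelvis_t=t, pelvis_pos=pos)
        assert ro.fishing_min_distance(s, "spider") == pytest.approx(2.3, abs=1e-6)

    def test_uncovered_window_rejected(self):
        t = np.arange(0.0, 50.0, 1 / 30)  # track ends before the window does
        pos = np.tile([0.0, 0.95, 1.0], (t.size, 1))
        s = make_session(pelvis_t=t, pelvis_pos=pos,
                         hand_t=t, hand_pos=pos.copy())
        with pytest.raises(ro.ReadoutError, match="does not cover"):
            ro.fishing_min_distance(s, "spider")


class TestMirrorSymmetry:
    def test_reflection_negates_readout_and_swaps_sides(self):
        """Mirroring trajectories and swapping animal sides negates the
        fishing readout and swaps the per-side physiology."""
        rng = np.random.default_rng(9)
        t = np.arange(0.0, 260.0, 1 / 30)
        x = 1.5 * np.sin(t / 17) + rng.normal(0, 0.05, t.size)
        z = 2.0 + 1.5 * np.sin(t / 23)
        pos = np.column_stack([x, np.full(t.size, 0.95), z])
        n_beats = 300
        rr_vals = 0.8 + 0.15 * np.sin(np.arange(n_beats) / 9.0)
        rr_t = 0.8 + np.cumsum(rr_vals)
        s = make_session(pelvis_t=t, pelvis_pos=pos, rr_t=rr_t, rr=rr_vals)
        mirrored = pos.copy()
        mirrored[:, 0] = -mirrored[:, 0]
        # mirrored walk against the unchanged layout: readout negated and
        # per-side physiology swapped
        s_mirror = make_session(pelvis_t=t, pelvis_pos=mirrored,
                                rr_t=rr_t, rr=rr_vals)
        assert ro.fishing_readout(s_mirror) == pytest.approx(
            -ro.fishing_readout(s), abs=1e-9)
        phys = ro.fishing_side_physiology(s)
        phys_m = ro.fishing_side_physiology(s_mirror)
        assert phys_m["spider"]["rr"] == pytest.approx(phys["turtle"]["rr"], abs=1e-12)
        assert phys_m["turtle"]["rr"] == pytest.approx(phys["spider"]["rr"], abs=1e-12)
        # mirroring the walk AND the animal sides is the identity
        s_both = make_session(
            pelvis_t=t, pelvis_pos=mirrored,
            layout=default_layout(fishing_spider_side="right"))
        assert ro.fishing_readout(s_both) == pytest.approx(
            ro.fishing_readout(s), abs=1e-9)


class TestGlanceDifference:
    def test_no_focus_gives_zero(self):
        s = make_session()
        assert ro.fishing_glance_difference(s) == 0

    def test_three_spider_one_turtle_gives_two(self):
        gaze_t = np.arange(0.0, 260.0, 1 / 110)
        focus = np.full(gaze_t.size, None, dtype=object)
        # three spider glances (one with a 0.1 s gap that must merge) ...
        for a, b in [(20, 21), (21.1, 21.5), (40, 41), (60, 61)]:
            focus[(gaze_t >= a) & (gaze_t < b)] = "spider"
        # ... and one turtle glance
        focus[(gaze_t >= 80) & (gaze_t < 81)] = "turtle"
        s = make_session(gaze_t=gaze_t, focus=focus,
                         pupil=np.full(gaze_t.size, 3.5))
        assert ro.fishing_glance_difference(s) == 2


class TestOrientation:
    def _session_with_yaw(self, x, yaw_value):
        t = np.arange(0.0, 260.0, 1 / 30)
        pos = np.tile([x, 0.95, 2.15], (t.size, 1))
        yaw = np.full(t.size, yaw_value)
        return make_session(pelvis_t=t, pelvis_pos=pos, yaw=yaw)

    def test_facing_stimulus_gives_zero(self):
        # on the spider half (x<0), level with the plank center
        yaw = _yaw_towards((-1.0, 2.15), (-2.3, 2.15))
        s = self._session_with_yaw(-1.0, yaw)
        assert ro.fishing_orientation(s, "spider") == pytest.approx(0.0, abs=1e-6)

    def test_back_to_stimulus_gives_180(self):
        yaw = _yaw_towards((-1.0, 2.15), (-2.3, 2.15)) + 180.0
        s = self._session_with_yaw(-1.0, yaw)
        assert ro.fishing_orientation(s, "spider") == pytest.approx(180.0, abs=1e-6)

    def test_perpendicular_gives_90(self):
        yaw = _yaw_towards((-1.0, 2.15), (-2.3, 2.15)) + 90.0
        s = self._session_with_yaw(-1.0, yaw)
        assert ro.fishing_orientation(s, "spider") == pytest.approx(90.0, abs=1e-6)

    def test_never_entered_side_is_missing(self):
        s = self._session_with_yaw(1.0, 0.0)  # stays on the turtle half
        assert math.isnan(ro.fishing_orientation(s, "spider"))

    def test_yaw_absent_rejected(self):
        s = make_session(yaw=None)
        with pytest.raises(ro.ReadoutError, match="yaw"):
            ro.fishing_orientation(s, "spider")


class TestSidePhysiology:
    def test_constant_rr_on_both_halves(self):
        t = np.arange(0.0, 260.0, 1 / 30)
        x = np.where((t % 40) < 20, -1.0, 1.0)  # alternate halves
        pos = np.column_stack([x, np.full(t.size, 0.95), np.full(t.size, 2.0)])
        s = make_session(pelvis_t=t, pelvis_pos=pos)
        phys = ro.fishing_side_physiology(s)
        assert phys["spider"]["rr"] == pytest.approx(0.8, abs=1e-9)
        assert phys["turtle"]["rr"] == pytest.approx(0.8, abs=1e-9)

    def test_side_never_occupied_is_missing(self):
        s = make_session()  # default pelvis fixed at x=+0.5 (turtle half)
        phys = ro.fishing_side_physiology(s)
        assert math.isnan(phys["spider"]["rr"])
        assert math.isnan(phys["spider"]["pupil"])
        assert np.isfinite(phys["turtle"]["rr"])


# ---------------------------------------------------------------------------
# path choice
# ---------------------------------------------------------------------------


def _leg_track(x_at_gate, direction="out"):
    """Straight pelvis leg crossing the gate line (z=2.0) at a given x."""
    t = np.linspace(0.0, 4.0, 60)
    z = 0.5 + t * 0.75 if direction == "out" else 3.5 - t * 0.75
    x = np.full(t.size, x_at_gate)
    return MotionTrack("pelvis", t, np.column_stack([x, np.full(t.size, 0.95), z]))


class TestClassifyPathSide:
    def test_left_and_right(self):
        lay = default_layout()
        assert ro.classify_path_side(_leg_track(-0.8), (0, 4), lay) == "left"
        assert ro.classify_path_side(_leg_track(+0.8), (0, 4), lay) == "right"

    def test_first_crossing_rules_on_zigzag(self):
        lay = default_layout()
        t = np.linspace(0.0, 6.0, 120)
        z = 0.5 + 3.0 * np.abs(np.sin(t / 6 * np.pi))  # crosses, retreats, crosses
        x = np.where(t < 3.0, 0.8, -0.8)  # first crossing happens at x > 0
        track = MotionTrack("pelvis", t, np.column_stack(
            [x, np.full(t.size, 0.95), z]))
        assert ro.classify_path_side(track, (0, 6), lay) == "right"

    def test_gate_never_crossed_rejected(self):
        lay = default_layout()
        t = np.linspace(0.0, 4.0, 50)
        pos = np.tile([0.0, 0.95, 0.5], (t.size, 1))
        with pytest.raises(ro.ReadoutError, match="never crossed"):
            ro.classify_path_side(MotionTrack("pelvis", t, pos), (0, 4), lay)


class TestAvoidanceScore:
    @pytest.mark.parametrize("first_side", ["left", "right"])
    def test_extreme_policies(self, first_side):
        lay = default_layout(path_spider_side_first=first_side)
        assert ro.avoidance_score(ro.make_policy_choices(lay, "always_turtle")) == 14
        assert ro.avoidance_score(ro.make_policy_choices(lay, "always_spider")) == -14

    @pytest.mark.parametrize("first_side", ["left", "right"])
    def test_spider_in_trial_one_then_near_side(self, first_side):
        """Spider side on both trial-1 legs, cheapest side afterwards -> -2."""
        lay = default_layout(path_spider_side_first=first_side)
        near = {2: "right", 3: "left", 4: "right", 5: "left"}
        choices = []
        for trial in range(1, 6):
            side = lay.spider_side("path_choice", trial) if trial == 1 else near[trial]
            for leg in ("outward", "return"):
                choices.append(ro.make_segment_choice(lay, trial, leg, side))
        assert ro.avoidance_score(choices) == -2

    def test_weight_table(self):
        assert ro.segment_weight("center", "left") == 1
        assert ro.segment_weight("center", "right") == 1
        assert ro.segment_weight("right", "right") == 0
        assert ro.segment_weight("right", "left") == 2
        assert ro.segment_weight("far_left", "left") == 0
        assert ro.segment_weight("far_left", "right") == 4

    def test_alternative_sign_convention(self):
        lay = default_layout()
        flipped = ro.make_policy_choices(lay, "always_turtle", spider_positive=False)
        assert ro.avoidance_score(flipped) == -14

    def test_wrong_segment_count_rejected(self):
        lay = default_layout()
        choices = ro.make_policy_choices(lay, "always_turtle")[:9]
        with pytest.raises(ro.ReadoutError, match="10"):
            ro.avoidance_score(choices)

    def test_duplicate_leg_rejected(self):
        lay = default_layout()
        choices = ro.make_policy_choices(lay, "always_turtle")
        choices[1] = choices[0]
        with pytest.raises(ro.ReadoutError, match="cover"):
            ro.avoidance_score(choices)


def test_path_segment_choices_from_trajectory(small_cohort):
    """Ten classified segments per generated session, one per trial x leg."""
    sessions, _ = small_cohort
    choices = ro.path_segment_choices(sessions[0])
    assert len(choices) == 10
    assert {(c.trial_index, c.leg) for c in choices} == {
        (tr, leg) for tr in range(1, 6) for leg in ("outward", "return")}
    assert all(c.weight in (0, 1, 2, 4) for c in choices)


# ---------------------------------------------------------------------------
# touch the enemy
# ---------------------------------------------------------------------------


class TestTouchTime:
    def test_simple_difference(self):
        s = make_session(events=make_events(touch_offsets=(3.2, 3.0, 2.0, 2.0)))
        assert ro.touch_time(s, 1) == pytest.approx(3.2)

    def test_touch_at_countdown_end_is_zero(self):
        s = make_session(events=make_events(touch_offsets=(0.0, 1.0, 1.0, 1.0)))
        assert ro.touch_time(s, 1) == 0.0

    def test_order_violation_rejected(self):
        events = [
            TaskEvent(TOUCH_T0, "task_start", "touch_enemy", 1),
            TaskEvent(TOUCH_T0 + 12.0, "countdown_end", "touch_enemy", 1, "spider"),
            TaskEvent(TOUCH_T0 + 11.0, "stimulus_touch", "touch_enemy", 1, "spider"),
        ]
        s = make_session(events=make_events())
        s.events = events
        with pytest.raises(ro.ReadoutError, match="precedes"):
            ro.touch_time(s, 1)


class TestTouchReadout:
    def test_large_difference_truncated_to_20(self):
        s = make_session(events=make_events(touch_offsets=(212.0, 2.0, 3.0, 3.0)))
        assert ro.touch_readout(s) == 20.0

    def test_equal_times_give_zero(self):
        s = make_session(events=make_events(touch_offsets=(4.0, 4.0, 3.0, 3.0)))
        assert ro.touch_readout(s) == 0.0

    def test_negative_difference_not_truncated(self):
        s = make_session(events=make_events(touch_offsets=(2.0, 47.0, 3.0, 3.0)))
        assert ro.touch_readout(s) == pytest.approx(-45.0)

    def test_counterbalanced_turtle_first(self):
        s = make_session(events=make_events(
            touch_stims=("turtle", "spider", "turtle", "spider"),
            touch_offsets=(2.0, 9.0, 2.0, 4.0)))
        assert ro.touch_readout(s) == pytest.approx(7.0)


def _approach_session(speed_profile, touch_offset):
    """Pelvis walks from the start toward the table during trial 1."""
    t = np.arange(0.0, 260.0, 1 / 30)
    pos = np.tile([0.0, 0.95, 0.3], (t.size, 1))
    cd = TOUCH_T0 + 10.0
    sel = (t >= cd) & (t <= cd + touch_offset)
    tau = (t[sel] - cd) / touch_offset
    pos[sel, 2] = 0.3 + 3.05 * speed_profile(tau)
    pos[t > cd + touch_offset, 2] = 0.3 + 3.05
    return make_session(
        events=make_events(touch_offsets=(touch_offset, 3.0, 3.0, 3.0)),
        pelvis_t=t, pelvis_pos=pos)


class TestThirdsDurations:
    def test_constant_speed_equal_thirds(self):
        s = _approach_session(lambda tau: tau, touch_offset=9.0)
        d = ro.thirds_durations(s, 1)
        # walk covers 3.05 m of the 3.5 m axis: the last band is entered at
        # proportion 2/3 * 3.5/3.05 of the walk and is left early
        total = 9.0
        np.testing.assert_allclose(d.sum(), total, atol=0.1)
        np.testing.assert_allclose(d[0], d[1], atol=0.1)

    def test_stall_in_last_band_dominates(self):
        def stall(tau):  # fast to 80 %, then crawl
            return np.where(tau < 0.3, tau * 0.8 / 0.3, 0.8 + 0.2 * (tau - 0.3) / 0.7)
        s = _approach_session(stall, touch_offset=12.0)
        d = ro.thirds_durations(s, 1)
        assert d[2] > d[0] and d[2] > d[1]

    def test_durations_sum_to_touch_time(self):
        s = _approach_session(lambda tau: tau, touch_offset=7.0)
        d = ro.thirds_durations(s, 1)
        assert d.sum() == pytest.approx(ro.touch_time(s, 1), abs=0.05)


class TestTrialAccelChanges:
    def test_straight_constant_velocity_hand_is_zero(self):
        t = np.arange(0.0, 260.0, 1 / 30)
        hand = np.column_stack([np.zeros(t.size), np.full(t.size, 1.1),
                                0.3 + 0.01 * t])
        s = make_session(events=make_events(touch_offsets=(5.0, 3.0, 3.0, 3.0)),
                         hand_t=t, hand_pos=hand)
        assert ro.trial_accel_changes(s, 1) == 0

    def test_tremor_count_capped_at_100(self):
        t = np.arange(0.0, 260.0, 1 / 30)
        rng = np.random.default_rng(2)
        hand = np.column_stack([rng.normal(0, 0.02, t.size),
                                np.full(t.size, 1.1), 0.3 + 0.01 * t])
        s = make_session(events=make_events(touch_offsets=(15.0, 3.0, 3.0, 3.0)),
                         hand_t=t, hand_pos=hand)
        assert ro.trial_accel_changes(s, 1) == 100


class TestPreTouchWindows:
    def test_constant_rr(self):
        rr = np.full(300, 0.9)
        s = make_session(rr_t=0.9 + np.cumsum(rr), rr=rr)
        out = ro.pre_touch_windows(s, 1)
        assert out["rr"] == pytest.approx(0.9, abs=1e-9)

    def test_constant_pupil_rescales_to_zero(self):
        s = make_session()
        out = ro.pre_touch_windows(s, 1)
        assert out["pupil"] == pytest.approx(0.0)
        assert not out["eyes_closed"]

    def test_eye_closed_through_window_flags_exclusion(self):
        gaze_t = np.arange(0.0, 260.0, 1 / 110)
        pupil = np.full(gaze_t.size, 3.5)
        touch = TOUCH_T0 + 13.0  # trial 1 touch with default offsets
        closed = (gaze_t >= touch - 0.6) & (gaze_t < touch + 0.1)
        pupil[closed] = np.nan
        s = make_session(gaze_t=gaze_t, pupil=pupil)
        out = ro.pre_touch_windows(s, 1)
        assert out["eyes_closed"]
        assert math.isnan(out["pupil"])


# ---------------------------------------------------------------------------
# row assembly over synthetic sessions
# ---------------------------------------------------------------------------


def test_readout_rows_satisfy_invariants(cohort31, small_cohort):
    """Full rows from generated sessions pass every range invariant."""
    for sessions, _ in (cohort31, small_cohort):
        for s in sessions:
            row = ro.compute_readout_row(s)
            row.validate()
            assert -14 <= row.path_choice_score <= 14
            assert row.touch_readout <= 20.0
            for v in row.accel_changes.values():
                assert v <= 100
            for v in row.pre_touch_pupil.values():
                assert math.isnan(v) or 0.0 <= v <= 1.0


def test_readouts_table_shape(small_cohort):
    sessions, _ = small_cohort
    df = ro.readouts_table(sessions)
    assert len(df) == len(sessions)
    assert "path_choice_score" in df.columns
    assert df["thirds_spider1_area1"].notna().all()
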