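"""Shared fixtures and builders for handcrafted test sessions."""

from __future__ import annotations

import numpy as np
import pytest

from vrbat.session import (
    GazeStream,
    MotionTrack,
    RRSeries,
    Session,
    TaskEvent,
    default_layout,
)
from vrbat.simulate import CohortConfig, generate_cohort

# default toy timeline: fishing [0, 130], path-choice trials of 10 s from
# 132, approach trials from 190 with configurable touch offsets
PATH_T0 = 132.0
TOUCH_T0 = 190.0
SESSION_END = 260.0


def make_events(touch_stims=("spider", "turtle", "spider", "turtle"),
                touch_offsets=(3.0, 3.0, 3.0, 3.0)):
    ev = [
        TaskEvent(0.0, "task_start", "fishing", 1),
        TaskEvent(0.0, "trial_start", "fishing", 1),
        TaskEvent(10.0, "countdown_end", "fishing", 1),
        TaskEvent(130.0, "trial_end", "fishing", 1),
        TaskEvent(130.0, "task_end", "fishing", 1),
        TaskEvent(PATH_T0, "task_start", "path_choice", 1),
    ]
    for trial in range(1, 6):
        t0 = PATH_T0 + 10.0 * (trial - 1)
        ev.append(TaskEvent(t0, "trial_start", "path_choice", trial))
        ev.append(TaskEvent(t0 + 9.5, "trial_end", "path_choice", trial))
    ev.append(TaskEvent(PATH_T0 + 50.0, "task_end", "path_choice", 5))
    ev.append(TaskEvent(TOUCH_T0, "task_start", "touch_enemy", 1))
    cursor = TOUCH_T0
    for trial, (stim, off) in enumerate(zip(touch_stims, touch_offsets), start=1):
        ev.append(TaskEvent(cursor, "trial_start", "touch_enemy", trial, stim))
        cd = cursor + 10.0
        ev.append(TaskEvent(cd, "countdown_end", "touch_enemy", trial, stim))
        ev.append(TaskEvent(cd + off, "stimulus_touch", "touch_enemy", trial, stim))
        ev.append(TaskEvent(cd + off + 1.0, "trial_end", "touch_enemy", trial, stim))
        cursor = cd + off + 1.5
    ev.append(TaskEvent(cursor, "task_end", "touch_enemy", 4))
    return ev


def make_session(
    pelvis_t=None,
    pelvis_pos=None,
    yaw=None,
    hand_t=None,
    hand_pos=None,
    gaze_t=None,
    focus=None,
    pupil=None,
    valid=None,
    rr_t=None,
    rr=None,
    events=None,
    layout=None,
    group="non_fearful",
    fsq=3.0,
) -> Session:
    """Assemble a session from overridable pieces; defaults are stationary."""
    layout = layout or default_layout()
    if pelvis_t is None:
        pelvis_t = np.arange(0.0, SESSION_END, 1 / 30)
    if pelvis_pos is None:
        pelvis_pos = np.tile([0.5, 0.95, 1.0], (len(pelvis_t), 1))
    if hand_t is None:
        hand_t = pelvis_t
    if hand_pos is None:
        hand_pos = np.asarray(pelvis_pos) + np.array([0.25, 0.15, 0.25])
    if gaze_t is None:
        gaze_t = np.arange(0.0, SESSION_END, 1 / 110)
    n = len(gaze_t)
    if focus is None:
        focus = np.full(n, None, dtype=object)
    if pupil is None:
        pupil = np.full(n, 3.5)
    if valid is None:
        valid = np.isfinite(pupil)
    if rr_t is None:
        rr = np.full(int(SESSION_END / 0.8), 0.8)
        rr_t = 0.8 + np.cumsum(rr)
    head = np.asarray(pelvis_pos) + np.array([0.0, 0.62, 0.0])
    tracks = {
        "pelvis": MotionTrack("pelvis", pelvis_t, pelvis_pos, yaw=yaw),
        "head": MotionTrack("head", pelvis_t, head),
        "right_hand": MotionTrack("right_hand", hand_t, hand_pos),
    }
    gaze = GazeStream(
        t=gaze_t, focus=focus, pupil_left=pupil.copy(), pupil_right=pupil.copy(),
        valid_left=valid.copy(), valid_right=valid.copy(),
    )
    return Session(
        participant_id="T01",
        group=group,
        questionnaire_scales={"FSQ": fsq},
        valence_ratings={"spider": 5.0, "turtle": 7.0},
        tracks=tracks,
        gaze=gaze,
        rr=RRSeries(rr_t, rr),
        events=events if events is not None else make_events(),
        layout=layout,
    )


@pytest.fixture(scope="session")
def cohort31():
    """Default synthetic cohort (15/6/10), seed 1."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort (4/3/4) for pipeline-level tests."""
    return generate_cohort(
        CohortConfig(seed=3, n_phobic=4, n_fearful=3, n_non_fearful=4)
    )
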