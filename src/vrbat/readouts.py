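"""Behavioral readouts of the three VR tasks.

Search task ("fishing"): minimum horizontal pelvis distance to each
stimulus over the 120 s window that starts when the 10 s wait ends; the
readout is the spider minus turtle minimum distance, so positive values
mean the participant stayed farther from the spider.  Detail analyses cover
glance counts, body orientation toward each stimulus, and per-side
heart-rate / pupil summaries based on which half of the field the pelvis
occupies.

Forced-choice task ("path choice"): each of five trials has an outward and
a return passage left or right of the central table, with the book placed
center / right / left / far right / far left so that avoiding an animal can
cost a detour.  Passages are weighted 0 (shorter path), 1 (equal paths),
2 (shorter detour), 4 (longer detour) and signed positive when the chosen
side is not the spider's, yielding an avoidance score in [-14, 14].

Approach task ("touch the enemy"): time from countdown end to stimulus
touch per trial; the readout is the first-spider minus first-turtle time,
truncated at 20 s.  Detail analyses split the approach into three equal
bands along the start-to-table axis, count right-hand acceleration sign
changes (truncated at 100), and average pupil size (0.5 s) and RR interval
(1 s) immediately before the touch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import preprocess as prep
from .session import (
    ReadoutRow,
    SceneLayout,
    Session,
    SessionValidationError,
    MotionTrack,
    STIMULI,
)

FISHING_WAIT_S = 10.0
FISHING_WINDOW_S = 120.0
TOUCH_CAP_S = 20.0
ACCEL_CAP = 100
PRE_TOUCH_PUPIL_S = 0.5
PRE_TOUCH_RR_S = 1.0

_WEIGHTS = {
    "center": {"left": 1, "right": 1},
    "right": {"right": 0, "left": 2},
    "left": {"left": 0, "right": 2},
    "far_right": {"right": 0, "left": 4},
    "far_left": {"left": 0, "right": 4},
}


class ReadoutError(ValueError):
    """A readout cannot be computed from the given session."""


def _side_of_x(x: float) -> str:
    return "left" if x < 0 else "right"


def _horizontal(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return p[..., [0, 2]]


# ---------------------------------------------------------------------------
# fishing
# ---------------------------------------------------------------------------


def fishing_window(session: Session) -> tuple[float, float]:
    """Analysis window: 120 s starting at the end of the 10 s wait."""
    start = session.find_event("countdown_end", "fishing").t
    return (start, start + FISHING_WINDOW_S)


def _pelvis_in_window(session: Session, window) -> tuple[np.ndarray, np.ndarray]:
    track = session.tracks["pelvis"]
    if track.t[0] > window[0] + 1e-9 or track.t[-1] < window[1] - 1e-9:
        raise ReadoutError(
            f"pelvis track [{track.t[0]:.2f}, {track.t[-1]:.2f}] does not cover "
            f"window [{window[0]:.2f}, {window[1]:.2f}]"
        )
    sel = (track.t >= window[0]) & (track.t <= window[1])
    return track.t[sel], track.position[sel]


def fishing_min_distance(session: Session, stimulus: str) -> float:
    """Minimum horizontal pelvis distance to a stimulus over the window."""
    window = fishing_window(session)
    _, pos = _pelvis_in_window(session, window)
    stim = session.layout.stimulus_positions["fishing"][1][stimulus]
    d = np.linalg.norm(_horizontal(pos) - _horizontal(stim), axis=1)
    return float(np.min(d))


def fishing_readout(session: Session) -> float:
    """Spider minus turtle minimum distance; positive = stayed farther from spider."""
    return fishing_min_distance(session, "spider") - fishing_min_distance(session, "turtle")


def fishing_glance_difference(session: Session, max_gap: float = 0.2) -> int:
    """Spider minus turtle glance counts within the fishing window."""
    window = fishing_window(session)
    spider = prep.segment_glances(session.gaze, "spider", max_gap=max_gap, window=window)
    turtle = prep.segment_glances(session.gaze, "turtle", max_gap=max_gap, window=window)
    return spider.count - turtle.count


def side_occupancy(session: Session, window=None) -> dict:
    """Time intervals during which the pelvis occupies each half (by x sign)."""
    if window is None:
        window = fishing_window(session)
    t, pos = _pelvis_in_window(session, window)
    sides = np.where(pos[:, 0] < 0, "left", "right")
    ends = np.empty_like(t)
    ends[:-1] = t[1:]
    ends[-1] = window[1]
    out = {"left": [], "right": []}
    run_start, run_side = t[0], sides[0]
    for i in range(1, t.size):
        if sides[i] != run_side:
            out[run_side].append((run_start, t[i]))
            run_start, run_side = t[i], sides[i]
    out[run_side].append((run_start, ends[-1]))
    return out


def fishing_orientation(session: Session, stimulus: str) -> float:
    """Mean pelvis-to-stimulus angle (degrees) while on that stimulus' half.

    0 means the hips faced the stimulus, 180 that the back did.  Returns NaN
    when the participant never entered that half (exclusion case).
    """
    track = session.tracks["pelvis"]
    if track.yaw is None:
        raise ReadoutError("pelvis yaw absent; orientation not computable")
    window = fishing_window(session)
    sel = (track.t >= window[0]) & (track.t <= window[1])
    pos, yaw = track.position[sel], track.yaw[sel]
    stim = np.asarray(session.layout.stimulus_positions["fishing"][1][stimulus], float)
    side = _side_of_x(stim[0])
    on_side = (pos[:, 0] < 0) if side == "left" else (pos[:, 0] >= 0)
    if not on_side.any():
        return float("nan")
    rad = np.deg2rad(yaw[on_side])
    fwd = np.column_stack([-np.sin(rad), np.cos(rad)])  # yaw 0 faces +z
    to_stim = _horizontal(stim) - _horizontal(pos[on_side])
    norm = np.linalg.norm(to_stim, axis=1)
    norm[norm == 0] = 1.0
    cosang = np.clip(np.einsum("ij,ij->i", fwd, to_stim) / norm, -1.0, 1.0)
    return float(np.mean(np.degrees(np.arccos(cosang))))


def fishing_side_physiology(
    session: Session, eye: str = "right"
) -> dict:
    """Mean RR interval and mean preprocessed pupil size per stimulus side.

    Averages run over the time intervals during which the pelvis occupied
    the half containing each stimulus; a never-entered side yields NaN.
    """
    occ = side_occupancy(session)
    spider_side = session.layout.spider_side("fishing", 1)
    task_seg = session.task_window("fishing")
    pupil = prep.preprocess_pupil(session.gaze, eye, window=task_seg)
    out = {}
    for stimulus in STIMULI:
        side = spider_side if stimulus == "spider" else (
            "right" if spider_side == "left" else "left"
        )
        intervals = occ[side]
        if not intervals:
            out[stimulus] = {"rr": float("nan"), "pupil": float("nan")}
            continue
        out[stimulus] = {
            "rr": prep.mean_rr_in_windows(session.rr, intervals),
            "pupil": pupil.mean_in_windows(intervals),
        }
    return out


# ---------------------------------------------------------------------------
# path choice
# ---------------------------------------------------------------------------


@dataclass
class PathSegmentChoice:
    """One scored passage (outward or return) of a forced-choice trial."""

    trial_index: int
    leg: str  # outward | return
    chosen_side: str
    spider_side: str
    book_offset: str
    weight: int
    signed_contribution: int


def segment_weight(book_offset: str, chosen_side: str) -> int:
    """Cost-of-avoidance weight of passing on ``chosen_side``.

    0 = shorter path (book's near side), 1 = equal paths (book centered),
    2 = shorter detour, 4 = longer detour.
    """
    try:
        return _WEIGHTS[book_offset][chosen_side]
    except KeyError:
        raise ReadoutError(f"unknown book offset {book_offset!r} or side {chosen_side!r}")


def make_segment_choice(
    layout: SceneLayout,
    trial_index: int,
    leg: str,
    chosen_side: str,
    spider_positive: bool = True,
) -> PathSegmentChoice:
    book = layout.book_offsets[trial_index - 1]
    spider_side = layout.spider_side("path_choice", trial_index)
    w = segment_weight(book, chosen_side)
    avoided = chosen_side != spider_side
    sign = 1 if avoided == spider_positive else -1
    return PathSegmentChoice(
        trial_index=trial_index,
        leg=leg,
        chosen_side=chosen_side,
        spider_side=spider_side,
        book_offset=book,
        weight=w,
        signed_contribution=sign * w,
    )


def make_policy_choices(layout: SceneLayout, policy: str, **kw) -> list:
    """Choices of a fixed policy: 'always_turtle' or 'always_spider'."""
    choices = []
    for trial in range(1, 6):
        spider_side = layout.spider_side("path_choice", trial)
        side = spider_side if policy == "always_spider" else (
            "right" if spider_side == "left" else "left"
        )
        for leg in ("outward", "return"):
            choices.append(make_segment_choice(layout, trial, leg, side, **kw))
    return choices


def classify_path_side(
    track: MotionTrack, window: tuple[float, float], layout: SceneLayout
) -> str:
    """Side of the first gate-line crossing within a leg's window.

    The gate line is the table's z-midline; left = x < 0 at the crossing.
    Re-crossings later in the leg do not reclassify.
    """
    sel = (track.t >= window[0]) & (track.t <= window[1])
    t, pos = track.t[sel], track.position[sel]
    if t.size < 2:
        raise ReadoutError("leg window not covered by track")
    z = pos[:, 2] - layout.gate_z
    cross = np.nonzero(z[:-1] * z[1:] < 0)[0]
    on_line = np.nonzero(z == 0)[0]
    if cross.size == 0 and on_line.size == 0:
        raise ReadoutError(
            f"gate line never crossed in window [{window[0]:.2f}, {window[1]:.2f}]"
        )
    if cross.size and (not on_line.size or cross[0] < on_line[0]):
        i = cross[0]
        frac = z[i] / (z[i] - z[i + 1])
        x = pos[i, 0] + frac * (pos[i + 1, 0] - pos[i, 0])
    else:
        x = pos[on_line[0], 0]
    return _side_of_x(x)


def path_segment_choices(session: Session, spider_positive: bool = True) -> list:
    """Classify and weight all ten passages of the forced-choice task.

    Each trial window is split at the moment of deepest penetration (the
    book pickup at the counter); the outward and return legs are classified
    by their first gate crossing.
    """
    track = session.tracks["pelvis"]
    choices = []
    for trial in range(1, 6):
        t0 = session.find_event("trial_start", "path_choice", trial).t
        t1 = session.find_event("trial_end", "path_choice", trial).t
        sel = (track.t >= t0) & (track.t <= t1)
        if not sel.any():
            raise ReadoutError(f"no pelvis samples in path-choice trial {trial}")
        tt = track.t[sel]
        split = float(tt[np.argmax(track.position[sel, 2])])
        for leg, win in (("outward", (t0, split)), ("return", (split, t1))):
            side = classify_path_side(track, win, session.layout)
            choices.append(
                make_segment_choice(session.layout, trial, leg, side,
                                    spider_positive=spider_positive)
            )
    return choices


def avoidance_score(choices) -> int:
    """Sum the ten signed, cost-weighted passage contributions.

    +14 means the spider side was never taken, -14 that it always was.
    """
    if len(choices) != 10:
        raise ReadoutError(f"need exactly 10 segment choices, got {len(choices)}")
    keys = {(c.trial_index, c.leg) for c in choices}
    expect = {(tr, leg) for tr in range(1, 6) for leg in ("outward", "return")}
    if keys != expect:
        raise ReadoutError("choices must cover trials 1..5 x {outward, return}")
    score = int(sum(c.signed_contribution for c in choices))
    if not -14 <= score <= 14:  # pragma: no cover - guaranteed by weight table
        raise ReadoutError(f"score {score} outside [-14, 14]")
    return score


# ---------------------------------------------------------------------------
# touch the enemy
# ---------------------------------------------------------------------------


def touch_time(session: Session, trial: int) -> float:
    """Seconds from countdown end to the stimulus touch of one trial."""
    cd = session.find_event("countdown_end", "touch_enemy", trial).t
    touch = session.find_event("stimulus_touch", "touch_enemy", trial).t
    if touch < cd:
        raise ReadoutError(f"trial {trial}: touch precedes countdown end")
    return touch - cd


def _touch_trial_stimuli(session: Session) -> list:
    stims = []
    for trial in range(1, 5):
        ev = session.find_event("stimulus_touch", "touch_enemy", trial)
        stims.append(ev.stimulus)
    return stims


def touch_readout(session: Session, cap: float = TOUCH_CAP_S) -> float:
    """First-spider minus first-turtle time to touch, truncated at ``cap``.

    The cap applies to the upper side only; faster spider touches give
    negative, untruncated values.
    """
    stims = _touch_trial_stimuli(session)
    first_spider = stims.index("spider") + 1
    first_turtle = stims.index("turtle") + 1
    diff = touch_time(session, first_spider) - touch_time(session, first_turtle)
    return float(prep.truncate_value(diff, cap))


def thirds_durations(session: Session, trial: int) -> np.ndarray:
    """Seconds spent in each of three equal bands along the start-table axis.

    The axis from the approach start position to the stimulus table is
    split into three equal-length bands by projection; time between the
    countdown end and the touch is accumulated per band.  Whenever the
    pelvis stays between start and table, the three durations sum to the
    trial's time to touch.
    """
    cd = session.find_event("countdown_end", "touch_enemy", trial).t
    touch = session.find_event("stimulus_touch", "touch_enemy", trial).t
    track = session.tracks["pelvis"]
    sel = (track.t >= cd) & (track.t <= touch)
    t, pos = track.t[sel], track.position[sel]
    if t.size == 0:
        raise ReadoutError(f"no pelvis samples between countdown and touch (trial {trial})")
    start = _horizontal(session.layout.touch_start)
    table = _horizontal(session.layout.table_position)
    axis = table - start
    length = np.linalg.norm(axis)
    u = axis / length
    proj = ((_horizontal(pos) - start) @ u) / length
    band = np.floor(proj * 3).astype(int)
    band[proj >= 1.0] = 2
    dt = np.empty_like(t)
    dt[:-1] = np.diff(t)
    dt[-1] = touch - t[-1]
    out = np.zeros(3)
    for k in range(3):
        out[k] = dt[(band == k) & (proj >= 0.0) & (proj <= 1.0 + 1e-12)].sum()
    return out


def trial_accel_changes(session: Session, trial: int, cap: int = ACCEL_CAP) -> int:
    """Right-hand acceleration sign changes during one approach, capped.

    The irregular hand track between countdown end and touch is
    spline-resampled to 10 Hz; sign changes of the second difference are
    counted and truncated at ``cap``.
    """
    cd = session.find_event("countdown_end", "touch_enemy", trial).t
    touch = session.find_event("stimulus_touch", "touch_enemy", trial).t
    grid = prep.resample_track(session.tracks["right_hand"], rate=10.0, window=(cd, touch))
    return int(prep.truncate_value(prep.count_acceleration_sign_changes(grid), cap))


def pre_touch_windows(
    session: Session,
    trial: int,
    pupil_series: prep.RegularSeries | None = None,
    pupil_window: float = PRE_TOUCH_PUPIL_S,
    rr_window: float = PRE_TOUCH_RR_S,
    eye: str = "right",
) -> dict:
    """Pre-touch pupil (0.5 s) and RR (1 s) means for one approach trial.

    If the eye was closed (no valid raw sample) throughout the pupil window
    the pupil value is missing and ``eyes_closed`` is flagged, mirroring the
    participant-level exclusion.  ``pupil_series`` may carry a precomputed
    per-task preprocessed series to avoid recomputation across trials.
    """
    touch = session.find_event("stimulus_touch", "touch_enemy", trial).t
    if pupil_series is None:
        pupil_series = prep.preprocess_pupil(
            session.gaze, eye, window=session.task_window("touch_enemy")
        )
    pwin = (touch - pupil_window, touch)
    raw_sel = (session.gaze.t >= pwin[0]) & (session.gaze.t < pwin[1])
    valid = getattr(session.gaze, f"valid_{eye}")[raw_sel]
    eyes_closed = bool(raw_sel.any()) and not bool(valid.any())
    pupil = float("nan") if eyes_closed else pupil_series.mean_in_windows([pwin])
    rr = prep.mean_rr_in_windows(session.rr, [(touch - rr_window, touch)])
    return {"pupil": pupil, "rr": rr, "eyes_closed": eyes_closed}


# ---------------------------------------------------------------------------
# row assembly
# ---------------------------------------------------------------------------


def compute_core_readouts(session: Session) -> dict:
    """The three primary task readouts plus grouping metadata (fast path)."""
    return {
        "participant_id": session.participant_id,
        "group": session.group,
        "fsq": session.questionnaire_scales["FSQ"],
        "fishing_readout": fishing_readout(session),
        "path_choice_score": avoidance_score(path_segment_choices(session)),
        "touch_readout": touch_readout(session),
    }


def compute_readout_row(session: Session, eye: str = "right") -> ReadoutRow:
    """Derive the full per-participant readout row from a session."""
    min_s = fishing_min_distance(session, "spider")
    min_t = fishing_min_distance(session, "turtle")
    win = fishing_window(session)
    glances = {
        s: prep.segment_glances(session.gaze, s, window=win).count for s in STIMULI
    }
    angles = {s: fishing_orientation(session, s) for s in STIMULI}
    never_entered = math.isnan(angles["spider"])
    physio = fishing_side_physiology(session, eye=eye)

    score = avoidance_score(path_segment_choices(session))

    stims = _touch_trial_stimuli(session)
    first = {"spider": stims.index("spider") + 1, "turtle": stims.index("turtle") + 1}
    thirds, accel, pp, prr = {}, {}, {}, {}
    eyes_closed = False
    missing_rr = False
    pupil_series = prep.preprocess_pupil(
        session.gaze, eye, window=session.task_window("touch_enemy")
    )
    occurrence = {"spider": 0, "turtle": 0}
    for trial in range(1, 5):
        stim = stims[trial - 1]
        occurrence[stim] += 1
        occ = occurrence[stim]
        d = thirds_durations(session, trial)
        for area in range(3):
            thirds[(stim, occ, area + 1)] = float(d[area])
        accel[(stim, occ)] = trial_accel_changes(session, trial)
        pt = pre_touch_windows(session, trial, pupil_series=pupil_series, eye=eye)
        pp[(stim, occ)] = pt["pupil"]
        prr[(stim, occ)] = pt["rr"]
        eyes_closed |= pt["eyes_closed"]
        missing_rr |= math.isnan(pt["rr"])

    row = ReadoutRow(
        participant_id=session.participant_id,
        group=session.group,
        fsq=session.questionnaire_scales["FSQ"],
        valence_spider=session.valence_ratings.get("spider", float("nan")),
        valence_turtle=session.valence_ratings.get("turtle", float("nan")),
        fishing_min_dist_spider=min_s,
        fishing_min_dist_turtle=min_t,
        fishing_readout=min_s - min_t,
        fishing_glances_spider=glances["spider"],
        fishing_glances_turtle=glances["turtle"],
        fishing_glance_diff=glances["spider"] - glances["turtle"],
        fishing_angle_spider=angles["spider"],
        fishing_angle_turtle=angles["turtle"],
        fishing_rr_spider_side=physio["spider"]["rr"],
        fishing_rr_turtle_side=physio["turtle"]["rr"],
        fishing_pupil_spider_side=physio["spider"]["pupil"],
        fishing_pupil_turtle_side=physio["turtle"]["pupil"],
        path_choice_score=score,
        touch_time_spider1=touch_time(session, first["spider"]),
        touch_time_turtle1=touch_time(session, first["turtle"]),
        touch_readout=touch_readout(session),
        thirds_durations=thirds,
        accel_changes=accel,
        pre_touch_pupil=pp,
        pre_touch_rr=prr,
        excluded_never_entered_spider_side=never_entered,
        excluded_eyes_closed_pre_touch=eyes_closed,
        excluded_missing_rr=missing_rr,
    )
    row.validate()
    return row


def readouts_table(sessions, **kw) -> pd.DataFrame:
    """Stack full readout rows for a cohort into one DataFrame."""
    return pd.DataFrame([compute_readout_row(s, **kw).to_flat_dict() for s in sessions])
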