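"""Synthetic cohort generator.

Emits complete sessions — motion tracks, gaze/pupil streams, RR beat
series, event logs, scene layouts, questionnaire scores — whose statistical
structure is driven by a single latent spider-aversion scalar per
participant.  The aversion drives every modality through configurable
gains: repulsion from the spider plank in the search task, attentional
glances toward the spider, body orientation toward it while on its half,
side-dependent heart-rate increase, avoidance choices under detour costs in
the forced-choice task, proximity-dependent hesitation and right-hand
tremor in the approach task, and pre-touch pupil dilation / RR shortening.

Group structure follows the study design this emulates: 15 phobic, 6
fearful and 10 non-fearful participants; trait fear (FSQ) is drawn per
group so that non-fearfuls stay at or below the cutoff of 8 and fearfuls
above it, rank-consistent with the latent aversion.  Defaults are chosen so
phobic vs non-fearful contrasts land at large standardized effects (Glass
Delta roughly 1.5-3), the order reported for real phobic cohorts, without
claiming any exact statistic.

Generation is deterministic given the seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .session import (
    GazeStream,
    MotionTrack,
    RRSeries,
    SceneLayout,
    Session,
    TaskEvent,
    default_layout,
    write_session,
)

FSQ_RANGES = {"non_fearful": (0, 8), "fearful": (9, 40), "phobic": (60, 108)}


class CohortConfig(BaseModel):
    """Cohort structure, latent-trait distribution, and modality gains."""

    n_phobic: int = 15
    n_fearful: int = 6
    n_non_fearful: int = 10
    aversion_mean_phobic: float = 2.0
    aversion_mean_fearful: float = 1.0
    aversion_mean_non_fearful: float = 0.0
    aversion_sd: float = 0.4
    #: fractional reduction of spider-trial hesitation on the second exposure
    habituation: float = Field(default=0.4, ge=0.0, le=1.0)
    counterbalance: bool = True
    # modality gains (per unit aversion)
    repulsion_gain: float = 0.5
    glance_gain: float = 1.0
    yaw_gain: float = 0.3
    rr_side_drop: float = 0.03
    choice_beta: float = 2.5
    choice_cost_scale: float = 1.0
    hesitation_gain: float = 1.5
    hand_jitter_gain: float = 1.0
    pupil_dilation_gain: float = 0.25
    rr_touch_drop: float = 0.05
    # noise scales
    avoid_radius_cap: float = 2.0
    trajectory_noise: float = 0.35
    pupil_noise: float = 0.03
    rr_noise: float = 0.03
    pace_sd: float = 0.12
    pause_rate: float = 0.08
    pause_mean_s: float = 2.0
    # stream rates
    motion_rate: float = 90.0
    gaze_rate: float = 110.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if min(self.n_phobic, self.n_fearful, self.n_non_fearful) < 0:
            raise ValueError("group counts must be >= 0")
        if not (
            self.aversion_mean_phobic
            >= self.aversion_mean_fearful
            >= self.aversion_mean_non_fearful
        ):
            raise ValueError("aversion means must be ordered phobic >= fearful >= non_fearful")
        return self


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _grid(t0: float, t1: float, rate: float) -> np.ndarray:
    n = max(int(np.floor((t1 - t0) * rate)), 2)
    return t0 + np.arange(n) / rate


def _fsq_scores(rng, group: str, aversion: np.ndarray) -> np.ndarray:
    """Rank-preserving integer FSQ totals honoring the cutoff-8 partition."""
    lo, hi = FSQ_RANGES[group]
    draws = np.sort(rng.integers(lo, hi + 1, size=aversion.size))
    ranks = np.argsort(np.argsort(aversion))
    return draws[ranks]


def _standing(rng, center, t: np.ndarray, sway: float = 0.01) -> np.ndarray:
    pos = np.tile(np.asarray(center, float), (t.size, 1))
    pos[:, [0, 2]] += rng.normal(0, sway, (t.size, 2))
    return pos


# ---------------------------------------------------------------------------
# per-task simulators
# ---------------------------------------------------------------------------


def simulate_fishing(rng, aversion: float, layout: SceneLayout, cfg: CohortConfig,
                     t0: float):
    """Bounded drift walk with aversion-scaled repulsion from the spider.

    Returns motion samples for the pelvis over [t0, t0+130] (10 s wait plus
    120 s of searching), with yaw biased toward the spider while on its
    half, plus the fishing event times.  Exploration waypoints within the
    aversion-scaled avoidance radius of the spider are resampled, so highly
    averse participants rarely (or never) enter the spider half.
    """
    import math

    spider = np.asarray(layout.stimulus_positions["fishing"][1]["spider"], float)
    sx, sz = float(spider[0]), float(spider[2])
    hw = layout.field_width / 2 - 0.25
    z_lo, z_hi = 0.25, layout.field_depth - 0.25
    dt = 0.2  # decision step of the walk
    n = int(130.0 / dt)
    pos = np.empty((n, 2))
    px = float(layout.start_position[0])
    pz = float(layout.start_position[2])
    wx, wz = px, pz
    av = max(aversion, 0.0)
    r_avoid = min(0.55 * av, cfg.avoid_radius_cap)
    noise = rng.normal(0, cfg.trajectory_noise, (n, 2))
    for i in range(n):
        if i * dt >= 10.0:
            if i % 40 == 0 or (wx - px) ** 2 + (wz - pz) ** 2 < 0.09:
                for _ in range(15):
                    wx = rng.uniform(-hw, hw)
                    wz = rng.uniform(z_lo, z_hi)
                    if math.hypot(wx - sx, wz - sz) >= r_avoid:
                        break
            dx, dz = wx - px, wz - pz
            d_wp = max(math.hypot(dx, dz), 1.0)
            vx, vz = 0.8 * dx / d_wp, 0.8 * dz / d_wp
            ax, az = px - sx, pz - sz
            d_sp = max(math.hypot(ax, az), 0.3)
            rep = min(cfg.repulsion_gain * av / d_sp, 1.5)
            vx += rep * ax / d_sp + noise[i, 0]
            vz += rep * az / d_sp + noise[i, 1]
            px = min(max(px + vx * dt, -hw), hw)
            pz = min(max(pz + vz * dt, z_lo), z_hi)
        pos[i, 0] = px
        pos[i, 1] = pz
    ts = t0 + np.arange(n) * dt
    grid = _grid(t0, t0 + 130.0, cfg.motion_rate)
    x = np.interp(grid, ts, pos[:, 0])
    z = np.interp(grid, ts, pos[:, 1])
    # yaw: face walking direction; bias toward the spider while on its half
    dx = np.gradient(x)
    dz = np.gradient(z)
    speed = np.hypot(dx, dz)
    yaw_move = np.degrees(np.arctan2(-dx, dz))
    yaw_move[speed < 1e-5] = 0.0
    to_sp = np.degrees(np.arctan2(-(spider[0] - x), spider[2] - z))
    on_side = np.sign(x) == np.sign(spider[0])
    w = np.clip(cfg.yaw_gain * av, 0.0, 0.9)
    # blend angles through unit vectors to avoid wrap-around artifacts
    ang_m, ang_s = np.deg2rad(yaw_move), np.deg2rad(to_sp)
    vx = (1 - w) * np.sin(ang_m) + np.where(on_side, w, 0) * np.sin(ang_s)
    vz = (1 - w) * np.cos(ang_m) + np.where(on_side, w, 0) * np.cos(ang_s)
    yaw = np.degrees(np.arctan2(vx, vz)) + rng.normal(0, 2.0, grid.size)
    pelvis = np.column_stack([x, np.full(grid.size, 0.95), z])
    events = [
        TaskEvent(t0, "task_start", "fishing", 1),
        TaskEvent(t0, "trial_start", "fishing", 1),
        TaskEvent(t0 + 10.0, "countdown_end", "fishing", 1),
        TaskEvent(t0 + 130.0, "trial_end", "fishing", 1),
        TaskEvent(t0 + 130.0, "task_end", "fishing", 1),
    ]
    return grid, pelvis, yaw, events


def simulate_path_choice(rng, aversion: float, layout: SceneLayout,
                         cfg: CohortConfig, t0: float):
    """Logistic side choices under detour costs, with walk trajectories.

    Per passage, utility = -cost(side) - beta * aversion * [side has the
    spider]; at zero aversion the shorter path is preferred and the
    equal-path trial is a coin flip.
    """
    from .readouts import segment_weight  # weight table doubles as cost table

    book_x = {"center": 0.0, "right": 0.7, "left": -0.7,
              "far_right": 1.4, "far_left": -1.4}
    av = max(aversion, 0.0)
    start = np.array([0.0, 0.6])
    events, chosen = [], []
    seg_t, seg_xz = [], []
    cursor = t0
    for trial in range(1, 6):
        book = layout.book_offsets[trial - 1]
        spider_side = layout.spider_side("path_choice", trial)
        counter = np.array([book_x[book], 3.4])
        events.append(TaskEvent(cursor, "trial_start", "path_choice", trial))
        waypoints = [start]
        times = [cursor]
        for leg in ("outward", "return"):
            utils = {}
            for side in ("left", "right"):
                cost = cfg.choice_cost_scale * segment_weight(book, side)
                utils[side] = -cost - cfg.choice_beta * av * (side == spider_side)
            p_left = 1.0 / (1.0 + np.exp(utils["right"] - utils["left"]))
            side = "left" if rng.uniform() < p_left else "right"
            chosen.append(side)
            gate = np.array([-0.9 if side == "left" else 0.9, layout.gate_z])
            target = counter if leg == "outward" else start
            speed = 1.1 * (1 + rng.normal(0, cfg.pace_sd))
            speed = max(speed, 0.5)
            for wpt in (gate, target):
                dist = np.linalg.norm(wpt - waypoints[-1])
                times.append(times[-1] + dist / speed + 0.2)
                waypoints.append(wpt)
            times[-1] += 0.8  # dwell at the counter / shelf
        trial_end = times[-1] + 0.3
        grid = _grid(cursor, trial_end, cfg.motion_rate)
        wp = np.array(waypoints)
        tt = np.array(times)
        x = np.interp(grid, tt, wp[:, 0]) + rng.normal(0, 0.015, grid.size)
        z = np.interp(grid, tt, wp[:, 1]) + rng.normal(0, 0.015, grid.size)
        seg_t.append(grid)
        seg_xz.append(np.column_stack([x, z]))
        events.append(TaskEvent(trial_end, "trial_end", "path_choice", trial))
        cursor = trial_end + 0.5
    t = np.concatenate(seg_t)
    xz = np.vstack(seg_xz)
    pelvis = np.column_stack([xz[:, 0], np.full(t.size, 0.95), xz[:, 1]])
    events.insert(0, TaskEvent(t0, "task_start", "path_choice", 1))
    events.append(TaskEvent(cursor, "task_end", "path_choice", 5))
    return t, pelvis, events, chosen, cursor


def simulate_touch(rng, aversion: float, layout: SceneLayout, cfg: CohortConfig,
                   t0: float):
    """Four alternating approach trials with proximity-dependent hesitation.

    Hesitation (slowdown concentrated in the last third), hand tremor,
    pre-touch pupil dilation and RR shortening all scale with aversion on
    spider trials; the second spider exposure is attenuated by the
    habituation factor.
    """
    order = [layout.stimulus_positions["touch_enemy"][i + 1] for i in range(4)]
    stims = [next(iter(d)) for d in order]
    start = np.array([layout.touch_start[0], layout.touch_start[2]])
    table = np.array([layout.table_position[0], layout.table_position[2]])
    reach = table - start
    length = np.linalg.norm(reach) - 0.45  # touch at arm's length from the table
    u = reach / np.linalg.norm(reach)
    av = max(aversion, 0.0)
    events = [TaskEvent(t0, "task_start", "touch_enemy", 1)]
    seg_t, seg_pelvis, seg_hand = [], [], []
    touch_info = []  # (touch_t, a_eff) per trial, for pupil/RR modulation
    cursor = t0
    spider_seen = 0
    dt = 1.0 / 30.0
    for trial, stim in enumerate(stims, start=1):
        events.append(TaskEvent(cursor, "trial_start", "touch_enemy", trial, stim))
        cd_end = cursor + 10.0
        events.append(TaskEvent(cd_end, "countdown_end", "touch_enemy", trial, stim))
        grid0 = _grid(cursor, cd_end, cfg.motion_rate)
        stand = _standing(rng, [start[0], 0.95, start[1]], grid0)

        if stim == "spider":
            spider_seen += 1
            a_eff = av * (1.0 - cfg.habituation) if spider_seen == 2 else av
        else:
            a_eff = 0.0
        h = cfg.hesitation_gain * a_eff
        pace = max(1 + rng.normal(0, cfg.pace_sd), 0.6)
        v0 = 0.85 * pace
        reaction = rng.uniform(0.3, 2.5)
        # step the walk; random pauses emulate everyday distraction
        max_steps = int(25.0 / dt)
        pause_draw = rng.uniform(size=max_steps)
        pause_len = rng.exponential(cfg.pause_mean_s, size=max_steps)
        prog, tw, pause_left = 0.0, reaction, 0.0
        walk_t, walk_p = [0.0], [0.0]
        for step in range(max_steps):
            if prog >= 1.0:
                break
            if pause_left > 0:
                pause_left -= dt
            else:
                if pause_draw[step] < cfg.pause_rate * dt:
                    pause_left = pause_len[step]
                v = v0 / (1.0 + 3.0 * h * prog**4)
                prog += v * dt / length
            tw += dt
            walk_t.append(tw)
            walk_p.append(min(prog, 1.0))
        touch_t = cd_end + tw
        gridw = _grid(cd_end, touch_t, cfg.motion_rate)
        pw = np.interp(gridw - cd_end, walk_t, walk_p)
        xz = start + pw[:, None] * (length * u)
        walk = np.column_stack([xz[:, 0], np.full(gridw.size, 0.95), xz[:, 1]])
        grid = np.concatenate([grid0, gridw])
        pelvis = np.vstack([stand, walk])

        # right hand: offset from pelvis, slow sinusoidal wobble, and a
        # tremor whose frequency grows with effective aversion so that the
        # 10 Hz acceleration-sign-change count grades with fear level
        hand = pelvis + np.array([0.25, 0.15, 0.25])
        hand[grid0.size:, 1] += 0.15 * pw  # raise toward the 1.1 m table
        rel = grid - grid[0]
        for ax in range(3):
            f = rng.uniform(0.4, 0.8)
            phase = rng.uniform(0, 2 * np.pi)
            hand[:, ax] += 0.02 * np.sin(2 * np.pi * f * rel + phase)
        if a_eff > 0 and cfg.hand_jitter_gain > 0:
            amp = 0.01 * min(cfg.hand_jitter_gain * a_eff, 1.0)
            f_trem = 0.8 + 1.3 * cfg.hand_jitter_gain * a_eff
            for ax in range(3):
                phase = rng.uniform(0, 2 * np.pi)
                hand[:, ax] += amp * np.sin(2 * np.pi * f_trem * rel + phase)

        seg_t.append(grid)
        seg_pelvis.append(pelvis)
        seg_hand.append(hand)
        events.append(TaskEvent(touch_t, "stimulus_touch", "touch_enemy", trial, stim))
        touch_info.append((touch_t, a_eff))
        trial_end = touch_t + 1.0
        grid1 = _grid(touch_t, trial_end, cfg.motion_rate)
        # step back and stand until the next trial
        seg_t.append(grid1[1:])
        back = _standing(rng, [xz[-1, 0], 0.95, xz[-1, 1]], grid1[1:])
        seg_pelvis.append(back)
        seg_hand.append(back + np.array([0.25, 0.15, 0.25]))
        events.append(TaskEvent(trial_end, "trial_end", "touch_enemy", trial, stim))
        cursor = trial_end + 0.5
    events.append(TaskEvent(cursor, "task_end", "touch_enemy", 4))
    t = np.concatenate(seg_t)
    return t, np.vstack(seg_pelvis), np.vstack(seg_hand), events, touch_info, cursor


# ---------------------------------------------------------------------------
# physiology across the session
# ---------------------------------------------------------------------------


def _simulate_gaze(rng, cfg: CohortConfig, t_end: float, fishing_win, aversion,
                   touch_info):
    """Gaze focus labels and two-eye pupil streams over the whole session."""
    av = max(aversion, 0.0)
    n = int(t_end * cfg.gaze_rate)
    t = np.arange(n) / cfg.gaze_rate
    t += rng.uniform(0.05, 0.45, n) / cfg.gaze_rate  # slight frame jitter
    focus = np.full(n, None, dtype=object)

    # glance renewal process during the search window
    lam_s = 0.06 * (1.0 + cfg.glance_gain * av)
    lam_t = 0.06
    cur = fishing_win[0]
    while cur < fishing_win[1]:
        cur += rng.exponential(1.0 / (lam_s + lam_t))
        if cur >= fishing_win[1]:
            break
        target = "spider" if rng.uniform() < lam_s / (lam_s + lam_t) else "turtle"
        dur = min(rng.gamma(2.0, 0.35), fishing_win[1] - cur)
        i0, i1 = np.searchsorted(t, [cur, cur + dur])
        focus[i0:i1] = target
        cur += dur

    base = 3.5 + rng.normal(0, 0.2)
    slow = 0.15 * np.sin(2 * np.pi * t / rng.uniform(40, 70))
    dilation = np.zeros(n)
    for touch_t, a_eff in touch_info:
        ramp = np.clip((t - (touch_t - 2.0)) / 2.0, 0.0, 1.0) * (t < touch_t + 1.0)
        dilation += cfg.pupil_dilation_gain * a_eff * ramp
    pupil = {}
    valid = {}
    blink = np.zeros(n, dtype=bool)
    cur = 0.0
    while cur < t_end:
        cur += rng.exponential(1.0 / 0.15)
        d = rng.uniform(0.1, 0.35)
        i0, i1 = np.searchsorted(t, [cur, cur + d])
        blink[i0:i1] = True
        cur += d
    for eye in ("left", "right"):
        v = base + slow + dilation + rng.normal(0, cfg.pupil_noise, n)
        spikes = rng.uniform(size=n) < 0.03 / cfg.gaze_rate * 60
        v[spikes] += rng.choice([-1.5, 1.5], size=int(spikes.sum()))
        v[blink] = np.nan
        pupil[eye] = v
        valid[eye] = ~blink
    return GazeStream(
        t=t, focus=focus, pupil_left=pupil["left"], pupil_right=pupil["right"],
        valid_left=valid["left"], valid_right=valid["right"],
        nominal_rate=cfg.gaze_rate,
    )


def _simulate_rr(rng, cfg: CohortConfig, t_end: float, fishing_win,
                 pelvis_t, pelvis_x, spider_x_sign, aversion, touch_info):
    """Beat-event RR series with side- and pre-touch modulation."""
    av = max(aversion, 0.0)
    base = 0.85 + rng.normal(0, 0.04)
    # coarse lookup of "pelvis on spider half" during the search window
    lut_rate = 4.0
    lut_t = np.arange(fishing_win[0], fishing_win[1], 1.0 / lut_rate)
    on_spider = np.sign(np.interp(lut_t, pelvis_t, pelvis_x)) == spider_x_sign
    n_max = int(t_end / 0.4) + 2
    noise = rng.normal(0, cfg.rr_noise, n_max)
    beats_t, beats_rr = [], []
    cur, i = 0.3, 0
    while cur < t_end and i < n_max:
        mod = 1.0
        if fishing_win[0] <= cur < fishing_win[1]:
            if on_spider[int((cur - fishing_win[0]) * lut_rate)]:
                mod -= cfg.rr_side_drop * av
        for touch_t, a_eff in touch_info:
            if touch_t - 3.0 <= cur < touch_t:
                mod -= cfg.rr_touch_drop * a_eff * (1 - (touch_t - cur) / 3.0)
        rr = min(max(base * mod + noise[i], 0.4), 2.0)
        cur += rr
        beats_t.append(cur)
        beats_rr.append(rr)
        i += 1
    return RRSeries(t=np.array(beats_t), rr=np.array(beats_rr))


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


def simulate_session(rng, participant_id: str, group: str, aversion: float,
                     fsq: float, cfg: CohortConfig, index: int = 0) -> Session:
    """Generate one complete session for a participant."""
    cb = index if cfg.counterbalance else 0
    layout = default_layout(
        fishing_spider_side="left" if cb % 2 == 0 else "right",
        path_spider_side_first="left" if (cb // 2) % 2 == 0 else "right",
        touch_first_stimulus="spider" if cb % 2 == 0 else "turtle",
    )
    ft, fpelvis, fyaw, fevents = simulate_fishing(rng, aversion, layout, cfg, 0.0)
    pt, ppelvis, pevents, chosen, cursor = simulate_path_choice(
        rng, aversion, layout, cfg, ft[-1] + 2.0
    )
    # bridge standing gaps so the pelvis track is continuous
    gap1 = _grid(ft[-1] + 1e-3, pt[0] - 1e-3, 10.0)
    bridge1 = _standing(rng, ppelvis[0], gap1)
    tt, tpelvis, thand, tevents, touch_info, t_end = simulate_touch(
        rng, aversion, layout, cfg, cursor + 2.0
    )
    gap2 = _grid(pt[-1] + 1e-3, tt[0] - 1e-3, 10.0)
    bridge2 = _standing(rng, tpelvis[0], gap2)

    t_all = np.concatenate([ft, gap1, pt, gap2, tt])
    pel_all = np.vstack([fpelvis, bridge1, ppelvis, bridge2, tpelvis])
    yaw_all = np.concatenate(
        [fyaw, np.zeros(gap1.size + pt.size + gap2.size + tt.size)]
    )
    head = pel_all + np.array([0.0, 0.62, 0.0])
    head[:, [0, 2]] += rng.normal(0, 0.01, (t_all.size, 2))
    hand_rest = pel_all + np.array([0.25, 0.15, 0.25])
    hand_all = np.vstack(
        [hand_rest[: ft.size + gap1.size + pt.size + gap2.size], thand]
    )
    hand_all[: ft.size, :] += rng.normal(0, 0.02, (ft.size, 3))

    tracks = {
        "pelvis": MotionTrack("pelvis", t_all, pel_all, yaw=yaw_all),
        "head": MotionTrack("head", t_all, head),
        "right_hand": MotionTrack("right_hand", t_all, hand_all),
    }
    fishing_win = (10.0, 130.0)
    gaze = _simulate_gaze(rng, cfg, t_end + 1.0, fishing_win, aversion, touch_info)
    rr = _simulate_rr(
        rng, cfg, t_end + 1.0, fishing_win, ft, fpelvis[:, 0],
        np.sign(layout.stimulus_positions["fishing"][1]["spider"][0]),
        aversion, touch_info,
    )
    av = aversion
    valence = {
        "spider": float(np.clip(round(7.5 - 2.5 * av + rng.normal(0, 0.8)), 0, 10)),
        "turtle": float(np.clip(round(7.0 + rng.normal(0, 1.0)), 0, 10)),
    }
    events = fevents + pevents + tevents
    return Session(
        participant_id=participant_id,
        group=group,
        questionnaire_scales={"FSQ": float(fsq)},
        valence_ratings=valence,
        tracks=tracks,
        gaze=gaze,
        rr=rr,
        events=events,
        layout=layout,
    )


def generate_cohort(config: CohortConfig | None = None):
    """Generate the full synthetic cohort.

    Returns ``(sessions, ground_truth)`` where ``ground_truth`` records each
    participant's latent aversion, FSQ and the intended direction of every
    readout effect, for parameter-recovery tests.
    """
    cfg = config or CohortConfig()
    root = np.random.default_rng(cfg.seed)
    sessions, truth = [], {"config": cfg.model_dump(), "participants": {}}
    idx = 0
    for group, n, mean in (
        ("phobic", cfg.n_phobic, cfg.aversion_mean_phobic),
        ("fearful", cfg.n_fearful, cfg.aversion_mean_fearful),
        ("non_fearful", cfg.n_non_fearful, cfg.aversion_mean_non_fearful),
    ):
        if n == 0:
            continue
        aversions = root.normal(mean, cfg.aversion_sd, size=n)
        fsqs = _fsq_scores(root, group, aversions)
        for a, fsq in zip(aversions, fsqs):
            idx += 1
            pid = f"P{idx:02d}"
            rng = np.random.default_rng(root.integers(0, 2**31 - 1))
            sessions.append(
                simulate_session(rng, pid, group, float(a), float(fsq), cfg, index=idx - 1)
            )
            truth["participants"][pid] = {
                "group": group,
                "aversion": float(a),
                "fsq": float(fsq),
                "expected_sign_fishing": float(np.sign(max(a, 0.0))),
                "expected_sign_path_choice": float(np.sign(max(a, 0.0))),
                "expected_sign_touch": float(np.sign(max(a, 0.0))),
            }
    return sessions, truth


def write_cohort(sessions, ground_truth, out_dir: str | Path) -> Path:
    """Write one container per session plus ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in sessions:
        write_session(s, out / s.participant_id)
    (out / "ground_truth.json").write_text(
        json.dumps(ground_truth, indent=1), encoding="utf-8"
    )
    return out
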