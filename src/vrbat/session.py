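"""Session data model and on-disk container I/O.

A *session* is one participant's run through the three behavioral tasks in
the virtual field: the search task ("fishing"), the forced-choice task
("path choice"), and the approach task ("touch the enemy").  It bundles the
irregularly sampled sensor streams (motion tracks, gaze/pupil, RR
intervals), the task event log, the scene layout, and participant metadata.

Coordinate conventions
----------------------
Positions are in meters.  ``x`` spans the field width (``x ∈ [-w/2, w/2]``),
``z`` spans the field depth (``z ∈ [0, d]``), and ``y`` is up.  The origin
sits at the midpoint of the long side where the participant starts, so side
membership ("left" vs "right" half) is the sign of pelvis ``x``.  Yaw is in
degrees, 0 = facing +z, increasing counter-clockwise viewed from above.
All times are seconds from session start on one shared clock.

The on-disk container is a directory of UTF-8 CSVs plus one JSON metadata
file (``meta.json``, ``motion.csv``, ``gaze.csv``, ``rr.csv``,
``events.csv``) so that fixtures stay inspectable and diff-able.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("phobic", "fearful", "non_fearful")
STIMULI = ("spider", "turtle")
TASKS = ("fishing", "path_choice", "touch_enemy")
SENSORS = ("head", "pelvis", "right_hand")
EVENT_KINDS = (
    "task_start",
    "trial_start",
    "countdown_end",
    "stimulus_touch",
    "trial_end",
    "task_end",
    "side_entry",
)
BOOK_OFFSETS = ("center", "right", "left", "far_right", "far_left")

#: FSQ total at or below which a non-phobic participant counts as non-fearful.
FSQ_CUTOFF = 8

#: Validated RR intervals must fall in this open interval (seconds).
RR_BOUNDS = (0.25, 3.0)


class SessionValidationError(ValueError):
    """A session or stream violates a structural invariant."""


class SessionLoadError(IOError):
    """A session container is missing a file or cannot be parsed."""


def _check_monotonic(t: np.ndarray, what: str) -> None:
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise SessionValidationError(
            f"{what}: timestamps not strictly increasing at index {int(bad[0]) + 1}"
        )


def derive_group(fsq_total: float, cidi_phobia: bool) -> str:
    """Assign a participant to a group from diagnosis and trait fear.

    A clinical diagnosis (CIDI animal-type spider phobia) makes the
    participant ``phobic`` regardless of FSQ; otherwise an FSQ total above
    the cutoff of 8 makes them ``fearful`` and at or below it
    ``non_fearful``.
    """
    if fsq_total < 0:
        raise SessionValidationError(f"FSQ total must be >= 0, got {fsq_total}")
    if cidi_phobia:
        return "phobic"
    return "fearful" if fsq_total > FSQ_CUTOFF else "non_fearful"


# ---------------------------------------------------------------------------
# scene layout
# ---------------------------------------------------------------------------


@dataclass
class SceneLayout:
    """Geometry of the virtual field and per-task stimulus placement.

    ``stimulus_positions`` maps task -> trial index (1-based) -> stimulus
    name -> 3D position.  ``book_offsets`` records the lateral book
    placement for the five forced-choice trials; ``animal_swap_schedule``
    maps each forced-choice trial to the spider's side.
    """

    field_width: float = 4.6
    field_depth: float = 4.3
    stimulus_positions: dict = field(default_factory=dict)
    start_position: tuple = (0.0, 0.0, 0.3)
    table_position: tuple = (0.0, 1.1, 3.8)
    table_height: float = 1.1
    book_offsets: tuple = BOOK_OFFSETS
    animal_swap_schedule: dict = field(default_factory=dict)
    #: z of the line the participant must cross beside the central table in
    #: the forced-choice task; side of passage is the sign of x there.
    gate_z: float = 2.0
    #: start position used in the approach task
    touch_start: tuple = (0.0, 0.0, 0.3)

    def validate(self) -> None:
        if self.field_width <= 0 or self.field_depth <= 0:
            raise SessionValidationError("field dimensions must be strictly positive")
        for label, p in (("start", self.start_position), ("table", self.table_position)):
            self._check_in_field(p, label)
        for task, trials in self.stimulus_positions.items():
            for trial, stims in trials.items():
                for stim, p in stims.items():
                    self._check_in_field(p, f"{task} trial {trial} {stim}")
        if tuple(self.book_offsets) != BOOK_OFFSETS:
            raise SessionValidationError(
                f"book offsets for trials 1..5 must be {BOOK_OFFSETS}"
            )
        sched = self.animal_swap_schedule
        if sched:
            if sorted(sched) != [1, 2, 3, 4, 5]:
                raise SessionValidationError("swap schedule must cover trials 1..5")
            a = sched[1]
            expect = {1: a, 2: _other_side(a), 3: _other_side(a), 4: a, 5: a}
            if dict(sched) != expect:
                raise SessionValidationError(
                    "animal sides must swap after trial 1 and after trial 3"
                )

    def _check_in_field(self, p, label: str) -> None:
        x, _, z = p
        hw = self.field_width / 2
        eps = 1e-9
        if not (-hw - eps <= x <= hw + eps and -eps <= z <= self.field_depth + eps):
            raise SessionValidationError(f"{label} position {p} outside field footprint")

    def spider_side(self, task: str, trial: int) -> str:
        """Side ('left'/'right') holding the spider for a given task trial."""
        x = self.stimulus_positions[task][trial]["spider"][0]
        return "left" if x < 0 else "right"


def _other_side(side: str) -> str:
    return "right" if side == "left" else "left"


def default_layout(
    fishing_spider_side: str = "left",
    path_spider_side_first: str = "left",
    touch_first_stimulus: str = "spider",
) -> SceneLayout:
    """Build the standard field layout with counterbalancing switches.

    The fishing stimuli sit centered on the left/right border planks; the
    forced-choice animals sit on the outer counter tables either side of the
    gate; the approach-task animal sits on the small round table (height
    1.1 m) in front of the far wall.  Animal sides in the forced-choice task
    swap after the first and after the third trial.
    """
    lay = SceneLayout()
    hw = lay.field_width / 2
    mid_z = lay.field_depth / 2

    def lr(side):
        return -1.0 if side == "left" else 1.0

    fs = lr(fishing_spider_side)
    stim = {
        "fishing": {
            1: {
                "spider": (fs * hw, 0.85, mid_z),
                "turtle": (-fs * hw, 0.85, mid_z),
            }
        }
    }
    # forced choice: spider side per trial from the swap schedule
    a = path_spider_side_first
    sched = {1: a, 2: _other_side(a), 3: _other_side(a), 4: a, 5: a}
    stim["path_choice"] = {
        tr: {
            "spider": (lr(s) * 1.4, 0.9, lay.gate_z),
            "turtle": (-lr(s) * 1.4, 0.9, lay.gate_z),
        }
        for tr, s in sched.items()
    }
    # approach task: alternating stimuli on the table, 4 trials
    first = touch_first_stimulus
    order = [first, _other_side_stim(first)] * 2
    tx, ty, tz = lay.table_position
    stim["touch_enemy"] = {
        i + 1: {order[i]: (tx, ty, tz)} for i in range(4)
    }
    lay.stimulus_positions = stim
    lay.animal_swap_schedule = sched
    lay.validate()
    return lay


def _other_side_stim(stim: str) -> str:
    return "turtle" if stim == "spider" else "spider"


# ---------------------------------------------------------------------------
# sensor streams
# ---------------------------------------------------------------------------


@dataclass
class MotionTrack:
    """Irregularly sampled 3D position (and optional yaw) of one sensor."""

    sensor_id: str
    t: np.ndarray
    position: np.ndarray  # (n, 3)
    yaw: np.ndarray | None = None  # degrees, may be None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if self.yaw is not None:
            self.yaw = np.asarray(self.yaw, dtype=float)

    def validate(self) -> None:
        if self.sensor_id not in SENSORS:
            raise SessionValidationError(f"unknown sensor {self.sensor_id!r}")
        if self.t.size < 2:
            raise SessionValidationError(f"{self.sensor_id}: at least 2 samples required")
        _check_monotonic(self.t, f"motion track {self.sensor_id}")
        if self.position.shape != (self.t.size, 3):
            raise SessionValidationError(f"{self.sensor_id}: position must be (n, 3)")
        if not np.all(np.isfinite(self.position)):
            raise SessionValidationError(f"{self.sensor_id}: non-finite position")
        if self.yaw is not None and self.yaw.shape != self.t.shape:
            raise SessionValidationError(f"{self.sensor_id}: yaw length mismatch")


@dataclass
class GazeStream:
    """Gaze focus labels and per-eye pupil diameters (~110 Hz nominal).

    ``focus`` holds the label of the currently fixated object or ``None``.
    Invalid samples (closed eyes, tracking loss) carry NaN pupil values and
    a False validity flag.
    """

    t: np.ndarray
    focus: np.ndarray  # object array of str | None
    pupil_left: np.ndarray
    pupil_right: np.ndarray
    valid_left: np.ndarray
    valid_right: np.ndarray
    nominal_rate: float = 110.0

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.focus = np.asarray(self.focus, dtype=object)
        self.pupil_left = np.asarray(self.pupil_left, dtype=float)
        self.pupil_right = np.asarray(self.pupil_right, dtype=float)
        self.valid_left = np.asarray(self.valid_left, dtype=bool)
        self.valid_right = np.asarray(self.valid_right, dtype=bool)

    def validate(self) -> None:
        if self.t.size == 0:
            raise SessionValidationError("gaze stream is empty")
        _check_monotonic(self.t, "gaze stream")
        n = self.t.size
        for name in ("focus", "pupil_left", "pupil_right", "valid_left", "valid_right"):
            if getattr(self, name).shape[0] != n:
                raise SessionValidationError(f"gaze {name}: length mismatch")
        if self.nominal_rate <= 0:
            raise SessionValidationError("gaze nominal rate must be positive")
        # invalid samples must carry missing pupil values
        for side in ("left", "right"):
            valid = getattr(self, f"valid_{side}")
            pupil = getattr(self, f"pupil_{side}")
            if np.any(np.isfinite(pupil[~valid])):
                raise SessionValidationError(
                    f"gaze: invalid {side} samples must have missing pupil values"
                )

    def pupil(self, eye: str) -> np.ndarray:
        if eye not in ("left", "right"):
            raise ValueError(f"eye must be 'left' or 'right', got {eye!r}")
        return getattr(self, f"pupil_{eye}")


@dataclass
class RRSeries:
    """Beat-event series: time of each heartbeat and the RR interval ending there."""

    t: np.ndarray
    rr: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)

    def validate(self) -> None:
        if self.t.size == 0:
            raise SessionValidationError("rr series is empty")
        _check_monotonic(self.t, "rr series")
        if self.rr.shape != self.t.shape:
            raise SessionValidationError("rr: length mismatch")
        lo, hi = RR_BOUNDS
        if np.any((self.rr <= lo) | (self.rr >= hi)):
            raise SessionValidationError(f"rr values must lie in ({lo}, {hi}) s")


@dataclass
class TaskEvent:
    t: float
    kind: str
    task: str
    trial_index: int = 0
    stimulus: str = "none"

    def validate(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise SessionValidationError(f"unknown event kind {self.kind!r}")
        if self.task not in TASKS:
            raise SessionValidationError(f"unknown task {self.task!r}")
        if self.stimulus not in STIMULI + ("none",):
            raise SessionValidationError(f"unknown stimulus {self.stimulus!r}")


# ---------------------------------------------------------------------------
# session
# ---------------------------------------------------------------------------


@dataclass
class Session:
    """One participant's complete recorded session."""

    participant_id: str
    group: str
    questionnaire_scales: dict
    valence_ratings: dict
    tracks: dict  # sensor_id -> MotionTrack
    gaze: GazeStream
    rr: RRSeries
    events: list  # of TaskEvent
    layout: SceneLayout

    def validate(self) -> None:
        if self.group not in GROUPS:
            raise SessionValidationError(f"unknown group {self.group!r}")
        if "FSQ" not in self.questionnaire_scales:
            raise SessionValidationError("FSQ total is mandatory in questionnaire_scales")
        fsq = self.questionnaire_scales["FSQ"]
        if self.group == "non_fearful" and fsq > FSQ_CUTOFF:
            raise SessionValidationError(f"non_fearful requires FSQ <= {FSQ_CUTOFF}, got {fsq}")
        if self.group == "fearful" and fsq <= FSQ_CUTOFF:
            raise SessionValidationError(f"fearful requires FSQ > {FSQ_CUTOFF}, got {fsq}")
        missing = set(SENSORS) - set(self.tracks)
        if missing:
            raise SessionValidationError(f"missing motion tracks: {sorted(missing)}")
        for tr in self.tracks.values():
            tr.validate()
        self.gaze.validate()
        self.rr.validate()
        self.layout.validate()
        last = -math.inf
        for ev in self.events:
            ev.validate()
            if ev.t < last:
                raise SessionValidationError("events out of time order")
            last = ev.t
        # each approach trial's countdown must end before its touch
        cd = {e.trial_index: e.t for e in self.events
              if e.task == "touch_enemy" and e.kind == "countdown_end"}
        for e in self.events:
            if e.task == "touch_enemy" and e.kind == "stimulus_touch":
                if e.trial_index in cd and e.t < cd[e.trial_index]:
                    raise SessionValidationError(
                        f"touch before countdown end in trial {e.trial_index}"
                    )

    # -- event helpers ------------------------------------------------------

    def find_event(self, kind: str, task: str, trial_index: int | None = None) -> TaskEvent:
        for ev in self.events:
            if ev.kind == kind and ev.task == task and (
                trial_index is None or ev.trial_index == trial_index
            ):
                return ev
        raise SessionValidationError(
            f"no event kind={kind} task={task} trial={trial_index}"
        )

    def task_window(self, task: str) -> tuple[float, float]:
        return (self.find_event("task_start", task).t, self.find_event("task_end", task).t)

    def events_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"t": e.t, "kind": e.kind, "task": e.task,
                 "trial": e.trial_index, "stimulus": e.stimulus}
                for e in self.events
            ]
        )


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------

_FILES = ("meta.json", "motion.csv", "gaze.csv", "rr.csv", "events.csv")


def _layout_to_json(lay: SceneLayout) -> dict:
    return {
        "field_width": lay.field_width,
        "field_depth": lay.field_depth,
        "stimulus_positions": {
            task: {str(tr): {s: list(p) for s, p in stims.items()}
                   for tr, stims in trials.items()}
            for task, trials in lay.stimulus_positions.items()
        },
        "start_position": list(lay.start_position),
        "table_position": list(lay.table_position),
        "table_height": lay.table_height,
        "book_offsets": list(lay.book_offsets),
        "animal_swap_schedule": {str(k): v for k, v in lay.animal_swap_schedule.items()},
        "gate_z": lay.gate_z,
        "touch_start": list(lay.touch_start),
    }


def _layout_from_json(d: Mapping) -> SceneLayout:
    return SceneLayout(
        field_width=d["field_width"],
        field_depth=d["field_depth"],
        stimulus_positions={
            task: {int(tr): {s: tuple(p) for s, p in stims.items()}
                   for tr, stims in trials.items()}
            for task, trials in d["stimulus_positions"].items()
        },
        start_position=tuple(d["start_position"]),
        table_position=tuple(d["table_position"]),
        table_height=d["table_height"],
        book_offsets=tuple(d["book_offsets"]),
        animal_swap_schedule={int(k): v for k, v in d["animal_swap_schedule"].items()},
        gate_z=d["gate_z"],
        touch_start=tuple(d["touch_start"]),
    )


def write_session(session: Session, container_path: str | Path) -> Path:
    """Write a session container (directory of CSVs + meta.json).

    ``load_session(write_session(s))`` reproduces ``s`` up to 1e-9 on
    floats.  Tracks without yaw omit the yaw column.
    """
    session.validate()
    path = Path(container_path)
    path.mkdir(parents=True, exist_ok=True)

    meta = {
        "participant_id": session.participant_id,
        "group": session.group,
        "questionnaire_scales": session.questionnaire_scales,
        "valence_ratings": session.valence_ratings,
        "layout": _layout_to_json(session.layout),
        "gaze_nominal_rate": session.gaze.nominal_rate,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1), encoding="utf-8")

    frames = []
    any_yaw = any(tr.yaw is not None for tr in session.tracks.values())
    for sid in SENSORS:
        tr = session.tracks[sid]
        df = pd.DataFrame(
            {"t": tr.t, "sensor": sid, "x": tr.position[:, 0],
             "y": tr.position[:, 1], "z": tr.position[:, 2]}
        )
        if any_yaw:
            df["yaw"] = tr.yaw if tr.yaw is not None else np.nan
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path / "motion.csv", index=False)

    g = session.gaze
    pd.DataFrame(
        {
            "t": g.t,
            "focus": ["" if f is None else f for f in g.focus],
            "pupil_l": g.pupil_left,
            "pupil_r": g.pupil_right,
            "valid_l": g.valid_left.astype(int),
            "valid_r": g.valid_right.astype(int),
        }
    ).to_csv(path / "gaze.csv", index=False)

    pd.DataFrame({"t": session.rr.t, "rr": session.rr.rr}).to_csv(
        path / "rr.csv", index=False
    )
    df = session.events_df()
    df["stimulus"] = df["stimulus"].replace("none", "")
    df.to_csv(path / "events.csv", index=False)
    return path


def load_session(container_path: str | Path) -> Session:
    """Load and validate a session container written by :func:`write_session`."""
    path = Path(container_path)
    if not path.is_dir():
        raise SessionLoadError(f"session container not found: {path}")
    for name in _FILES:
        if not (path / name).exists():
            stream = name.split(".")[0]
            raise SessionLoadError(f"{stream} stream absent: missing {path / name}")

    meta = json.loads((path / "meta.json").read_text(encoding="utf-8"))
    motion = pd.read_csv(path / "motion.csv")
    tracks = {}
    for sid, df in motion.groupby("sensor", sort=False):
        yaw = None
        if "yaw" in df.columns and not df["yaw"].isna().all():
            yaw = df["yaw"].to_numpy(dtype=float)
        tracks[sid] = MotionTrack(
            sensor_id=sid,
            t=df["t"].to_numpy(dtype=float),
            position=df[["x", "y", "z"]].to_numpy(dtype=float),
            yaw=yaw,
        )

    gz = pd.read_csv(path / "gaze.csv")
    focus = np.array(
        [None if (isinstance(f, float) and math.isnan(f)) or f == "" else str(f)
         for f in gz["focus"]],
        dtype=object,
    )
    gaze = GazeStream(
        t=gz["t"].to_numpy(dtype=float),
        focus=focus,
        pupil_left=gz["pupil_l"].to_numpy(dtype=float),
        pupil_right=gz["pupil_r"].to_numpy(dtype=float),
        valid_left=gz["valid_l"].to_numpy(dtype=bool),
        valid_right=gz["valid_r"].to_numpy(dtype=bool),
        nominal_rate=meta.get("gaze_nominal_rate", 110.0),
    )

    rrdf = pd.read_csv(path / "rr.csv")
    rr = RRSeries(t=rrdf["t"].to_numpy(dtype=float), rr=rrdf["rr"].to_numpy(dtype=float))

    ev = pd.read_csv(path / "events.csv", keep_default_na=False)
    events = [
        TaskEvent(
            t=float(r.t),
            kind=str(r.kind),
            task=str(r.task),
            trial_index=int(r.trial),
            stimulus=str(r.stimulus) if r.stimulus != "" else "none",
        )
        for r in ev.itertuples()
    ]

    session = Session(
        participant_id=meta["participant_id"],
        group=meta["group"],
        questionnaire_scales=meta["questionnaire_scales"],
        valence_ratings=meta["valence_ratings"],
        tracks=tracks,
        gaze=gaze,
        rr=rr,
        events=events,
        layout=_layout_from_json(meta["layout"]),
    )
    session.validate()
    return session


# ---------------------------------------------------------------------------
# readout rows
# ---------------------------------------------------------------------------


@dataclass
class ReadoutRow:
    """Per-participant derived readouts across the three tasks.

    Scalar readouts plus flattened per-trial physiology summaries, with
    named exclusion flags.  ``validate`` enforces the documented value
    ranges (score within ±14, truncations, pupil in the unit interval).
    """

    participant_id: str
    group: str
    fsq: float
    valence_spider: float
    valence_turtle: float
    fishing_min_dist_spider: float
    fishing_min_dist_turtle: float
    fishing_readout: float
    fishing_glances_spider: float
    fishing_glances_turtle: float
    fishing_glance_diff: float
    fishing_angle_spider: float
    fishing_angle_turtle: float
    fishing_rr_spider_side: float
    fishing_rr_turtle_side: float
    fishing_pupil_spider_side: float
    fishing_pupil_turtle_side: float
    path_choice_score: float
    touch_time_spider1: float
    touch_time_turtle1: float
    touch_readout: float
    thirds_durations: dict = field(default_factory=dict)  # (stim, occ, area)->s
    accel_changes: dict = field(default_factory=dict)  # (stim, occ)->count
    pre_touch_pupil: dict = field(default_factory=dict)  # (stim, occ)->[0,1]
    pre_touch_rr: dict = field(default_factory=dict)  # (stim, occ)->s
    excluded_never_entered_spider_side: bool = False
    excluded_eyes_closed_pre_touch: bool = False
    excluded_missing_rr: bool = False

    def validate(self) -> None:
        if not -14 <= self.path_choice_score <= 14:
            raise SessionValidationError("path_choice_score out of [-14, 14]")
        if np.isfinite(self.touch_readout) and self.touch_readout > 20:
            raise SessionValidationError("touch_readout exceeds 20 s cap")
        for key, v in self.accel_changes.items():
            if np.isfinite(v) and v > 100:
                raise SessionValidationError(f"accel_changes{key} exceeds cap 100")
        for key, v in self.pre_touch_pupil.items():
            if np.isfinite(v) and not 0 <= v <= 1:
                raise SessionValidationError(f"pre_touch_pupil{key} outside [0, 1]")
        for name in ("fishing_angle_spider", "fishing_angle_turtle"):
            v = getattr(self, name)
            if np.isfinite(v) and not 0 <= v <= 180:
                raise SessionValidationError(f"{name} outside [0, 180]")

    def to_flat_dict(self) -> dict:
        d = {}
        for name in (
            "participant_id group fsq valence_spider valence_turtle "
            "fishing_min_dist_spider fishing_min_dist_turtle fishing_readout "
            "fishing_glances_spider fishing_glances_turtle fishing_glance_diff "
            "fishing_angle_spider fishing_angle_turtle "
            "fishing_rr_spider_side fishing_rr_turtle_side "
            "fishing_pupil_spider_side fishing_pupil_turtle_side "
            "path_choice_score touch_time_spider1 touch_time_turtle1 touch_readout"
        ).split():
            d[name] = getattr(self, name)
        for (stim, occ, area), v in sorted(self.thirds_durations.items()):
            d[f"thirds_{stim}{occ}_area{area}"] = v
        for (stim, occ), v in sorted(self.accel_changes.items()):
            d[f"accel_{stim}{occ}"] = v
        for (stim, occ), v in sorted(self.pre_touch_pupil.items()):
            d[f"pre_touch_pupil_{stim}{occ}"] = v
        for (stim, occ), v in sorted(self.pre_touch_rr.items()):
            d[f"pre_touch_rr_{stim}{occ}"] = v
        for flag in (
            "excluded_never_entered_spider_side",
            "excluded_eyes_closed_pre_touch",
            "excluded_missing_rr",
        ):
            d[flag] = int(getattr(self, flag))
        return d
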