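"""Psychophysiological signal preprocessing.

Implements the pupil-size preprocessing chain (moving-median outlier
rejection with scaled MAD, linear interpolation of missing runs,
nearest-neighbour resampling to a regular 110 Hz grid, unit-interval
rescaling), glance segmentation on gaze focus labels with 200 ms gap
merging, cubic-spline resampling of hand kinematics with
acceleration-sign-change counting, and windowed RR-interval averaging on a
250 Hz step-function rendering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .session import GazeStream, MotionTrack, RRSeries

#: Consistency constant relating the median absolute deviation to the
#: standard deviation of a normal distribution.
MAD_SCALE = 1.4826

#: RR series are rendered as a step function at this rate before windowed
#: averaging.
RR_RENDER_RATE = 250.0


class PreprocessError(ValueError):
    """Input too short or otherwise unusable for a preprocessing step."""


# ---------------------------------------------------------------------------
# regular series container
# ---------------------------------------------------------------------------


@dataclass
class RegularSeries:
    """Values on a regular time grid ``t0 + i / rate``."""

    t0: float
    rate: float
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise PreprocessError("rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.rate

    def mean_in_windows(self, windows) -> float:
        """Mean of grid samples falling in the union of [start, end) windows."""
        mask = _union_mask(self.times, windows)
        if not mask.any():
            return float("nan")
        return float(np.mean(self.values[mask]))


def _union_mask(t: np.ndarray, windows) -> np.ndarray:
    mask = np.zeros(t.size, dtype=bool)
    for start, end in windows:
        mask |= (t >= start) & (t < end)
    return mask


# ---------------------------------------------------------------------------
# pupil chain
# ---------------------------------------------------------------------------


def flag_pupil_outliers(
    values: np.ndarray, window: int = 100, k: float = 3.0
) -> np.ndarray:
    """Mark moving-median outliers as missing (NaN).

    A value is flagged iff its absolute deviation from the moving median
    (centered window of ``window`` samples, shrunk at the edges) is strictly
    greater than ``k`` scaled MADs of that same window.  Already-missing
    samples (NaN) are ignored by the window statistics and stay missing.
    Deviation 0 is never greater than 0, so all-equal windows flag nothing.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise PreprocessError("empty series")
    if v.size < window // 2:
        raise PreprocessError(
            f"series of {v.size} samples shorter than half the window ({window})"
        )
    half = window // 2
    # pad so each centered window can be taken as a fixed-width slice; NaN
    # padding is ignored by the nanmedian, which shrinks edge windows.
    pad = np.concatenate([np.full(half, np.nan), v, np.full(window - half - 1, np.nan)])
    win = np.lib.stride_tricks.sliding_window_view(pad, window)
    has_nan = np.isnan(win).any(axis=1)
    clean = ~has_nan

    def _rowmedian(a, nan_rows):
        out = np.empty(a.shape[0])
        with np.errstate(all="ignore"):
            if nan_rows.any():
                out[nan_rows] = np.nanmedian(a[nan_rows], axis=1)
            if clean.any():
                out[clean] = np.median(a[clean], axis=1)
        return out

    med = _rowmedian(win, has_nan)
    mad = _rowmedian(np.abs(win - med[:, None]), has_nan)
    dev = np.abs(v - med)
    out = dev > k * MAD_SCALE * mad
    res = v.copy()
    res[out] = np.nan
    return res


def interpolate_and_resample(
    t: np.ndarray, values: np.ndarray, rate: float = 110.0
) -> RegularSeries:
    """Fill missing values linearly in time, then resample to a regular grid.

    Internal missing runs are linearly interpolated between their valid
    neighbours; leading/trailing missing samples take the nearest valid
    value.  The completed irregular series is then mapped onto the grid
    ``t[0] + i/rate`` by nearest-neighbour lookup.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(values, dtype=float)
    valid = np.isfinite(v)
    if valid.sum() < 2:
        raise PreprocessError("need at least two non-missing samples")
    filled = np.interp(t, t[valid], v[valid])  # clamps at the ends
    t0 = t[0]
    n = int(np.floor((t[-1] - t0) * rate + 1e-9)) + 1
    grid = t0 + np.arange(n) / rate
    idx = np.searchsorted(t, grid)
    idx = np.clip(idx, 1, t.size - 1)
    left_closer = (grid - t[idx - 1]) <= (t[idx] - grid)
    nearest = np.where(left_closer, idx - 1, idx)
    return RegularSeries(t0=t0, rate=rate, values=filled[nearest])


def rescale_unit(series: RegularSeries) -> RegularSeries:
    """Min-max rescale to [0, 1]; a constant series maps to all zeros."""
    v = series.values
    if v.size == 0:
        raise PreprocessError("empty series")
    lo, hi = np.min(v), np.max(v)
    scaled = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
    return RegularSeries(t0=series.t0, rate=series.rate, values=scaled)


def preprocess_pupil(
    gaze: GazeStream,
    eye: str,
    window: tuple[float, float] | None = None,
    outlier_window: int = 100,
    outlier_k: float = 3.0,
    rate: float = 110.0,
) -> RegularSeries:
    """Full pupil chain: outlier rejection -> interpolation -> 110 Hz -> [0, 1].

    ``window`` restricts the chain to one task segment, so that the
    unit-interval rescaling is per segment.
    """
    t = gaze.t
    v = gaze.pupil(eye).copy()
    v[~getattr(gaze, f"valid_{eye}")] = np.nan
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        t, v = t[sel], v[sel]
    if t.size == 0:
        raise PreprocessError("no gaze samples in window")
    flagged = flag_pupil_outliers(v, window=outlier_window, k=outlier_k)
    return rescale_unit(interpolate_and_resample(t, flagged, rate=rate))


# ---------------------------------------------------------------------------
# glance segmentation
# ---------------------------------------------------------------------------


@dataclass
class GlanceSet:
    """Merged intervals of gaze focus on one object."""

    target: str
    intervals: list  # of (start, end)
    count: int
    total_duration: float


def merge_intervals(intervals, max_gap: float = 0.2):
    """Merge consecutive intervals separated by gaps strictly below ``max_gap``."""
    merged = []
    for start, end in intervals:
        if merged and (start - merged[-1][1]) < max_gap:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return merged


def segment_glances(
    gaze: GazeStream,
    target: str,
    max_gap: float = 0.2,
    window: tuple[float, float] | None = None,
) -> GlanceSet:
    """Segment maximal focus runs on ``target`` into glances.

    The focus label is treated as a step function holding from each sample
    until the next (the final sample holds for one nominal sample period).
    Runs of target focus become intervals; interruptions strictly shorter
    than ``max_gap`` (200 ms by default) are considered continuous viewing
    and merged.  An unknown target yields an empty glance set.
    """
    t = gaze.t
    hit = np.array([f == target for f in gaze.focus], dtype=bool)
    if window is not None:
        sel = (t >= window[0]) & (t < window[1])
        t, hit = t[sel], hit[sel]
    if t.size == 0 or not hit.any():
        return GlanceSet(target=target, intervals=[], count=0, total_duration=0.0)
    ends = np.empty_like(t)
    ends[:-1] = t[1:]
    ends[-1] = t[-1] + 1.0 / gaze.nominal_rate
    # maximal runs of True
    padded = np.concatenate([[False], hit, [False]])
    d = np.diff(padded.astype(int))
    starts_i = np.nonzero(d == 1)[0]
    stops_i = np.nonzero(d == -1)[0] - 1
    raw = [(t[i], ends[j]) for i, j in zip(starts_i, stops_i)]
    merged = merge_intervals(raw, max_gap=max_gap)
    total = float(sum(e - s for s, e in merged))
    return GlanceSet(target=target, intervals=merged, count=len(merged), total_duration=total)


# ---------------------------------------------------------------------------
# hand kinematics
# ---------------------------------------------------------------------------


def resample_track(
    track: MotionTrack,
    rate: float = 10.0,
    window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Cubic-spline resample a 3D track onto a regular grid.

    Each coordinate is independently interpolated with a cubic spline
    through all samples and evaluated on the grid spanning the (optionally
    windowed) track. Returns an (n, 3) array.
    """
    t, pos = track.t, track.position
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        t, pos = t[sel], pos[sel]
    if t.size < 4:
        raise PreprocessError(f"need >= 4 samples for cubic spline, got {t.size}")
    n = int(np.floor((t[-1] - t[0]) * rate + 1e-9)) + 1
    grid = t[0] + np.arange(n) / rate
    out = np.empty((n, 3))
    for ax in range(3):
        out[:, ax] = CubicSpline(t, pos[:, ax])(grid)
    return out


def count_acceleration_sign_changes(positions: np.ndarray) -> int:
    """Count strict sign changes of the second finite difference.

    The second central difference is taken per coordinate axis on the
    regular grid; zeros are ignored and the remaining strict sign flips are
    summed over the three axes.  Magnitudes below 1e-9 of the position scale
    count as zero so exactly straight segments are not polluted by rounding
    noise.  The count is invariant to rigid translation and to time reversal
    of the trajectory.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim == 1:
        pos = pos[:, None]
    if pos.shape[0] < 4:
        raise PreprocessError("need >= 4 grid samples")
    acc = pos[2:] - 2 * pos[1:-1] + pos[:-2]
    eps = 1e-9 * max(1.0, float(np.abs(pos).max()))
    total = 0
    for ax in range(pos.shape[1]):
        a = acc[:, ax]
        s = np.sign(a[np.abs(a) > eps])
        if s.size > 1:
            total += int(np.count_nonzero(np.diff(s)))
    return total


def truncate_value(value, cap):
    """Cap a value (or array) from above: ``min(value, cap)``."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    return np.minimum(value, cap)


# ---------------------------------------------------------------------------
# RR windows
# ---------------------------------------------------------------------------


def mean_rr_in_windows(
    rr: RRSeries, windows, render_rate: float = RR_RENDER_RATE
) -> float:
    """Mean RR interval over a union of time windows.

    The beat series is rendered as a step function sampled at
    ``render_rate`` (each RR value holds from its beat until the next) and
    the arithmetic mean of the samples falling in any ``[start, end)``
    window is returned; NaN if no rendered sample falls inside.
    """
    if windows is None or len(windows) == 0:
        raise PreprocessError("empty window set")
    for start, end in windows:
        if not end > start:
            raise PreprocessError(f"degenerate window ({start}, {end})")
    t0, t1 = rr.t[0], rr.t[-1]
    n = int(np.floor((t1 - t0) * render_rate)) + 1
    grid = t0 + np.arange(n) / render_rate
    idx = np.searchsorted(rr.t, grid, side="right") - 1
    stepped = rr.rr[np.clip(idx, 0, rr.t.size - 1)]
    mask = _union_mask(grid, windows)
    if not mask.any():
        return float("nan")
    return float(np.mean(stepped[mask]))
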