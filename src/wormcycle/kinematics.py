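"""Posture and trajectory kinematics of undulatory locomotion.

Everything downstream of the raw midline lives here: the signed bend angle
at a body point, segmentation of the bend trace into undulation cycles, and
the per-cycle summary metrics (angular excursion, half-cycle slopes, lateral
displacement, centroid speed, path curvature).

Sign convention, used throughout the package: **positive bend = dorsal**.
For synthetic data the lab frame is oriented with dorsal toward +y; for real
tracks the caller is responsible for orienting coordinates accordingly.

Cycle convention: cycles are half-open frame intervals ``[b_i, b_{i+1})``
whose boundaries are interior dorsal-bend maxima, so cycle fraction
``phi = 0`` sits at the dorsal-bend maximum.  Under the swim (co-activation)
emission model this places straight postures at fractions 0.25 and 0.75.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

__all__ = [
    "MidlineTrack",
    "BendTrace",
    "CycleSet",
    "bend_angle",
    "detect_cycles",
    "angular_excursion",
    "half_cycle_slopes",
    "lateral_displacement",
    "centroid_speed",
    "path_curvature",
]


@dataclass
class MidlineTrack:
    """Time-resolved body midline: ``coords[frame, point, (x, y)]`` in µm."""

    coords: np.ndarray
    fps: float
    note: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError("coords must have shape (frames, points, 2)")
        if self.coords.shape[1] < 3:
            raise ValueError("midline needs at least 3 points per frame")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("midline coordinates must be finite")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_points(self) -> int:
        return self.coords.shape[1]

    def centroid(self) -> np.ndarray:
        """Per-frame centroid of the midline points, shape (frames, 2)."""
        return self.coords.mean(axis=1)

    def arc_length(self) -> np.ndarray:
        """Per-frame midline arc length (µm)."""
        seg = np.diff(self.coords, axis=1)
        return np.linalg.norm(seg, axis=2).sum(axis=1)


@dataclass
class BendTrace:
    """Signed bend angle (degrees, positive = dorsal) at a named body point."""

    values: np.ndarray
    fps: float
    label: str = "tail"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("bend trace must be one-dimensional")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if np.any(np.abs(self.values) >= 180.0):
            raise ValueError("bend angle magnitude must be < 180 degrees")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.fps


@dataclass
class CycleSet:
    """Detected undulation cycles.

    Cycle *i* is the half-open frame interval ``[starts[i], ends[i])`` whose
    endpoints are interior dorsal-bend maxima of the trace it was detected
    on; ``ventral_minima[i]`` is the frame of its ventral-bend minimum.
    Consecutive cycles usually share a boundary (``ends[i] == starts[i+1]``)
    but need not, since cycles without an interior ventral minimum are
    discarded at detection time.
    """

    starts: np.ndarray
    ends: np.ndarray
    ventral_minima: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=int)
        self.ends = np.asarray(self.ends, dtype=int)
        self.ventral_minima = np.asarray(self.ventral_minima, dtype=int)
        if not (len(self.starts) == len(self.ends) == len(self.ventral_minima)):
            raise ValueError("starts, ends and ventral_minima must align")
        if np.any(self.ends <= self.starts):
            raise ValueError("cycles must be non-empty")
        if np.any(self.starts[1:] < self.ends[:-1]):
            raise ValueError("cycles must be ordered and non-overlapping")
        if np.any((self.ventral_minima <= self.starts) | (self.ventral_minima >= self.ends)):
            raise ValueError("ventral minimum must be interior to its cycle")

    @property
    def n_cycles(self) -> int:
        return len(self.starts)

    def __len__(self) -> int:
        return self.n_cycles

    @property
    def intervals(self) -> list[tuple[int, int]]:
        return [(int(b), int(e)) for b, e in zip(self.starts, self.ends)]

    @property
    def boundaries(self) -> np.ndarray:
        """Sorted union of all cycle endpoints (dorsal-maximum frames)."""
        return np.unique(np.concatenate([self.starts, self.ends]))

    @property
    def durations(self) -> np.ndarray:
        """Cycle durations in seconds."""
        return (self.ends - self.starts) / self.fps

    @property
    def lengths(self) -> np.ndarray:
        """Cycle lengths in frames."""
        return self.ends - self.starts


class ExcursionResult(NamedTuple):
    per_cycle: np.ndarray
    mean: float


class SlopesResult(NamedTuple):
    slope_d: np.ndarray  # ventro-dorsal half, deg/s, magnitudes
    slope_v: np.ndarray  # dorso-ventral half
    mean_d: float
    mean_v: float


class DisplacementResult(NamedTuple):
    d_v: np.ndarray  # head displacement over the dorso-ventral sweep (µm)
    d_d: np.ndarray  # over the ventro-dorsal sweep
    mean_v: float
    mean_d: float
    ratio: float  # mean_v / mean_d


def _signed_angle(u: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Signed angle (deg) from vectors u to w; positive = counter-clockwise."""
    cross = u[..., 0] * w[..., 1] - u[..., 1] * w[..., 0]
    dot = (u * w).sum(axis=-1)
    return np.degrees(np.arctan2(cross, dot))


def bend_angle(
    track: MidlineTrack,
    tip_index: int = -1,
    anterior_index: int = 0,
    vertex_index: int | None = None,
) -> BendTrace:
    """Bend angle at a body vertex from three midline points.

    The returned angle is ``180° − interior angle`` at the vertex, i.e. the
    turn of the vertex→tip chord relative to the anterior→vertex chord,
    signed positive when the tip lies dorsal (+y) of the anterior→vertex
    axis.  Collinear points give 0.
    """
    n = track.n_points
    if vertex_index is None:
        vertex_index = n // 2
    tip_index, anterior_index, vertex_index = (
        int(np.arange(n)[i]) for i in (tip_index, anterior_index, vertex_index)
    )
    if len({tip_index, anterior_index, vertex_index}) != 3:
        raise ValueError("tip, anterior and vertex indices must be distinct")
    a = track.coords[:, anterior_index]
    v = track.coords[:, vertex_index]
    t = track.coords[:, tip_index]
    u, w = v - a, t - v
    if np.any(np.linalg.norm(u, axis=1) == 0) or np.any(np.linalg.norm(w, axis=1) == 0):
        raise ValueError("degenerate geometry: coincident measurement points")
    return BendTrace(_signed_angle(u, w), track.fps, label=f"vertex{vertex_index}")


def detect_cycles(
    trace: BendTrace,
    min_period: float = 0.3,
    min_prominence: float = 0.2,
    smooth_window: int = 3,
) -> CycleSet:
    """Segment a bend trace into undulation cycles.

    The trace is smoothed with a ``smooth_window``-frame moving average,
    then interior local maxima with prominence at least
    ``min_prominence × range`` and spacing at least ``min_period`` seconds
    become cycle boundaries.  Cycles whose within-cycle minimum is not
    interior (no true ventral sweep) are discarded.
    """
    if min_period <= 0:
        raise ValueError("min_period must be positive")
    if len(trace) < 3:
        raise ValueError("trace too short for cycle detection")
    x = trace.values
    if smooth_window > 1:
        x = uniform_filter1d(x, size=int(smooth_window), mode="nearest")
    empty = CycleSet(np.empty(0, int), np.empty(0, int), np.empty(0, int), trace.fps)
    span = float(np.ptp(x))
    if span == 0.0:
        return empty
    distance = max(1, int(round(min_period * trace.fps)))
    peaks, _ = find_peaks(x, distance=distance, prominence=min_prominence * span)
    starts, ends, minima = [], [], []
    for b, e in zip(peaks[:-1], peaks[1:]):
        vmin = b + 1 + int(np.argmin(x[b + 1 : e]))
        # require a genuine interior minimum (a ventral sweep)
        if vmin == b + 1 and x[vmin] >= x[b]:
            continue
        if vmin == e - 1 and x[vmin] >= x[e]:
            continue
        starts.append(int(b))
        ends.append(int(e))
        minima.append(int(vmin))
    if not starts:
        return empty
    return CycleSet(np.array(starts), np.array(ends), np.array(minima), trace.fps)


def angular_excursion(trace: BendTrace, cycles: CycleSet) -> ExcursionResult:
    """Per-cycle peak-to-trough bend range E (degrees) and its mean."""
    if cycles.n_cycles == 0:
        raise ValueError("no cycles")
    per = np.array(
        [float(np.ptp(trace.values[b:e])) for b, e in cycles.intervals]
    )
    return ExcursionResult(per, float(per.mean()))


def _ls_slope(t: np.ndarray, y: np.ndarray) -> float:
    return float(np.polyfit(t, y, 1)[0])


def half_cycle_slopes(trace: BendTrace, cycles: CycleSet) -> SlopesResult:
    """Least-squares bend-angle slopes (deg/s, magnitudes) per half-cycle.

    ``slope_v`` covers the dorso-ventral sweep (opening dorsal maximum →
    ventral minimum), ``slope_d`` the ventro-dorsal sweep (ventral minimum →
    closing dorsal maximum).  Both endpoints are included in each fit.
    """
    if cycles.n_cycles == 0:
        raise ValueError("no cycles")
    t = trace.times
    y = trace.values
    s_d, s_v = [], []
    for (b, e), v in zip(cycles.intervals, cycles.ventral_minima):
        if v - b < 1 or e - v < 1:
            warnings.warn("half-cycle with <2 samples; cycle skipped")
            continue
        s_v.append(abs(_ls_slope(t[b : v + 1], y[b : v + 1])))
        s_d.append(abs(_ls_slope(t[v : e + 1], y[v : e + 1])))
    s_d, s_v = np.array(s_d), np.array(s_v)
    return SlopesResult(s_d, s_v, float(s_d.mean()), float(s_v.mean()))


def lateral_displacement(
    head_track: np.ndarray, cycles: CycleSet
) -> DisplacementResult:
    """Head displacement between bend extremes, per cycle.

    ``d_v`` is the Euclidean distance between the head position at the
    opening dorsal maximum and at the ventral minimum (dorso-ventral sweep);
    ``d_d`` between the ventral minimum and the closing dorsal maximum.
    """
    head = np.asarray(head_track, dtype=float)
    if head.ndim != 2 or head.shape[1] != 2:
        raise ValueError("head_track must have shape (frames, 2)")
    if cycles.n_cycles == 0:
        raise ValueError("no complete cycle")
    d_v, d_d = [], []
    for (b, e), v in zip(cycles.intervals, cycles.ventral_minima):
        d_v.append(float(np.linalg.norm(head[v] - head[b])))
        d_d.append(float(np.linalg.norm(head[e] - head[v])))
    d_v, d_d = np.array(d_v), np.array(d_d)
    mean_v, mean_d = float(d_v.mean()), float(d_d.mean())
    ratio = mean_v / mean_d if mean_d != 0 else float("nan")
    return DisplacementResult(d_v, d_d, mean_v, mean_d, ratio)


def centroid_speed(track: MidlineTrack) -> float:
    """Mean centroid speed: total centroid path length / elapsed time (µm/s)."""
    if track.n_frames < 2:
        raise ValueError("need at least two frames for a speed")
    c = track.centroid()
    path = float(np.linalg.norm(np.diff(c, axis=0), axis=1).sum())
    return path / ((track.n_frames - 1) / track.fps)


def _resample_by_arclength(xy: np.ndarray, step: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    # N equal steps spanning the whole path: the grid is symmetric under
    # traversal reversal, so the curvature estimate is too
    n_steps = max(int(np.floor(total / step)), 1)
    grid = np.linspace(0.0, total, n_steps + 1)
    x = np.interp(grid, arclen, xy[:, 0])
    y = np.interp(grid, arclen, xy[:, 1])
    return np.column_stack([x, y])


def path_curvature(centroid_track: np.ndarray, resample_step: float = 50.0) -> float:
    """Path curvature: summed unsigned turning angle / distance traveled.

    The trajectory is resampled at uniform arc-length steps
    (``resample_step``, µm) and the absolute turning angles between
    consecutive steps are summed and divided by the resampled path length,
    giving rad/µm.  Invariant to rigid motions and traversal direction.
    """
    xy = np.asarray(centroid_track, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("centroid_track must have shape (frames, 2)")
    if resample_step <= 0:
        raise ValueError("resample_step must be positive")
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    total = float(seg.sum())
    if total == 0.0:
        raise ValueError("degenerate (zero-length) path")
    if total < 2 * resample_step:
        raise ValueError("path shorter than two resampling steps")
    pts = _resample_by_arclength(xy, resample_step)
    d = np.diff(pts, axis=0)
    # drop zero-length steps that can appear at the very end of the grid
    d = d[np.linalg.norm(d, axis=1) > 0]
    if len(d) < 2:
        return 0.0
    ang = np.abs(np.radians(_signed_angle(d[:-1], d[1:])))
    length = float(np.linalg.norm(d, axis=1).sum())
    return float(ang.sum() / length)
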