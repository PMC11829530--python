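"""Oculomotor event detection: saccades, blinks and square-wave jerks.

Saccades are segmented with fixed velocity (30 deg/s), acceleration
(8000 deg/s^2) and motion (0.15 deg) thresholds, the standard parser
configuration for 500 Hz video-oculography.  Square-wave jerks (SWJs)
are paired from the saccade stream: a small outward saccade followed
within 200 ms by an approximately antiparallel return saccade that
refoveates the fixation point, both with amplitudes in [0.1, 5] deg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import GazeTrace, angular_amplitude

__all__ = [
    "DetectionParams",
    "SaccadeEvent",
    "BlinkEvent",
    "SWJEvent",
    "compute_velocity",
    "detect_blinks",
    "detect_saccades",
    "detect_swjs",
    "swj_rate",
]


@dataclass(frozen=True)
class DetectionParams:
    velocity_threshold_dps: float = 30.0
    acceleration_threshold_dps2: float = 8000.0
    motion_threshold_deg: float = 0.15
    swj_max_isi_ms: float = 200.0
    swj_min_amp_deg: float = 0.1
    swj_max_amp_deg: float = 5.0
    swj_direction_tol_deg: float = 30.0
    swj_refoveation_tol: float = 0.5
    min_blink_ms: float = 20.0
    blink_pad_ms: float = 50.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"DetectionParams.{name} must be positive")
        if self.swj_min_amp_deg >= self.swj_max_amp_deg:
            raise ValueError("swj_min_amp_deg must be < swj_max_amp_deg")


@dataclass(frozen=True)
class SaccadeEvent:
    onset_ms: float
    offset_ms: float
    start_deg: tuple
    end_deg: tuple
    amplitude_deg: float
    direction_deg: float  # [0, 360), 0 = rightward, 90 = upward
    peak_velocity_dps: float

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise ValueError("saccade offset must exceed onset")

    @property
    def dx(self) -> float:
        return self.end_deg[0] - self.start_deg[0]

    @property
    def dy(self) -> float:
        return self.end_deg[1] - self.start_deg[1]


@dataclass(frozen=True)
class BlinkEvent:
    onset_ms: float
    offset_ms: float

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise ValueError("blink offset must exceed onset")

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass(frozen=True)
class SWJEvent:
    first: SaccadeEvent
    second: SaccadeEvent

    @property
    def isi_ms(self) -> float:
        return self.second.onset_ms - self.first.offset_ms


# ---------------------------------------------------------------------------
# kinematics

_D5 = np.array([-1.0, 8.0, 0.0, -8.0, 1.0]) / 12.0  # 5-point central difference


def compute_velocity(trace: GazeTrace):
    """Per-sample speed (deg/s) and acceleration (deg/s^2).

    Velocity uses a 5-point central difference on each axis, combined as
    sqrt(vx^2 + vy^2); acceleration is the first difference of speed.
    Invalid samples propagate as NaN through the difference windows.
    The two edge samples on either side are NaN.
    """
    n = len(trace)
    if n < 5:
        raise ValueError("need at least 5 samples to compute velocity")
    dt_s = (1000.0 / trace.nominal_rate_hz) / 1000.0
    x = np.where(trace.valid, trace.x_deg, np.nan)
    y = np.where(trace.valid, trace.y_deg, np.nan)
    # correlate with the difference kernel; edges padded with NaN
    vx = np.full(n, np.nan)
    vy = np.full(n, np.nan)
    vx[2:-2] = np.convolve(x, _D5[::-1], mode="valid") / dt_s
    vy[2:-2] = np.convolve(y, _D5[::-1], mode="valid") / dt_s
    speed = np.hypot(vx, vy)
    accel = np.full(n, np.nan)
    accel[1:] = np.diff(speed) / dt_s
    return speed, accel


# ---------------------------------------------------------------------------
# blinks


def detect_blinks(trace: GazeTrace, min_duration_ms: float = 20.0):
    """Maximal runs of invalid samples longer than ``min_duration_ms``."""
    v = trace.valid
    if v.all():
        return []
    inv = (~v).astype(np.int8)
    d = np.diff(np.concatenate(([0], inv, [0])))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1  # inclusive index
    dt = 1000.0 / trace.nominal_rate_hz
    out = []
    for s, e in zip(starts, ends):
        onset = trace.t_ms[s]
        offset = trace.t_ms[e] + dt
        if offset - onset > min_duration_ms:
            out.append(BlinkEvent(float(onset), float(offset)))
    return out


# ---------------------------------------------------------------------------
# saccades


def _runs(mask: np.ndarray):
    m = mask.astype(np.int8)
    d = np.diff(np.concatenate(([0], m, [0])))
    return np.flatnonzero(d == 1), np.flatnonzero(d == -1) - 1


def detect_saccades(trace: GazeTrace, params: DetectionParams | None = None,
                    blinks=None):
    """Segment saccades from a trace.

    A candidate region is open wherever speed exceeds the velocity
    threshold or |acceleration| exceeds the acceleration threshold, and
    closes when speed falls back below the velocity threshold.  Regions
    separated by fewer than 2 samples are merged; a region is kept only
    if its net displacement reaches the motion threshold.  Candidates
    within ``blink_pad_ms`` of a blink are discarded (eyelid artifacts
    mimic saccades).
    """
    params = params or DetectionParams()
    if blinks is None:
        blinks = detect_blinks(trace)
    speed, accel = compute_velocity(trace)
    above_v = np.nan_to_num(speed, nan=0.0) > params.velocity_threshold_dps
    above_a = np.abs(np.nan_to_num(accel, nan=0.0)) > params.acceleration_threshold_dps2
    cand = above_v | above_a
    starts, ends = _runs(cand)
    if starts.size == 0:
        return []
    # merge regions separated by < 2 samples
    merged = [[int(starts[0]), int(ends[0])]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] - 1 < 2:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])

    t = trace.t_ms
    x, y = trace.x_deg, trace.y_deg
    n = len(trace)
    out = []
    for s, e in merged:
        i0 = max(s - 1, 0)
        i1 = min(e + 1, n - 1)
        start = (float(x[i0]), float(y[i0]))
        end = (float(x[i1]), float(y[i1]))
        if not all(map(math.isfinite, (*start, *end))):
            continue
        amp = angular_amplitude(start, end)
        if amp < params.motion_threshold_deg:
            continue
        onset, offset = float(t[s]), float(t[i1])
        if any(b.onset_ms - params.blink_pad_ms <= offset
               and onset <= b.offset_ms + params.blink_pad_ms for b in blinks):
            continue
        pv = float(np.nanmax(speed[s:e + 1]))
        direction = math.degrees(math.atan2(end[1] - start[1], end[0] - start[0])) % 360.0
        out.append(SaccadeEvent(onset, offset, start, end, amp, direction, pv))
    return out


# ---------------------------------------------------------------------------
# square-wave jerks


def _angle_diff(a: float, b: float) -> float:
    """Absolute angular difference in degrees, in [0, 180]."""
    return abs((a - b + 180.0) % 360.0 - 180.0)


def detect_swjs(saccades, fixation_deg=(0.0, 0.0),
                params: DetectionParams | None = None):
    """Pair consecutive saccades into square-wave jerks.

    A consecutive pair (i, i+1) qualifies when all four hold:

    a. both amplitudes lie in [swj_min_amp_deg, swj_max_amp_deg];
    b. the inter-saccadic interval (second onset - first offset) is in
       [0, swj_max_isi_ms];
    c. the first saccade moves gaze away from ``fixation_deg`` and the
       second's direction is within ``swj_direction_tol_deg`` of
       antiparallel to the first;
    d. the second saccade ends within ``swj_refoveation_tol`` x (first
       amplitude) of ``fixation_deg``.

    Pairing is greedy left-to-right; each saccade joins at most one SWJ.
    """
    params = params or DetectionParams()
    out = []
    i = 0
    while i < len(saccades) - 1:
        a, b = saccades[i], saccades[i + 1]
        if b.onset_ms < a.onset_ms:
            raise ValueError("saccades must be time-ordered")
        isi = b.onset_ms - a.offset_ms
        amp_ok = (params.swj_min_amp_deg <= a.amplitude_deg <= params.swj_max_amp_deg
                  and params.swj_min_amp_deg <= b.amplitude_deg <= params.swj_max_amp_deg)
        isi_ok = 0.0 <= isi <= params.swj_max_isi_ms
        away = (angular_amplitude(fixation_deg, a.end_deg)
                > angular_amplitude(fixation_deg, a.start_deg))
        anti = _angle_diff(b.direction_deg, a.direction_deg + 180.0) <= params.swj_direction_tol_deg
        refov = (angular_amplitude(fixation_deg, b.end_deg)
                 <= params.swj_refoveation_tol * a.amplitude_deg)
        if amp_ok and isi_ok and away and anti and refov:
            out.append(SWJEvent(a, b))
            i += 2
        else:
            i += 1
    return out


def swj_rate(swjs, analyzed_duration_ms: float) -> float:
    """SWJs per minute of analysed recording."""
    if analyzed_duration_ms <= 0:
        raise ValueError("analyzed duration must be positive")
    n = swjs if isinstance(swjs, (int, np.integer)) else len(swjs)
    return n / (analyzed_duration_ms / 60000.0)
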