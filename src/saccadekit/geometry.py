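"""Core domain types: screen geometry, gaze traces, trial annotations.

All internal gaze positions are in degrees of visual angle, with the
screen centre as origin, rightward and upward positive.  Conversion
between pixels and degrees uses a per-axis arctangent about the screen
centre, which is exact at the 8-10 deg eccentricities the saccade tasks
use (a small-angle linearisation would already be ~1% off at 10 deg).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "ScreenGeometry",
    "GazeTrace",
    "Task",
    "TrialAnnotation",
    "Psychometrics",
    "Recording",
    "px_to_deg",
    "deg_to_px",
    "angular_amplitude",
    "average_eyes",
]


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display geometry used for pixel <-> degree conversion.

    Defaults describe a 24-inch 16:9 monitor at 1920x1080 viewed from
    90 cm, the configuration the default task battery assumes.
    """

    width_px: int = 1920
    height_px: int = 1080
    width_cm: float = 53.136
    height_cm: float = 29.889
    distance_cm: float = 90.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"ScreenGeometry.{f.name} must be positive, got {v!r}")
        aspect_px = self.width_px / self.height_px
        aspect_cm = self.width_cm / self.height_cm
        if abs(aspect_px - aspect_cm) / aspect_cm > 0.01:
            raise ValueError(
                "pixel aspect ratio and physical aspect ratio disagree by more "
                f"than 1% ({aspect_px:.4f} vs {aspect_cm:.4f}); check width/height"
            )

    @classmethod
    def from_diagonal(
        cls,
        diagonal_in: float = 24.0,
        width_px: int = 1920,
        height_px: int = 1080,
        distance_cm: float = 90.0,
    ) -> "ScreenGeometry":
        """Derive physical size from the diagonal (inches) and pixel aspect."""
        if diagonal_in <= 0:
            raise ValueError("diagonal must be positive")
        aspect = width_px / height_px
        height_cm = diagonal_in * 2.54 / math.hypot(aspect, 1.0)
        return cls(
            width_px=width_px,
            height_px=height_px,
            width_cm=aspect * height_cm,
            height_cm=height_cm,
            distance_cm=distance_cm,
        )

    @property
    def cm_per_px_x(self) -> float:
        return self.width_cm / self.width_px

    @property
    def cm_per_px_y(self) -> float:
        return self.height_cm / self.height_px


def px_to_deg(px_x, px_y, geom: ScreenGeometry):
    """Convert pixel coordinates (origin top-left, y down) to degrees.

    Returns ``(x_deg, y_deg)`` with screen-centre origin, rightward and
    upward positive.  Vectorised over array inputs.
    """
    px_x = np.asarray(px_x, dtype=float)
    px_y = np.asarray(px_y, dtype=float)
    if not (np.all(np.isfinite(px_x)) and np.all(np.isfinite(px_y))):
        raise ValueError("pixel coordinates must be finite")
    dx_cm = (px_x - geom.width_px / 2.0) * geom.cm_per_px_x
    dy_cm = (geom.height_px / 2.0 - px_y) * geom.cm_per_px_y
    x_deg = np.degrees(np.arctan2(dx_cm, geom.distance_cm))
    y_deg = np.degrees(np.arctan2(dy_cm, geom.distance_cm))
    return x_deg, y_deg


def deg_to_px(x_deg, y_deg, geom: ScreenGeometry):
    """Inverse of :func:`px_to_deg` (exact to floating-point rounding)."""
    x_deg = np.asarray(x_deg, dtype=float)
    y_deg = np.asarray(y_deg, dtype=float)
    if not (np.all(np.isfinite(x_deg)) and np.all(np.isfinite(y_deg))):
        raise ValueError("degree coordinates must be finite")
    dx_cm = geom.distance_cm * np.tan(np.radians(x_deg))
    dy_cm = geom.distance_cm * np.tan(np.radians(y_deg))
    px_x = dx_cm / geom.cm_per_px_x + geom.width_px / 2.0
    px_y = geom.height_px / 2.0 - dy_cm / geom.cm_per_px_y
    return px_x, px_y


def angular_amplitude(p0, p1) -> float:
    """Euclidean amplitude (deg) between two (x_deg, y_deg) positions."""
    dx = float(p1[0]) - float(p0[0])
    dy = float(p1[1]) - float(p0[1])
    if not (math.isfinite(dx) and math.isfinite(dy)):
        raise ValueError("positions must be finite")
    return math.hypot(dx, dy)


def average_eyes(left: np.ndarray, right: np.ndarray,
                 left_valid: np.ndarray, right_valid: np.ndarray):
    """Binocular-to-monocular reduction: mean of the eyes where both are
    valid, the valid eye where only one is, NaN (invalid) where neither.

    ``left``/``right`` are (n, 2) position arrays in degrees.  Returns
    ``(pos, valid)``.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    lv = np.asarray(left_valid, dtype=bool)
    rv = np.asarray(right_valid, dtype=bool)
    pos = np.full_like(left, np.nan)
    both = lv & rv
    pos[both] = 0.5 * (left[both] + right[both])
    only_l = lv & ~rv
    pos[only_l] = left[only_l]
    only_r = rv & ~lv
    pos[only_r] = right[only_r]
    return pos, lv | rv


class GazeTrace:
    """Time-ordered monocular(-reduced) gaze samples for one trial.

    Stored as parallel numpy arrays: ``t_ms`` (strictly increasing),
    ``x_deg``, ``y_deg`` and boolean ``valid`` (False during signal loss
    or blinks).  The median inter-sample interval must agree with the
    nominal rate within 10%.
    """

    __slots__ = ("t_ms", "x_deg", "y_deg", "valid", "nominal_rate_hz")

    def __init__(self, t_ms, x_deg, y_deg, valid=None, nominal_rate_hz: float = 500.0):
        t = np.asarray(t_ms, dtype=float)
        x = np.asarray(x_deg, dtype=float)
        y = np.asarray(y_deg, dtype=float)
        if valid is None:
            valid = np.isfinite(x) & np.isfinite(y)
        v = np.asarray(valid, dtype=bool)
        if not (t.shape == x.shape == y.shape == v.shape) or t.ndim != 1:
            raise ValueError("t_ms, x_deg, y_deg, valid must be equal-length 1-D arrays")
        if t.size == 0:
            raise ValueError("empty trace")
        if np.any(t < 0) or not np.all(np.isfinite(t)):
            raise ValueError("t_ms must be finite and non-negative")
        dt = np.diff(t)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0)) + 1
            raise ValueError(f"t_ms not strictly increasing at sample {i}")
        if nominal_rate_hz <= 0:
            raise ValueError("nominal_rate_hz must be positive")
        if t.size > 1:
            expected = 1000.0 / nominal_rate_hz
            med = float(np.median(dt))
            if abs(med - expected) > 0.1 * expected:
                raise ValueError(
                    f"median inter-sample interval {med:.3f} ms inconsistent with "
                    f"nominal rate {nominal_rate_hz} Hz ({expected:.3f} ms)"
                )
        self.t_ms = t
        self.x_deg = x
        self.y_deg = y
        self.valid = v
        self.nominal_rate_hz = float(nominal_rate_hz)

    def __len__(self) -> int:
        return self.t_ms.size

    @property
    def duration_ms(self) -> float:
        return float(self.t_ms[-1] - self.t_ms[0])

    def position_at(self, t: float):
        """Position of the sample nearest to time ``t`` (ms)."""
        i = int(np.argmin(np.abs(self.t_ms - t)))
        return float(self.x_deg[i]), float(self.y_deg[i])


class Task(str, enum.Enum):
    FIXATION = "fixation"
    PROSACCADE = "prosaccade"
    ANTISACCADE = "antisaccade"
    MEMORY_GUIDED = "memory_guided"


@dataclass(frozen=True)
class TrialAnnotation:
    """Timing and target metadata for one trial (trial-relative ms)."""

    task: Task
    block_index: int
    fixation_onset_ms: float
    trial_end_ms: float
    target_onset_ms: float | None = None
    target_x_deg: float | None = None
    target_offset_ms: float | None = None
    go_signal_ms: float | None = None

    def __post_init__(self) -> None:
        task = Task(self.task)
        object.__setattr__(self, "task", task)
        if self.trial_end_ms <= self.fixation_onset_ms:
            raise ValueError("trial_end_ms must exceed fixation_onset_ms")
        if task is Task.FIXATION:
            return
        if self.target_onset_ms is None or self.target_x_deg is None:
            raise ValueError(f"{task.value} trial requires target_onset_ms and target_x_deg")
        if not (self.fixation_onset_ms < self.target_onset_ms < self.trial_end_ms):
            raise ValueError("need fixation_onset_ms < target_onset_ms < trial_end_ms")
        delay = self.target_onset_ms - self.fixation_onset_ms
        if not (1000.0 <= delay <= 3000.0):
            raise ValueError(f"fixation period must be 1000-3000 ms, got {delay:g}")
        if task is Task.MEMORY_GUIDED:
            if self.target_offset_ms is None or self.go_signal_ms is None:
                raise ValueError("memory-guided trial requires target_offset_ms and go_signal_ms")
            if abs((self.target_offset_ms - self.target_onset_ms) - 50.0) > 1e-9:
                raise ValueError("memory-guided target flash must last 50 ms")
            if not (self.target_offset_ms <= self.go_signal_ms < self.trial_end_ms):
                raise ValueError("go signal must follow target offset and precede trial end")


_PSY_RANGES = {
    "edeq_restraint": (0.0, 6.0),
    "edeq_eating": (0.0, 6.0),
    "edeq_shape": (0.0, 6.0),
    "edeq_weight": (0.0, 6.0),
    "edeq_global": (0.0, 6.0),
    "stai_state": (0.0, 80.0),
    "stai_trait": (0.0, 80.0),
    "premorbid_iq": (0.0, 30.0),
}


@dataclass(frozen=True)
class Psychometrics:
    """Questionnaire covariates: S-EDE-Q subscales/global (0-6), STAI
    state/trait (0-80), premorbid IQ word-reading score (0-30), age, BMI."""

    edeq_restraint: float
    edeq_eating: float
    edeq_shape: float
    edeq_weight: float
    edeq_global: float
    stai_state: float
    stai_trait: float
    premorbid_iq: int
    age: float
    bmi: float

    def __post_init__(self) -> None:
        for name, (lo, hi) in _PSY_RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"Psychometrics.{name}={v!r} outside [{lo}, {hi}]")


SCHEDULE_COUNTS = {Task.FIXATION: 3, Task.PROSACCADE: 240, Task.MEMORY_GUIDED: 52}


@dataclass
class Recording:
    """One participant's full session: geometry, trials and covariates.

    The pro/antisaccade block contributes 240 trials (annotated
    per-trial as prosaccade or antisaccade), the fixation task 3 and
    the memory-guided task 52 when the session is complete.
    """

    participant_id: str
    group: str
    geometry: ScreenGeometry
    trials: list  # list[(TrialAnnotation, GazeTrace)]
    psychometrics: Psychometrics = None
    complete: bool = True

    def __post_init__(self) -> None:
        if self.group not in ("control", "subclinical"):
            raise ValueError(f"group must be 'control' or 'subclinical', got {self.group!r}")
        if self.complete:
            n_fix = sum(1 for a, _ in self.trials if a.task is Task.FIXATION)
            n_sac = sum(1 for a, _ in self.trials
                        if a.task in (Task.PROSACCADE, Task.ANTISACCADE))
            n_mg = sum(1 for a, _ in self.trials if a.task is Task.MEMORY_GUIDED)
            expected = (3, 240, 52)
            if (n_fix, n_sac, n_mg) != expected:
                raise ValueError(
                    f"complete recording needs (fixation, pro/anti, memory-guided) "
                    f"trial counts {expected}, got ({n_fix}, {n_sac}, {n_mg})"
                )

    def trials_for(self, *tasks: Task):
        tasks = tuple(Task(t) for t in tasks)
        return [(a, tr) for a, tr in self.trials if a.task in tasks]
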