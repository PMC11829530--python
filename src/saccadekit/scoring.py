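"""Trial classification and participant-level outcome aggregation.

Each valid trial of the pro/antisaccade and memory-guided tasks is
assigned one category (correct, anticipation, prosaccade error,
corrected/uncorrected antisaccade error, inhibitory or directional
memory-guided error); trials lost to blinks, fixation errors or
amplitude violations are excluded with a reason.  Saccades smaller
than 2 degrees never enter the analysis.  Error rates are proportions
of erroneous trials among all valid (non-excluded) trials; gain,
latency and peak velocity are means over correct trials only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import BlinkEvent, DetectionParams, SaccadeEvent, detect_blinks, detect_saccades
from .geometry import GazeTrace, ScreenGeometry, Task, TrialAnnotation

__all__ = [
    "ScoringParams",
    "TrialScore",
    "OUTCOME_FAMILY",
    "apply_exclusions",
    "primary_saccade",
    "score_trial",
    "score_prosaccade",
    "score_antisaccade",
    "score_memory_guided",
    "aggregate_outcomes",
    "participant_outlier_qc",
]


@dataclass(frozen=True)
class ScoringParams:
    anticipation_window_ms: float = 80.0
    min_saccade_amp_deg: float = 2.0
    fixation_error_radius_deg: float = 2.0
    fixation_error_min_dur_ms: float = 100.0
    max_gain: float = 2.0
    response_window_ms: float = 1000.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"ScoringParams.{name} must be positive")


@dataclass(frozen=True)
class TrialScore:
    status: str                      # valid | excluded
    exclusion_reason: str | None = None
    category: str | None = None
    latency_ms: float | None = None
    gain: float | None = None
    peak_velocity_dps: float | None = None
    correction_latency_ms: float | None = None
    eccentricity_deg: float | None = None

    def __post_init__(self) -> None:
        if self.status == "excluded":
            if self.exclusion_reason is None or self.category is not None:
                raise ValueError("excluded trials need a reason and no category")
        elif self.status == "valid":
            if self.category is None:
                raise ValueError("valid trials need a category")
            if self.category == "corrected_error" and self.correction_latency_ms is None:
                raise ValueError("corrected_error requires correction_latency_ms")
        else:
            raise ValueError(f"unknown status {self.status!r}")


# The 23-outcome comparison family: 1 fixation + 5 prosaccade +
# 7 antisaccade + 10 memory-guided measures.
OUTCOME_FAMILY = [
    "swj_rate_per_min",
    "pro_gain", "pro_latency_ms", "pro_peak_velocity_dps",
    "pro_anticipation_rate", "pro_error_rate",
    "anti_gain", "anti_latency_ms", "anti_peak_velocity_dps",
    "anti_anticipation_rate", "anti_uncorrected_rate", "anti_corrected_rate",
    "anti_correction_latency_ms",
    "mg_gain_5", "mg_gain_10", "mg_latency_5_ms", "mg_latency_10_ms",
    "mg_peak_velocity_5_dps", "mg_peak_velocity_10_dps",
    "mg_inhibitory_5", "mg_inhibitory_10", "mg_directional_5", "mg_directional_10",
]


# ---------------------------------------------------------------------------
# helpers


def _analysed(saccades, params: ScoringParams):
    """Saccades at or above the 2-degree analysis floor."""
    return [s for s in saccades if s.amplitude_deg >= params.min_saccade_amp_deg]


def _toward_target(sacc: SaccadeEvent, target_x: float) -> bool:
    return math.copysign(1.0, sacc.dx) == math.copysign(1.0, target_x)


def primary_saccade(saccades, ann: TrialAnnotation, params: ScoringParams,
                    reference_ms: float | None = None):
    """First analysed (>= 2 deg) saccade at or after the reference event
    (target onset for pro/anti, go signal for memory-guided).  Returns
    ``None`` when no such saccade exists."""
    if reference_ms is None:
        reference_ms = (ann.go_signal_ms if ann.task is Task.MEMORY_GUIDED
                        else ann.target_onset_ms)
    for s in _analysed(saccades, params):
        if s.onset_ms >= reference_ms:
            return s
    return None


def _fixation_error(trace: GazeTrace, t0: float, t1: float,
                    params: ScoringParams) -> bool:
    """Gaze left the fixation radius for >= the minimum dwell within
    [t0, t1] (valid samples only)."""
    sel = (trace.t_ms >= t0) & (trace.t_ms <= t1) & trace.valid
    if not sel.any():
        return False
    r = np.hypot(trace.x_deg[sel], trace.y_deg[sel])
    out = r > params.fixation_error_radius_deg
    if not out.any():
        return False
    dt = 1000.0 / trace.nominal_rate_hz
    run = 0
    for o in out:
        run = run + 1 if o else 0
        if run * dt >= params.fixation_error_min_dur_ms:
            return True
    return False


def _off_screen(sacc: SaccadeEvent, geom: ScreenGeometry) -> bool:
    half_x = math.degrees(math.atan2(geom.width_cm / 2.0, geom.distance_cm))
    half_y = math.degrees(math.atan2(geom.height_cm / 2.0, geom.distance_cm))
    ex, ey = sacc.end_deg
    return abs(ex) > half_x or abs(ey) > half_y


def apply_exclusions(trace: GazeTrace, ann: TrialAnnotation, saccades, blinks,
                     params: ScoringParams, geom: ScreenGeometry | None = None,
                     skip_fixation_check: bool = False):
    """Exclusion reason for a task trial, or ``None`` if it stands.

    Precedence is blink > fixation error > amplitude threshold.  The
    fixation-error window ends at target onset; for the memory-guided
    task the delay period is governed by the inhibitory-error outcome
    instead, so departures there are scored, not excluded.
    ``skip_fixation_check`` suppresses the fixation-error rule when an
    anticipatory saccade already explains the departure.
    """
    geom = geom or ScreenGeometry()
    primary = primary_saccade(saccades, ann, params)
    window_end = primary.offset_ms if primary is not None else ann.trial_end_ms
    t0 = ann.target_onset_ms - 100.0
    if any(b.onset_ms <= window_end and b.offset_ms >= t0 for b in blinks):
        return "blink"
    if not skip_fixation_check and _fixation_error(
            trace, ann.fixation_onset_ms, ann.target_onset_ms, params):
        return "fixation_error"
    if primary is not None:
        denom = abs(ann.target_x_deg)
        if primary.amplitude_deg / denom > params.max_gain or _off_screen(primary, geom):
            return "amplitude_threshold"
    return None


def _anticipatory(saccades, ann: TrialAnnotation, params: ScoringParams):
    """First analysed saccade in the fixation period or within the
    80 ms post-target window (too early to be stimulus-driven)."""
    cutoff = ann.target_onset_ms + params.anticipation_window_ms
    for s in _analysed(saccades, params):
        if ann.fixation_onset_ms <= s.onset_ms < cutoff:
            return s
    return None


# ---------------------------------------------------------------------------
# per-task scoring


def score_prosaccade(trace, ann, saccades, blinks,
                     params: ScoringParams | None = None,
                     geom: ScreenGeometry | None = None) -> TrialScore:
    params = params or ScoringParams()
    ant = _anticipatory(saccades, ann, params)
    reason = apply_exclusions(trace, ann, saccades, blinks, params, geom,
                              skip_fixation_check=ant is not None)
    if reason == "blink":
        return TrialScore("excluded", "blink")
    if ant is not None:
        return TrialScore("valid", category="anticipation",
                          latency_ms=ant.onset_ms - ann.target_onset_ms)
    if reason is not None:
        return TrialScore("excluded", reason)
    prim = primary_saccade(saccades, ann, params)
    if prim is None:
        return TrialScore("excluded", "no_saccade")
    latency = prim.onset_ms - ann.target_onset_ms
    if not _toward_target(prim, ann.target_x_deg):
        return TrialScore("valid", category="prosaccade_error", latency_ms=latency)
    return TrialScore("valid", category="correct", latency_ms=latency,
                      gain=prim.amplitude_deg / abs(ann.target_x_deg),
                      peak_velocity_dps=prim.peak_velocity_dps)


def score_antisaccade(trace, ann, saccades, blinks,
                      params: ScoringParams | None = None,
                      geom: ScreenGeometry | None = None) -> TrialScore:
    params = params or ScoringParams()
    ant = _anticipatory(saccades, ann, params)
    reason = apply_exclusions(trace, ann, saccades, blinks, params, geom,
                              skip_fixation_check=ant is not None)
    if reason == "blink":
        return TrialScore("excluded", "blink")
    if ant is not None:
        return TrialScore("valid", category="anticipation",
                          latency_ms=ant.onset_ms - ann.target_onset_ms)
    if reason is not None:
        return TrialScore("excluded", reason)
    prim = primary_saccade(saccades, ann, params)
    if prim is None:
        return TrialScore("excluded", "no_saccade")
    latency = prim.onset_ms - ann.target_onset_ms
    mirror_sign = -math.copysign(1.0, ann.target_x_deg)
    if _toward_target(prim, ann.target_x_deg):
        # erroneous reflexive saccade: corrected if a later analysed
        # saccade crosses to the mirror side within the trial
        for s in _analysed(saccades, params):
            if s.onset_ms > prim.onset_ms and math.copysign(1.0, s.end_deg[0]) == mirror_sign:
                return TrialScore("valid", category="corrected_error",
                                  latency_ms=latency,
                                  correction_latency_ms=s.onset_ms - prim.onset_ms)
        return TrialScore("valid", category="uncorrected_error", latency_ms=latency)
    return TrialScore("valid", category="correct", latency_ms=latency,
                      gain=prim.amplitude_deg / abs(ann.target_x_deg),
                      peak_velocity_dps=prim.peak_velocity_dps)


def score_memory_guided(trace, ann, saccades, blinks,
                        params: ScoringParams | None = None,
                        geom: ScreenGeometry | None = None) -> TrialScore:
    params = params or ScoringParams()
    ecc = abs(ann.target_x_deg)
    # inhibitory error: looking at the dot, or any analysed saccade
    # toward it, before the response period begins
    inhibitory = None
    for s in _analysed(saccades, params):
        if (ann.target_onset_ms <= s.onset_ms < ann.go_signal_ms
                and _toward_target(s, ann.target_x_deg)):
            inhibitory = s
            break
    reason = apply_exclusions(trace, ann, saccades, blinks, params, geom,
                              skip_fixation_check=False)
    if reason == "blink":
        return TrialScore("excluded", "blink")
    if inhibitory is not None:
        return TrialScore("valid", category="inhibitory_error", eccentricity_deg=ecc)
    if reason is not None:
        return TrialScore("excluded", reason, eccentricity_deg=None)
    prim = primary_saccade(saccades, ann, params)
    if prim is None or prim.onset_ms > ann.go_signal_ms + params.response_window_ms:
        return TrialScore("excluded", "no_saccade")
    latency = prim.onset_ms - ann.go_signal_ms
    if not _toward_target(prim, ann.target_x_deg):
        return TrialScore("valid", category="directional_error",
                          latency_ms=latency, eccentricity_deg=ecc)
    return TrialScore("valid", category="correct", latency_ms=latency,
                      gain=prim.amplitude_deg / ecc,
                      peak_velocity_dps=prim.peak_velocity_dps,
                      eccentricity_deg=ecc)


_SCORERS = {
    Task.PROSACCADE: score_prosaccade,
    Task.ANTISACCADE: score_antisaccade,
    Task.MEMORY_GUIDED: score_memory_guided,
}


def score_trial(trace: GazeTrace, ann: TrialAnnotation,
                params: ScoringParams | None = None,
                detection: DetectionParams | None = None,
                geom: ScreenGeometry | None = None,
                saccades=None, blinks=None) -> TrialScore:
    """Detect events (unless provided) and score one task trial."""
    if ann.task is Task.FIXATION:
        raise ValueError("fixation trials are analysed at the event level, not scored")
    if blinks is None:
        blinks = detect_blinks(trace)
    if saccades is None:
        saccades = detect_saccades(trace, detection or DetectionParams(), blinks)
    return _SCORERS[ann.task](trace, ann, saccades, blinks,
                              params or ScoringParams(), geom)


# ---------------------------------------------------------------------------
# aggregation


def _rate(count: int, valid: int) -> float:
    return count / valid if valid > 0 else np.nan


def _mean(values) -> float:
    return float(np.mean(values)) if values else np.nan


def aggregate_outcomes(participant_id: str, group: str, scored,
                       swj_rate_per_min: float,
                       psychometrics=None) -> dict:
    """Collapse per-trial scores into one participant outcome row.

    ``scored`` is a sequence of ``(TrialAnnotation, TrialScore)``.
    Error rates are proportions of valid trials (memory-guided rates use
    the eccentricity's own valid-trial denominator); kinematic outcomes
    are means over correct trials.  Tasks with zero valid trials yield
    NaN (missing), never zero.
    """
    by_task = {t: [] for t in (Task.PROSACCADE, Task.ANTISACCADE, Task.MEMORY_GUIDED)}
    for ann, sc in scored:
        if ann.task in by_task:
            by_task[ann.task].append((ann, sc))

    row = {"participant_id": participant_id, "group": group,
           "swj_rate_per_min": swj_rate_per_min}

    for task, prefix in ((Task.PROSACCADE, "pro"), (Task.ANTISACCADE, "anti")):
        trials = by_task[task]
        valid = [sc for _, sc in trials if sc.status == "valid"]
        nv = len(valid)
        correct = [sc for sc in valid if sc.category == "correct"]
        row[f"{prefix}_gain"] = _mean([sc.gain for sc in correct])
        row[f"{prefix}_latency_ms"] = _mean([sc.latency_ms for sc in correct])
        row[f"{prefix}_peak_velocity_dps"] = _mean([sc.peak_velocity_dps for sc in correct])
        row[f"{prefix}_anticipation_rate"] = _rate(
            sum(sc.category == "anticipation" for sc in valid), nv)
        if task is Task.PROSACCADE:
            row["pro_error_rate"] = _rate(
                sum(sc.category == "prosaccade_error" for sc in valid), nv)
        else:
            row["anti_uncorrected_rate"] = _rate(
                sum(sc.category == "uncorrected_error" for sc in valid), nv)
            row["anti_corrected_rate"] = _rate(
                sum(sc.category == "corrected_error" for sc in valid), nv)
            row["anti_correction_latency_ms"] = _mean(
                [sc.correction_latency_ms for sc in valid
                 if sc.category == "corrected_error"])

    for ecc, suffix in ((5.0, "5"), (10.0, "10")):
        trials = [(a, sc) for a, sc in by_task[Task.MEMORY_GUIDED]
                  if abs(a.target_x_deg) == ecc]
        valid = [sc for _, sc in trials if sc.status == "valid"]
        nv = len(valid)
        correct = [sc for sc in valid if sc.category == "correct"]
        row[f"mg_gain_{suffix}"] = _mean([sc.gain for sc in correct])
        row[f"mg_latency_{suffix}_ms"] = _mean([sc.latency_ms for sc in correct])
        row[f"mg_peak_velocity_{suffix}_dps"] = _mean(
            [sc.peak_velocity_dps for sc in correct])
        row[f"mg_inhibitory_{suffix}"] = _rate(
            sum(sc.category == "inhibitory_error" for sc in valid), nv)
        row[f"mg_directional_{suffix}"] = _rate(
            sum(sc.category == "directional_error" for sc in valid), nv)

    sacc_trials = by_task[Task.PROSACCADE] + by_task[Task.ANTISACCADE]
    mg_trials = by_task[Task.MEMORY_GUIDED]
    for name, trials in (("saccade", sacc_trials), ("memory_guided", mg_trials)):
        n = len(trials)
        row[f"excl_pct_{name}"] = (
            100.0 * sum(sc.status == "excluded" for _, sc in trials) / n
            if n else np.nan)

    if psychometrics is not None:
        for fname in ("edeq_restraint", "edeq_eating", "edeq_shape", "edeq_weight",
                      "edeq_global", "stai_state", "stai_trait", "premorbid_iq",
                      "age", "bmi"):
            row[fname] = getattr(psychometrics, fname)
    return row


def participant_outlier_qc(rows: pd.DataFrame,
                           columns=("excl_pct_saccade", "excl_pct_memory_guided")
                           ) -> pd.Series:
    """Flag participants whose excluded-trial percentage on any task
    exceeds the Tukey upper fence Q3 + 1.5 IQR (strict inequality)."""
    if len(rows) < 4:
        raise ValueError("need at least 4 participants for boxplot QC")
    flags = pd.Series(False, index=rows.index)
    for col in columns:
        vals = rows[col].astype(float)
        q1, q3 = np.nanpercentile(vals, [25, 75])
        fence = q3 + 1.5 * (q3 - q1)
        flags |= vals > fence
    return flags
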