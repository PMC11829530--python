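"""Ground-truthed synthetic gaze recordings.

Generates the three-task battery — fixation (3 x 60 s), the five-block
prosaccade/antisaccade sequence (60 pro, 40 anti, 40 anti, 40 anti,
60 pro at +/-8 deg) and 52 memory-guided trials (13 per side x {5, 10}
deg cell) — as 500 Hz gaze traces with known injected events.

Saccades follow the main sequence v_peak = v_max * (1 - exp(-A/A0))
with a raised-cosine velocity profile (smooth and symmetric; the
detector only needs realistic kinematics, and real saccadic waveforms
are not modelled beyond that).  Fixation trials receive Poisson
square-wave-jerk pairs; task trials realise exactly one sampled
behaviour category (correct / anticipation / direction error / ...)
whose identity is recorded in a :class:`TruthRecord`.  Blinks are
validity gaps of 100-300 ms.

Default rates and distribution locations follow the scale of the study
this battery emulates (e.g. prosaccade latency median ~317 ms,
antisaccade anticipation ~0.55); distribution *shapes* (lognormal
latencies, Gaussian gain) are stand-ins, flagged as such in the docs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (
    GazeTrace,
    Psychometrics,
    Recording,
    ScreenGeometry,
    Task,
    TrialAnnotation,
)

__all__ = [
    "DistSpec",
    "BehaviorProfile",
    "PsychometricsSpec",
    "CohortConfig",
    "TruthRecord",
    "InjectedSaccade",
    "main_sequence_peak_velocity",
    "make_schedule",
    "simulate_trial",
    "simulate_recording",
    "simulate_cohort",
    "truth_table",
]


@dataclass(frozen=True)
class DistSpec:
    """Tiny distribution spec: ``uniform(lo, hi)``, ``normal(mean, sd)``
    or ``lognormal(median, sigma)`` (sigma on the log scale)."""

    kind: str
    a: float
    b: float

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "normal", "lognormal"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "uniform" and self.a >= self.b:
            raise ValueError("uniform needs a < b")
        if self.kind in ("normal", "lognormal") and self.b < 0:
            raise ValueError("scale parameter must be non-negative")

    def sample(self, rng: np.random.Generator, size=None):
        if self.kind == "uniform":
            return rng.uniform(self.a, self.b, size)
        if self.kind == "normal":
            return rng.normal(self.a, self.b, size)
        return np.exp(rng.normal(math.log(self.a), self.b, size))

    @property
    def support(self):
        if self.kind == "uniform":
            return (self.a, self.b)
        if self.kind == "lognormal":
            return (0.0, math.inf)
        return (-math.inf, math.inf)


def main_sequence_peak_velocity(amplitude_deg: float, v_max_dps: float = 500.0,
                                amp_const_deg: float = 5.0) -> float:
    """Main-sequence peak velocity: v_max * (1 - exp(-A / A0))."""
    return v_max_dps * (1.0 - math.exp(-amplitude_deg / amp_const_deg))


@dataclass(frozen=True)
class BehaviorProfile:
    """Per-group behavioural parameters of the simulator.

    Error probabilities are per-trial category probabilities; exclusion
    probability triples are (fixation_error, amplitude, blink) for the
    pro/antisaccade task and the memory-guided task respectively.
    """

    swj_rate_per_min: float = 1.688
    swj_amp_deg: DistSpec = DistSpec("uniform", 0.3, 1.5)
    swj_isi_ms: DistSpec = DistSpec("uniform", 50.0, 180.0)
    latency_ms: dict = field(default_factory=lambda: {
        Task.PROSACCADE: DistSpec("lognormal", 317.0, 0.2),
        Task.ANTISACCADE: DistSpec("lognormal", 440.0, 0.2),
        Task.MEMORY_GUIDED: DistSpec("lognormal", 690.0, 0.2),
    })
    correction_delay_ms: DistSpec = DistSpec("lognormal", 500.0, 0.25)
    anticipation_prob: float = 0.55
    prosaccade_error_prob: float = 0.003
    antisaccade_uncorrected_prob: float = 0.17
    antisaccade_corrected_prob: float = 0.15
    mg_inhibitory_prob: float = 0.02
    mg_directional_prob: float = 0.011
    gain_mean: float = 0.98
    gain_sd: float = 0.055
    noise_sd_deg: float = 0.05
    blink_rate_per_min: float = 0.5
    main_sequence: tuple = (500.0, 5.0)  # (v_max deg/s, amplitude constant deg)
    excl_probs_saccade: tuple = (0.04429, 0.01427, 0.00162)
    excl_probs_memory: tuple = (0.01638, 0.05629, 0.00524)

    def __post_init__(self) -> None:
        probs = (self.anticipation_prob, self.prosaccade_error_prob,
                 self.antisaccade_uncorrected_prob, self.antisaccade_corrected_prob,
                 self.mg_inhibitory_prob, self.mg_directional_prob,
                 *self.excl_probs_saccade, *self.excl_probs_memory)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.anticipation_prob + self.prosaccade_error_prob > 1.0:
            raise ValueError("prosaccade category probabilities exceed 1")
        if (self.anticipation_prob + self.antisaccade_uncorrected_prob
                + self.antisaccade_corrected_prob) > 1.0:
            raise ValueError("antisaccade category probabilities exceed 1")
        if self.mg_inhibitory_prob + self.mg_directional_prob > 1.0:
            raise ValueError("memory-guided category probabilities exceed 1")
        if self.noise_sd_deg < 0 or self.swj_rate_per_min < 0 or self.blink_rate_per_min < 0:
            raise ValueError("rates and noise sd must be non-negative")

    def peak_velocity(self, amplitude_deg: float) -> float:
        return main_sequence_peak_velocity(amplitude_deg, *self.main_sequence)


# Group-level psychometric locations follow the descriptive scale of the
# study population (young adult women, normal-range BMI).
_CONTROL_PSY = {
    "edeq_restraint": (0.593, 0.514), "edeq_eating": (0.345, 0.362),
    "edeq_shape": (0.841, 0.576), "edeq_weight": (0.434, 0.421),
    "edeq_global": (0.553, 0.310), "stai_state": (49.714, 7.605),
    "stai_trait": (40.607, 11.364), "premorbid_iq": (8.214, 3.425),
    "age": (20.310, 1.417), "bmi": (21.285, 1.578),
}
_SUBCLINICAL_PSY = {
    "edeq_restraint": (2.462, 1.118), "edeq_eating": (1.438, 1.042),
    "edeq_shape": (3.288, 1.256), "edeq_weight": (2.731, 1.243),
    "edeq_global": (2.480, 0.951), "stai_state": (38.880, 9.369),
    "stai_trait": (31.120, 10.764), "premorbid_iq": (8.182, 2.612),
    "age": (20.038, 1.428), "bmi": (21.769, 1.889),
}
_PSY_CLIP = {
    "edeq_restraint": (0, 6), "edeq_eating": (0, 6), "edeq_shape": (0, 6),
    "edeq_weight": (0, 6), "edeq_global": (0, 6), "stai_state": (0, 80),
    "stai_trait": (0, 80), "premorbid_iq": (0, 30), "age": (18, 25),
    "bmi": (18.5, 24.9),
}


@dataclass(frozen=True)
class PsychometricsSpec:
    """Gaussian (mean, sd) per questionnaire field, truncated to each
    instrument's range on sampling."""

    params: dict

    @classmethod
    def control(cls) -> "PsychometricsSpec":
        return cls(dict(_CONTROL_PSY))

    @classmethod
    def subclinical(cls) -> "PsychometricsSpec":
        return cls(dict(_SUBCLINICAL_PSY))

    def sample(self, rng: np.random.Generator) -> Psychometrics:
        vals = {}
        for name, (m, s) in self.params.items():
            lo, hi = _PSY_CLIP[name]
            vals[name] = float(np.clip(rng.normal(m, s), lo, hi))
        vals["premorbid_iq"] = int(round(vals["premorbid_iq"]))
        return Psychometrics(**vals)


@dataclass(frozen=True)
class CohortConfig:
    n_control: int = 26
    n_subclinical: int = 26
    seed: int = 0
    control_profile: BehaviorProfile = field(default_factory=BehaviorProfile)
    subclinical_profile: BehaviorProfile = field(default_factory=BehaviorProfile)
    control_psychometrics: PsychometricsSpec = field(default_factory=PsychometricsSpec.control)
    subclinical_psychometrics: PsychometricsSpec = field(
        default_factory=PsychometricsSpec.subclinical)
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_subclinical < 1:
            raise ValueError("need at least one participant per group")


@dataclass(frozen=True)
class InjectedSaccade:
    kind: str  # primary | correction | anticipation | inhibitory | return | swj_out | swj_ret
    onset_ms: float
    amplitude_deg: float
    duration_ms: float
    peak_velocity_dps: float


@dataclass
class TruthRecord:
    """Ground truth for one simulated trial."""

    category: str            # correct/anticipation/... or 'fixation'
    excluded_as: str | None  # None, 'fixation_error', 'amplitude_threshold', 'blink'
    saccades: list
    swj_count: int = 0
    blink_windows: list = field(default_factory=list)
    latency_ms: float | None = None
    gain: float | None = None


# ---------------------------------------------------------------------------
# schedules

_BLOCKS = [(Task.PROSACCADE, 60), (Task.ANTISACCADE, 40), (Task.ANTISACCADE, 40),
           (Task.ANTISACCADE, 40), (Task.PROSACCADE, 60)]

FIXATION_TRIAL_MS = 60_000.0
TARGET_DISPLAY_MS = 1000.0
MG_FLASH_MS = 50.0
MG_RESPONSE_TAIL_MS = 1500.0


def make_schedule(task, rng) -> list:
    """Trial annotations for one task run.

    ``task`` is 'fixation', 'prosaccade' (the combined five-block
    pro/antisaccade sequence) or 'memory_guided'.  ``rng`` is either a
    ``numpy.random.Generator`` or an integer seed.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    task = Task(task)
    if task is Task.FIXATION:
        return [TrialAnnotation(Task.FIXATION, 0, 0.0, FIXATION_TRIAL_MS)
                for _ in range(3)]
    if task in (Task.PROSACCADE, Task.ANTISACCADE):
        anns = []
        for block_idx, (block_task, n) in enumerate(_BLOCKS):
            for _ in range(n):
                onset = rng.uniform(1000.0, 3000.0)
                side = rng.choice([-1.0, 1.0])
                anns.append(TrialAnnotation(
                    task=block_task, block_index=block_idx,
                    fixation_onset_ms=0.0, target_onset_ms=onset,
                    target_x_deg=8.0 * side,
                    trial_end_ms=onset + TARGET_DISPLAY_MS))
        return anns
    # memory-guided: 13 trials per (side x eccentricity) cell, shuffled
    cells = [s * e for s in (-1.0, 1.0) for e in (5.0, 10.0)]
    targets = np.repeat(cells, 13)
    rng.shuffle(targets)
    anns = []
    for tx in targets:
        onset = rng.uniform(1000.0, 3000.0)
        go = onset + rng.uniform(1000.0, 3000.0)
        anns.append(TrialAnnotation(
            task=Task.MEMORY_GUIDED, block_index=0,
            fixation_onset_ms=0.0, target_onset_ms=onset,
            target_x_deg=float(tx), target_offset_ms=onset + MG_FLASH_MS,
            go_signal_ms=go, trial_end_ms=go + MG_RESPONSE_TAIL_MS))
    return anns


# ---------------------------------------------------------------------------
# trial synthesis


def _displacement_profile(n_samp: int) -> np.ndarray:
    """Normalised raised-cosine-velocity displacement, 0 -> 1 over n_samp."""
    tau = np.linspace(0.0, 1.0, n_samp)
    return tau - np.sin(2.0 * np.pi * tau) / (2.0 * np.pi)


# Hann smoothing kernel (~30 ms), scaled so filtered noise keeps unit
# marginal sd; gives the band-limited noise floor fixed-threshold
# parsers presume.
_NOISE_KERNEL = np.hanning(17)[1:-1]
_NOISE_KERNEL /= math.sqrt(np.sum(_NOISE_KERNEL ** 2))


def _band_limited_noise(rng, sd: float, n: int) -> np.ndarray:
    """Temporally correlated Gaussian position noise with marginal
    standard deviation ``sd``.  Gaze-position noise in video
    oculography is band-limited (tremor plus low-passed sensor noise),
    not white sample to sample; white noise of the same amplitude would
    carry unrealistically large sample-to-sample velocity power."""
    white = rng.normal(0.0, sd, n + _NOISE_KERNEL.size - 1)
    return np.convolve(white, _NOISE_KERNEL, mode="valid")


class _TraceBuilder:
    def __init__(self, trial_end_ms: float, profile: BehaviorProfile,
                 rng: np.random.Generator, rate_hz: float = 500.0):
        self.dt = 1000.0 / rate_hz
        self.t = np.arange(0.0, trial_end_ms, self.dt)
        self.x = np.zeros_like(self.t)
        self.y = np.zeros_like(self.t)
        self.valid = np.ones(self.t.size, dtype=bool)
        self.profile = profile
        self.rng = rng
        self.rate_hz = rate_hz
        self.events: list[InjectedSaccade] = []
        self.blinks: list[tuple] = []

    def saccade(self, kind: str, onset_ms: float, dx: float, dy: float = 0.0):
        """Inject a main-sequence saccade starting at ``onset_ms``;
        gaze stays displaced afterwards.  Returns the injected event."""
        amp = math.hypot(dx, dy)
        vp = self.profile.peak_velocity(amp)
        dur_ms = 2.0 * amp / vp * 1000.0
        # n+1 samples span n*dt ~= dur_ms so the realised peak velocity
        # matches the main-sequence value
        n = max(int(round(dur_ms / self.dt)), 2) + 1
        i0 = int(np.searchsorted(self.t, onset_ms))
        i1 = min(i0 + n, self.t.size)
        prof = _displacement_profile(i1 - i0)
        self.x[i0:i1] += dx * prof
        self.y[i0:i1] += dy * prof
        self.x[i1:] += dx
        self.y[i1:] += dy
        ev = InjectedSaccade(kind, float(self.t[i0]) if i0 < self.t.size else onset_ms,
                             amp, dur_ms, vp)
        self.events.append(ev)
        return ev

    def slow_excursion(self, onset_ms: float, offset_deg: float,
                       ramp_ms: float = 250.0, dwell_ms: float = 350.0):
        """Sub-threshold drift out, dwell, drift back (a fixation error)."""
        n_ramp = max(int(round(ramp_ms / self.dt)), 2)
        i0 = int(np.searchsorted(self.t, onset_ms))
        prof = _displacement_profile(n_ramp)
        i1 = min(i0 + n_ramp, self.t.size)
        self.x[i0:i1] += offset_deg * prof[: i1 - i0]
        i2 = min(int(np.searchsorted(self.t, onset_ms + ramp_ms + dwell_ms)), self.t.size)
        self.x[i1:i2] += offset_deg
        i3 = min(i2 + n_ramp, self.t.size)
        self.x[i2:i3] += offset_deg * prof[::-1][: i3 - i2]

    def blink(self, onset_ms: float, duration_ms: float):
        i0 = int(np.searchsorted(self.t, onset_ms))
        i1 = min(int(np.searchsorted(self.t, onset_ms + duration_ms)), self.t.size)
        if i1 > i0:
            self.valid[i0:i1] = False
            self.blinks.append((float(self.t[i0]), onset_ms + duration_ms))

    def random_blinks(self, avoid_windows=()):
        rate = self.profile.blink_rate_per_min
        if rate <= 0:
            return
        dur_min = (self.t[-1] + self.dt) / 60000.0
        for _ in range(self.rng.poisson(rate * dur_min)):
            onset = self.rng.uniform(0.0, self.t[-1])
            dur = self.rng.uniform(100.0, 300.0)
            if any(lo - dur <= onset <= hi for lo, hi in avoid_windows):
                continue
            self.blink(onset, dur)

    def build(self) -> GazeTrace:
        if self.profile.noise_sd_deg > 0:
            self.x += _band_limited_noise(self.rng, self.profile.noise_sd_deg, self.t.size)
            self.y += _band_limited_noise(self.rng, self.profile.noise_sd_deg, self.t.size)
        x = np.where(self.valid, self.x, np.nan)
        y = np.where(self.valid, self.y, np.nan)
        return GazeTrace(self.t, x, y, self.valid, self.rate_hz)


def _sample_gain(profile: BehaviorProfile, rng) -> float:
    return float(rng.normal(profile.gain_mean, profile.gain_sd))


def _clipped_latency(spec: DistSpec, rng, max_ms: float) -> float:
    """Latency draw truncated to ``max_ms`` (rejection sampling, so no
    point mass at the bound for realistic tail probabilities)."""
    for _ in range(50):
        v = float(spec.sample(rng))
        if v < max_ms:
            return v
    return 0.95 * max_ms


def _simulate_fixation(ann, profile, rng) -> tuple:
    tb = _TraceBuilder(ann.trial_end_ms, profile, rng)
    dur_min = ann.trial_end_ms / 60000.0
    n_swj = rng.poisson(profile.swj_rate_per_min * dur_min)
    # Poisson count, placed with >= 1 s separation (rejection sampling)
    # so consecutive SWJ pairs never interleave
    lo, hi = 500.0, ann.trial_end_ms - 1000.0
    kept = []
    for _ in range(200):
        times = np.sort(rng.uniform(lo, hi, n_swj))
        if n_swj < 2 or np.diff(times).min() >= 1000.0:
            kept = [float(t) for t in times]
            break
    else:  # dense regime: jittered regular grid keeps the exact count
        slots = np.linspace(lo, hi, n_swj, endpoint=False)
        jitter = max(0.0, (hi - lo) / n_swj - 1000.0)
        kept = [float(s + rng.uniform(0.0, jitter)) for s in slots]
    for t0 in kept:
        amp = float(profile.swj_amp_deg.sample(rng))
        side = rng.choice([-1.0, 1.0])
        out = tb.saccade("swj_out", t0, side * amp)
        isi = float(profile.swj_isi_ms.sample(rng))
        ret_amp = amp + float(rng.normal(0.0, 0.05))
        tb.saccade("swj_ret", t0 + out.duration_ms + isi, -side * ret_amp)
    tb.random_blinks(avoid_windows=[(t - 100.0, t + 700.0) for t in kept])
    truth = TruthRecord("fixation", None, tb.events, swj_count=len(kept),
                        blink_windows=tb.blinks)
    return tb.build(), truth


def _simulate_saccade_task(ann, profile, rng) -> tuple:
    tb = _TraceBuilder(ann.trial_end_ms, profile, rng)
    target = ann.target_x_deg
    onset = ann.target_onset_ms
    window_end = ann.trial_end_ms
    gain = _sample_gain(profile, rng)
    lat_spec = profile.latency_ms[ann.task]

    pf, pa, pb = profile.excl_probs_saccade
    u = rng.uniform()
    excluded_as = None
    category = None
    latency = None

    if u < pf:
        excluded_as = "fixation_error"
        tb.slow_excursion(ann.fixation_onset_ms + 100.0, rng.choice([-1.0, 1.0]) * 2.8)
        latency = _clipped_latency(lat_spec, rng, window_end - onset - 120.0)
        tb.saccade("primary", onset + latency, target * gain)
    elif u < pf + pa:
        excluded_as = "amplitude_threshold"
        latency = _clipped_latency(lat_spec, rng, window_end - onset - 200.0)
        tb.saccade("primary", onset + latency, target * rng.uniform(2.2, 2.6))
    elif u < pf + pa + pb:
        excluded_as = "blink"
        tb.blink(onset - 50.0, rng.uniform(150.0, 250.0))
        latency = _clipped_latency(lat_spec, rng, window_end - onset - 120.0)
        tb.saccade("primary", onset + latency, target * gain)

    if excluded_as is not None:
        category = "correct"  # behaviour behind the exclusion; not scored
        tb.random_blinks(avoid_windows=[(onset - 200.0, window_end)])
        truth = TruthRecord(category, excluded_as, tb.events,
                            blink_windows=tb.blinks, latency_ms=latency, gain=gain)
        return tb.build(), truth

    v = rng.uniform()
    if ann.task is Task.PROSACCADE:
        if v < profile.anticipation_prob:
            category = "anticipation"
        elif v < profile.anticipation_prob + profile.prosaccade_error_prob:
            category = "prosaccade_error"
        else:
            category = "correct"
    else:
        p_ant = profile.anticipation_prob
        p_unc = profile.antisaccade_uncorrected_prob
        p_cor = profile.antisaccade_corrected_prob
        if v < p_ant:
            category = "anticipation"
        elif v < p_ant + p_unc:
            category = "uncorrected_error"
        elif v < p_ant + p_unc + p_cor:
            category = "corrected_error"
        else:
            category = "correct"

    if category == "anticipation":
        t_ant = rng.uniform(ann.fixation_onset_ms + 250.0, onset + 60.0)
        side = rng.choice([-1.0, 1.0])
        tb.saccade("anticipation", t_ant, side * 8.0 * gain)
        latency = t_ant - onset
    elif category == "prosaccade_error":
        latency = _clipped_latency(lat_spec, rng, window_end - onset - 120.0)
        tb.saccade("primary", onset + latency, -target * gain)
    elif category == "uncorrected_error":
        latency = _clipped_latency(lat_spec, rng, window_end - onset - 120.0)
        tb.saccade("primary", onset + latency, target * gain)
    elif category == "corrected_error":
        latency = _clipped_latency(lat_spec, rng, window_end - onset - 700.0)
        prim = tb.saccade("primary", onset + latency, target * gain)
        delay = _clipped_latency(profile.correction_delay_ms, rng,
                                 window_end - (onset + latency + prim.duration_ms) - 120.0)
        tb.saccade("correction", prim.onset_ms + prim.duration_ms + delay,
                   -target * gain * 2.0)
    else:  # correct
        latency = _clipped_latency(lat_spec, rng, window_end - onset - 120.0)
        landing = target * gain if ann.task is Task.PROSACCADE else -target * gain
        tb.saccade("primary", onset + latency, landing)

    tb.random_blinks(avoid_windows=[(onset - 200.0, window_end)])
    truth = TruthRecord(category, None, tb.events, blink_windows=tb.blinks,
                        latency_ms=latency, gain=gain)
    return tb.build(), truth


# compliant participants respond inside the 1000 ms response period;
# leave margin for detector onset lag
MG_MAX_LATENCY_MS = 920.0


def _simulate_memory_guided(ann, profile, rng) -> tuple:
    tb = _TraceBuilder(ann.trial_end_ms, profile, rng)
    target = ann.target_x_deg
    go = ann.go_signal_ms
    gain = _sample_gain(profile, rng)
    lat_spec = profile.latency_ms[Task.MEMORY_GUIDED]
    window_end = ann.trial_end_ms

    pf, pa, pb = profile.excl_probs_memory
    u = rng.uniform()
    excluded_as = None
    latency = None
    if u < pf:
        excluded_as = "fixation_error"
        tb.slow_excursion(ann.fixation_onset_ms + 100.0, rng.choice([-1.0, 1.0]) * 2.8)
        latency = _clipped_latency(lat_spec, rng, min(window_end - go - 120.0, MG_MAX_LATENCY_MS))
        tb.saccade("primary", go + latency, target * gain)
    elif u < pf + pa:
        excluded_as = "amplitude_threshold"
        latency = _clipped_latency(lat_spec, rng, window_end - go - 250.0)
        tb.saccade("primary", go + latency, target * rng.uniform(2.2, 2.6))
    elif u < pf + pa + pb:
        excluded_as = "blink"
        tb.blink(ann.target_onset_ms + rng.uniform(0.0, go - ann.target_onset_ms - 300.0),
                 rng.uniform(150.0, 250.0))
        latency = _clipped_latency(lat_spec, rng, min(window_end - go - 120.0, MG_MAX_LATENCY_MS))
        tb.saccade("primary", go + latency, target * gain)

    if excluded_as is not None:
        tb.random_blinks(avoid_windows=[(ann.target_onset_ms - 200.0, window_end)])
        truth = TruthRecord("correct", excluded_as, tb.events,
                            blink_windows=tb.blinks, latency_ms=latency, gain=gain)
        return tb.build(), truth

    v = rng.uniform()
    if v < profile.mg_inhibitory_prob:
        category = "inhibitory_error"
        t_inh = ann.target_onset_ms + rng.uniform(150.0, 600.0)
        inh = tb.saccade("inhibitory", t_inh, target * gain)
        tb.saccade("return", t_inh + inh.duration_ms + rng.uniform(250.0, 450.0),
                   -target * gain)
        latency = _clipped_latency(lat_spec, rng, min(window_end - go - 120.0, MG_MAX_LATENCY_MS))
        tb.saccade("primary", go + latency, target * gain)
    elif v < profile.mg_inhibitory_prob + profile.mg_directional_prob:
        category = "directional_error"
        latency = _clipped_latency(lat_spec, rng, min(window_end - go - 120.0, MG_MAX_LATENCY_MS))
        tb.saccade("primary", go + latency, -target * gain)
    else:
        category = "correct"
        latency = _clipped_latency(lat_spec, rng, min(window_end - go - 120.0, MG_MAX_LATENCY_MS))
        tb.saccade("primary", go + latency, target * gain)

    tb.random_blinks(avoid_windows=[(ann.target_onset_ms - 200.0, window_end)])
    truth = TruthRecord(category, None, tb.events, blink_windows=tb.blinks,
                        latency_ms=latency, gain=gain)
    return tb.build(), truth


def simulate_trial(ann: TrialAnnotation, profile: BehaviorProfile,
                   geom: ScreenGeometry | None = None, rng=None):
    """Simulate one trial.  Returns ``(GazeTrace, TruthRecord)``.

    ``rng`` is a ``numpy.random.Generator`` or an integer seed.  ``geom``
    is accepted for interface symmetry (positions are generated directly
    in degrees and must stay on screen for valid trials).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if ann.task is Task.FIXATION:
        return _simulate_fixation(ann, profile, rng)
    if ann.task in (Task.PROSACCADE, Task.ANTISACCADE):
        return _simulate_saccade_task(ann, profile, rng)
    return _simulate_memory_guided(ann, profile, rng)


def simulate_recording(participant_id: str, group: str, profile: BehaviorProfile,
                       psychometrics_spec: PsychometricsSpec,
                       geom: ScreenGeometry, rng) -> tuple:
    """One participant's full battery.  Returns ``(Recording, truths)``
    where ``truths`` is a list parallel to ``Recording.trials``."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    anns = (make_schedule(Task.FIXATION, rng)
            + make_schedule(Task.PROSACCADE, rng)
            + make_schedule(Task.MEMORY_GUIDED, rng))
    trials, truths = [], []
    for ann in anns:
        trace, truth = simulate_trial(ann, profile, geom, rng)
        trials.append((ann, trace))
        truths.append(truth)
    psych = psychometrics_spec.sample(rng)
    rec = Recording(participant_id, group, geom, trials, psych)
    return rec, truths


def simulate_cohort(cfg: CohortConfig):
    """Simulate a two-group cohort.

    Returns ``(recordings, truths)``: a list of :class:`Recording` and a
    dict participant_id -> list of :class:`TruthRecord`.  Each
    participant uses an RNG stream derived from ``(cfg.seed, index)``,
    so output is reproducible and independent of generation order.
    """
    recordings, truths = [], {}
    specs = ([("control", cfg.control_profile, cfg.control_psychometrics)]
             * cfg.n_control
             + [("subclinical", cfg.subclinical_profile, cfg.subclinical_psychometrics)]
             * cfg.n_subclinical)
    for idx, (group, profile, psy) in enumerate(specs):
        pid = f"{'C' if group == 'control' else 'S'}{idx:03d}"
        rng = np.random.default_rng([cfg.seed, idx])
        rec, tr = simulate_recording(pid, group, profile, psy, cfg.geometry, rng)
        recordings.append(rec)
        truths[pid] = tr
    return recordings, truths


# ---------------------------------------------------------------------------
# outcome-level cohort sampler

# (kind, p1, p2): normal outcomes are (mean, sd); rate outcomes are
# binomial counts over n trials, (p, n_trials), reproducing the
# granularity of real per-participant proportions (including
# zero-variance outcomes when p*n is tiny).  Locations follow the
# control-group scale of the emulated study battery.
OUTCOME_DISTRIBUTIONS = {
    "swj_rate_per_min": ("poisson_rate", 1.688, 3.0),  # (rate/min, minutes analysed)
    "pro_gain": ("normal", 0.981, 0.055),
    "pro_latency_ms": ("normal", 317.090, 62.814),
    "pro_peak_velocity_dps": ("normal", 303.453, 45.338),
    "pro_anticipation_rate": ("binomial_rate", 0.569, 113),
    "pro_error_rate": ("binomial_rate", 0.003, 113),
    "anti_gain": ("normal", 1.046, 0.230),
    "anti_latency_ms": ("normal", 437.953, 100.787),
    "anti_peak_velocity_dps": ("normal", 281.549, 55.053),
    "anti_anticipation_rate": ("binomial_rate", 0.342, 113),
    "anti_uncorrected_rate": ("binomial_rate", 0.169, 113),
    "anti_corrected_rate": ("binomial_rate", 0.144, 113),
    "anti_correction_latency_ms": ("normal", 540.904, 165.400),
    "mg_gain_5": ("normal", 0.962, 0.413),
    "mg_gain_10": ("normal", 0.954, 0.131),
    "mg_latency_5_ms": ("normal", 705.859, 199.840),
    "mg_latency_10_ms": ("normal", 674.987, 162.821),
    "mg_peak_velocity_5_dps": ("normal", 210.309, 42.224),
    "mg_peak_velocity_10_dps": ("normal", 278.263, 58.723),
    "mg_inhibitory_5": ("binomial_rate", 0.001, 24),
    "mg_inhibitory_10": ("binomial_rate", 0.023, 24),
    "mg_directional_5": ("binomial_rate", 0.010, 24),
    "mg_directional_10": ("binomial_rate", 0.011, 24),
}


def _sample_outcome(rng, kind, p1, p2, size):
    if kind == "normal":
        return rng.normal(p1, p2, size)
    if kind == "binomial_rate":
        return rng.binomial(int(p2), p1, size) / float(p2)
    if kind == "poisson_rate":
        return rng.poisson(p1 * p2, size) / p2
    raise ValueError(f"unknown outcome distribution kind {kind!r}")


def simulate_outcome_rows(n_control: int, n_subclinical: int, rng=None,
                          control_dists=None, subclinical_dists=None) -> pd.DataFrame:
    """Draw participant outcome rows directly at the outcome level.

    Far cheaper than trace-level simulation; used for null-calibration
    studies of the comparison stage.  With both distribution dicts left
    at the defaults the two groups are exchangeable (a null cohort).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    control_dists = control_dists or OUTCOME_DISTRIBUTIONS
    subclinical_dists = subclinical_dists or OUTCOME_DISTRIBUTIONS
    frames = []
    for group, n, dists in (("control", n_control, control_dists),
                            ("subclinical", n_subclinical, subclinical_dists)):
        cols = {"participant_id": [f"{group[0].upper()}{i:03d}" for i in range(n)],
                "group": group}
        for name, (kind, p1, p2) in dists.items():
            cols[name] = _sample_outcome(rng, kind, p1, p2, n)
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


def truth_table(recordings, truths) -> pd.DataFrame:
    """Flatten per-trial ground truth into a tidy table (one row per trial)."""
    rows = []
    for rec in recordings:
        for i, ((ann, _), truth) in enumerate(zip(rec.trials, truths[rec.participant_id])):
            rows.append({
                "participant_id": rec.participant_id,
                "group": rec.group,
                "trial_index": i,
                "task": ann.task.value,
                "target_x_deg": ann.target_x_deg,
                "category": truth.category,
                "excluded_as": truth.excluded_as,
                "swj_count": truth.swj_count,
                "latency_ms": truth.latency_ms,
                "gain": truth.gain,
            })
    return pd.DataFrame(rows)
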