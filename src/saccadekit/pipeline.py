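"""End-to-end drivers: recording -> events -> trial scores -> outcome row."""

from __future__ import annotations

import dataclasses

import pandas as pd

from .events import detect_blinks, detect_saccades, detect_swjs, swj_rate
from .geometry import Recording, Task
from .io import RunConfig
from .scoring import aggregate_outcomes, score_trial

__all__ = ["detect_events", "score_recording", "outcomes_table", "events_table"]


def detect_events(recording: Recording, config: RunConfig | None = None):
    """Detect saccades and blinks for every trial, and SWJs on the
    fixation trials.  Returns ``(per_trial, swjs, fixation_ms)`` where
    ``per_trial`` is a list of (saccades, blinks) parallel to
    ``recording.trials``."""
    config = config or RunConfig()
    per_trial = []
    swjs = []
    fixation_ms = 0.0
    for ann, trace in recording.trials:
        blinks = detect_blinks(trace)
        saccades = detect_saccades(trace, config.detection, blinks)
        per_trial.append((saccades, blinks))
        if ann.task is Task.FIXATION:
            swjs.extend(detect_swjs(saccades, (0.0, 0.0), config.detection))
            fixation_ms += trace.t_ms[-1] - trace.t_ms[0] + 1000.0 / trace.nominal_rate_hz
    return per_trial, swjs, fixation_ms


def score_recording(recording: Recording, config: RunConfig | None = None):
    """Score one participant.  Returns ``(outcome_row_dict, scored)``
    with ``scored`` the list of (annotation, TrialScore) task trials."""
    config = config or RunConfig()
    per_trial, swjs, fixation_ms = detect_events(recording, config)
    scored = []
    for (ann, trace), (saccades, blinks) in zip(recording.trials, per_trial):
        if ann.task is Task.FIXATION:
            continue
        scored.append((ann, score_trial(trace, ann, config.scoring,
                                        config.detection, recording.geometry,
                                        saccades=saccades, blinks=blinks)))
    rate = swj_rate(swjs, fixation_ms) if fixation_ms > 0 else float("nan")
    row = aggregate_outcomes(recording.participant_id, recording.group, scored,
                             rate, recording.psychometrics)
    return row, scored


def outcomes_table(recordings, config: RunConfig | None = None) -> pd.DataFrame:
    """Participant-by-outcome table for a cohort."""
    return pd.DataFrame([score_recording(r, config)[0] for r in recordings])


def events_table(recording: Recording, config: RunConfig | None = None) -> pd.DataFrame:
    """All detected events of one recording as a tidy table."""
    per_trial, _, _ = detect_events(recording, config)
    rows = []
    for idx, ((ann, _), (saccades, blinks)) in enumerate(zip(recording.trials, per_trial)):
        for s in saccades:
            rows.append({"trial_index": idx, "task": ann.task.value, "kind": "saccade",
                         **dataclasses.asdict(s)})
        for b in blinks:
            rows.append({"trial_index": idx, "task": ann.task.value, "kind": "blink",
                         "onset_ms": b.onset_ms, "offset_ms": b.offset_ms})
    return pd.DataFrame(rows)
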