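"""File formats: gaze CSV, annotations JSON, result TSVs, YAML config.

The gaze format is a plain CSV with ``#``-prefixed header lines::

    # saccadekit-gaze v1
    # participant_id=P001
    # nominal_rate_hz=500
    # eye_reduction=mean
    # geometry=1920,1080,53.136,29.889,90.0
    trial_index,t_ms,x_deg,y_deg,valid

Positions may alternatively be given as ``x_px,y_px`` (screen pixels,
origin top-left); they are converted to degrees on read using the
header geometry.  Annotations (task, timing, targets), group label and
psychometrics live in a sidecar JSON.  Missing values in result TSVs
are empty fields, never sentinel numbers (a rate of 0 is meaningful).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .events import DetectionParams
from .geometry import (
    GazeTrace,
    Psychometrics,
    Recording,
    ScreenGeometry,
    Task,
    TrialAnnotation,
    px_to_deg,
)
from .scoring import ScoringParams

__all__ = [
    "FORMAT_VERSION",
    "GazeFileError",
    "RunConfig",
    "write_gaze_csv",
    "read_gaze_csv",
    "write_annotations_json",
    "read_annotations_json",
    "write_recording",
    "read_recording",
    "write_table",
    "comparison_table",
]

FORMAT_VERSION = 1


class GazeFileError(ValueError):
    """Malformed gaze or annotation file (message carries location)."""


# ---------------------------------------------------------------------------
# gaze CSV


def write_gaze_csv(recording: Recording, path, eye_reduction: str = "mean") -> None:
    path = Path(path)
    g = recording.geometry
    with open(path, "w") as fh:
        fh.write(f"# saccadekit-gaze v{FORMAT_VERSION}\n")
        fh.write(f"# participant_id={recording.participant_id}\n")
        rate = recording.trials[0][1].nominal_rate_hz if recording.trials else 500.0
        fh.write(f"# nominal_rate_hz={rate:g}\n")
        fh.write(f"# eye_reduction={eye_reduction}\n")
        fh.write(f"# geometry={g.width_px},{g.height_px},{g.width_cm:g},"
                 f"{g.height_cm:g},{g.distance_cm:g}\n")
        fh.write("trial_index,t_ms,x_deg,y_deg,valid\n")
        for idx, (_, trace) in enumerate(recording.trials):
            for t, x, y, v in zip(trace.t_ms, trace.x_deg, trace.y_deg, trace.valid):
                xs = f"{x:.6f}" if np.isfinite(x) else ""
                ys = f"{y:.6f}" if np.isfinite(y) else ""
                fh.write(f"{idx},{t:.6f},{xs},{ys},{int(v)}\n")


def _parse_header(lines):
    header = {}
    n = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n += 1
        body = line[1:].strip()
        if body.startswith("saccadekit-gaze"):
            version = body.split("v")[-1]
            if version != str(FORMAT_VERSION):
                raise GazeFileError(f"unknown gaze format version {version!r}")
            header["version"] = int(version)
        elif "=" in body:
            k, v = body.split("=", 1)
            header[k.strip()] = v.strip()
    if "version" not in header:
        raise GazeFileError("missing '# saccadekit-gaze v1' header line")
    return header, n


def read_gaze_csv(path):
    """Read a gaze CSV into ``(header_dict, {trial_index: GazeTrace})``.

    Validates monotone timestamps per trial; errors report 1-based file
    line numbers.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    header, n_header = _parse_header(lines)
    rate = float(header.get("nominal_rate_hz", 500.0))
    if rate <= 0:
        raise GazeFileError("nominal_rate_hz must be positive")
    df = pd.read_csv(path, comment="#")
    required_deg = {"trial_index", "t_ms", "x_deg", "y_deg", "valid"}
    required_px = {"trial_index", "t_ms", "x_px", "y_px", "valid"}
    cols = set(df.columns)
    if required_deg <= cols:
        pixel = False
    elif required_px <= cols:
        pixel = True
        if "geometry" not in header:
            raise GazeFileError("pixel-coordinate file requires a geometry header")
    else:
        missing = sorted(required_deg - cols)
        raise GazeFileError(f"missing column(s): {', '.join(missing)}")

    geom = None
    if "geometry" in header:
        parts = header["geometry"].split(",")
        if len(parts) != 5:
            raise GazeFileError("geometry header must have 5 comma-separated fields")
        geom = ScreenGeometry(int(parts[0]), int(parts[1]), float(parts[2]),
                              float(parts[3]), float(parts[4]))

    traces = {}
    # data row i sits at file line n_header + 2 + i (1-based; +1 column row)
    line0 = n_header + 2
    for idx, sub in df.groupby("trial_index", sort=True):
        t = sub["t_ms"].to_numpy(dtype=float)
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            line = line0 + int(sub.index[bad[0] + 1])
            raise GazeFileError(
                f"t_ms not strictly increasing in trial {idx} at line {line}")
        valid = sub["valid"].to_numpy(dtype=float).astype(bool)
        if pixel:
            x, y = px_to_deg(sub["x_px"].fillna(0.0).to_numpy(dtype=float),
                             sub["y_px"].fillna(0.0).to_numpy(dtype=float), geom)
            x = np.where(valid, x, np.nan)
            y = np.where(valid, y, np.nan)
        else:
            x = sub["x_deg"].to_numpy(dtype=float)
            y = sub["y_deg"].to_numpy(dtype=float)
        traces[int(idx)] = GazeTrace(t, x, y, valid, rate)
    header["geometry_obj"] = geom
    return header, traces


# ---------------------------------------------------------------------------
# annotations JSON

_ANN_FIELDS = ("task", "block_index", "fixation_onset_ms", "trial_end_ms",
               "target_onset_ms", "target_x_deg", "target_offset_ms",
               "go_signal_ms")


def write_annotations_json(recording: Recording, path) -> None:
    g = recording.geometry
    doc = {
        "format_version": FORMAT_VERSION,
        "participant_id": recording.participant_id,
        "group": recording.group,
        "geometry": {"width_px": g.width_px, "height_px": g.height_px,
                     "width_cm": g.width_cm, "height_cm": g.height_cm,
                     "distance_cm": g.distance_cm},
        "psychometrics": (dataclasses.asdict(recording.psychometrics)
                          if recording.psychometrics is not None else None),
        "trials": [],
    }
    for ann, _ in recording.trials:
        d = {k: getattr(ann, k) for k in _ANN_FIELDS}
        d["task"] = ann.task.value
        doc["trials"].append({k: v for k, v in d.items() if v is not None})
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_annotations_json(path):
    """Read an annotation file; returns the parsed document with
    ``trials`` as validated :class:`TrialAnnotation` objects.  Schema
    violations raise :class:`GazeFileError` with a JSON pointer."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != FORMAT_VERSION:
        raise GazeFileError("/format_version: unrecognised value")
    for key in ("participant_id", "group", "trials"):
        if key not in doc:
            raise GazeFileError(f"/{key}: required field missing")
    anns = []
    for i, td in enumerate(doc["trials"]):
        unknown = set(td) - set(_ANN_FIELDS)
        if unknown:
            raise GazeFileError(f"/trials/{i}: unknown field(s) {sorted(unknown)}")
        try:
            anns.append(TrialAnnotation(**td))
        except (ValueError, TypeError) as exc:
            raise GazeFileError(f"/trials/{i}: {exc}") from exc
    doc["trials"] = anns
    if doc.get("geometry") is not None:
        doc["geometry"] = ScreenGeometry(**doc["geometry"])
    if doc.get("psychometrics") is not None:
        try:
            doc["psychometrics"] = Psychometrics(**doc["psychometrics"])
        except (ValueError, TypeError) as exc:
            raise GazeFileError(f"/psychometrics: {exc}") from exc
    return doc


# ---------------------------------------------------------------------------
# recordings


def write_recording(recording: Recording, out_dir) -> tuple:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gaze = out_dir / f"{recording.participant_id}_gaze.csv"
    ann = out_dir / f"{recording.participant_id}_annotations.json"
    write_gaze_csv(recording, gaze)
    write_annotations_json(recording, ann)
    return gaze, ann


def read_recording(gaze_path, annotations_path, complete: bool | None = None) -> Recording:
    header, traces = read_gaze_csv(gaze_path)
    doc = read_annotations_json(annotations_path)
    if header.get("participant_id") != doc["participant_id"]:
        raise GazeFileError("participant_id differs between gaze and annotation files")
    anns = doc["trials"]
    if set(traces) != set(range(len(anns))):
        raise GazeFileError("trial indices in gaze file do not match annotations")
    trials = [(anns[i], traces[i]) for i in range(len(anns))]
    geom = doc.get("geometry") or header.get("geometry_obj") or ScreenGeometry()
    if complete is None:
        n_sac = sum(1 for a in anns if a.task in (Task.PROSACCADE, Task.ANTISACCADE))
        complete = len(anns) == 295 and n_sac == 240
    return Recording(doc["participant_id"], doc["group"], geom, trials,
                     doc.get("psychometrics"), complete=complete)


# ---------------------------------------------------------------------------
# result tables and config


def write_table(df: pd.DataFrame, path) -> None:
    """TSV with empty fields for missing values."""
    df.to_csv(path, sep="\t", index=False, na_rep="")


def comparison_table(results) -> pd.DataFrame:
    """Comparison results as a table mirroring the outcome-summary
    layout (group means/SDs, test, statistic, raw/adjusted p, effect)."""
    return pd.DataFrame([dataclasses.asdict(r) for r in results])


@dataclasses.dataclass
class StatsConfig:
    alpha: float = 0.05
    bh_q: float = 0.05
    shapiro_alpha: float = 0.05
    mahalanobis_alpha: float = 0.001

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"StatsConfig.{name} must lie in (0, 1)")


@dataclasses.dataclass
class RunConfig:
    """Bundled pipeline configuration with the battery's defaults."""

    detection: DetectionParams = dataclasses.field(default_factory=DetectionParams)
    scoring: ScoringParams = dataclasses.field(default_factory=ScoringParams)
    stats: StatsConfig = dataclasses.field(default_factory=StatsConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {"detection", "scoring", "stats", "seed"}
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        return cls(
            detection=DetectionParams(**raw.get("detection", {})),
            scoring=ScoringParams(**raw.get("scoring", {})),
            stats=StatsConfig(**raw.get("stats", {})),
            seed=int(raw.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        doc = {"detection": dataclasses.asdict(self.detection),
               "scoring": dataclasses.asdict(self.scoring),
               "stats": dataclasses.asdict(self.stats),
               "seed": self.seed}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    def digest(self) -> str:
        doc = {"detection": dataclasses.asdict(self.detection),
               "scoring": dataclasses.asdict(self.scoring),
               "stats": dataclasses.asdict(self.stats),
               "seed": self.seed}
        return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:12]
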