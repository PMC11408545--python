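"""Readers and writers for the plain-text interchange formats.

Kinematic CSV: ``# units: time=s, position=cm`` header comment, then
columns ``time,x,y,z[,ex,ey,ez]``.  Force CSV: ``# units: time=s,
force=N`` then ``time,thumb,index,middle``.  Segment annotations are a
JSON object ``{"S1": [k0, kf], ...}`` with half-open 0-based windows on
the kinematic timeline.  A trial manifest JSON binds the five files plus
subject metadata.  Readers reject files whose units are not declared.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    FINGERS,
    SEGMENT_IDS,
    ForceTrace,
    FormatError,
    Group,
    GroupComparisonResult,
    Hand,
    Instrument,
    KinematicTrace,
    MetricValue,
    SegmentAnnotation,
    TrialRecording,
    ValidationError,
)

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"  # round-trips doubles well under the 1e-9 contract


def _read_header_units(path: Path) -> dict[str, str]:
    units: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if body.lower().startswith("units:"):
                for part in body[len("units:"):].split(","):
                    if "=" in part:
                        key, val = part.split("=", 1)
                        units[key.strip()] = val.strip()
    return units


def _infer_rate(timestamps: np.ndarray, nominal: float | None) -> float:
    if nominal is not None:
        return float(nominal)
    dt = np.median(np.diff(timestamps))
    if dt <= 0:
        raise ValidationError("cannot infer sample rate from non-increasing timestamps")
    return 1.0 / float(dt)


def read_kinematic_csv(
    path, instrument: Instrument | str, sample_rate: float | None = None
) -> KinematicTrace:
    """Load a tool-tip pose CSV.

    Rows whose coordinates are missing (NaN) are flagged as gaps for the
    preprocessing stage rather than silently filled.  The declared units
    must be seconds and centimetres.
    """
    path = Path(path)
    units = _read_header_units(path)
    if units.get("time") != "s" or units.get("position") != "cm":
        raise FormatError(
            f"{path}: units not declared as time=s, position=cm "
            f"(found {units or 'no units header'})"
        )
    df = pd.read_csv(path, comment="#")
    required = ["time", "x", "y", "z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    t = df["time"].to_numpy(dtype=float)
    pos = df[["x", "y", "z"]].to_numpy(dtype=float)
    orient = None
    if {"ex", "ey", "ez"}.issubset(df.columns):
        orient = df[["ex", "ey", "ez"]].to_numpy(dtype=float)
    gaps = np.nonzero(~np.isfinite(pos).all(axis=1))[0]
    return KinematicTrace(
        instrument=Instrument(instrument),
        sample_rate=_infer_rate(t, sample_rate),
        timestamps=t,
        positions=pos,
        orientations=orient,
        gap_indices=gaps,
    )


def write_kinematic_csv(trace: KinematicTrace, path) -> None:
    path = Path(path)
    cols = {"time": trace.timestamps}
    for i, c in enumerate("xyz"):
        cols[c] = trace.positions[:, i]
    if trace.orientations is not None:
        for i, c in enumerate(["ex", "ey", "ez"]):
            cols[c] = trace.orientations[:, i]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write("# units: time=s, position=cm\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_force_csv(path, hand: Hand | str, sample_rate: float | None = None) -> ForceTrace:
    """Load a per-finger force CSV; negative readings are clipped to 0 N.

    The number of clipped samples is stored on the trace and logged.
    """
    path = Path(path)
    units = _read_header_units(path)
    if units.get("time") != "s" or units.get("force") != "N":
        raise FormatError(
            f"{path}: units not declared as time=s, force=N "
            f"(found {units or 'no units header'})"
        )
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("time", *FINGERS) if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    t = df["time"].to_numpy(dtype=float)
    channels = {}
    n_clipped = 0
    for finger in FINGERS:
        arr = df[finger].to_numpy(dtype=float)
        neg = arr < 0
        n_clipped += int(neg.sum())
        channels[finger] = np.where(neg, 0.0, arr)
    if n_clipped:
        log.warning("%s: clipped %d negative force samples to 0 N", path, n_clipped)
    return ForceTrace(
        hand=Hand(hand),
        sample_rate=_infer_rate(t, sample_rate),
        timestamps=t,
        channels=channels,
        n_clipped=n_clipped,
    )


def write_force_csv(trace: ForceTrace, path) -> None:
    path = Path(path)
    df = pd.DataFrame({"time": trace.timestamps, **trace.channels})
    with open(path, "w") as fh:
        fh.write("# units: time=s, force=N\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_segments(path, trace: KinematicTrace) -> list[SegmentAnnotation]:
    """Load the four S1..S4 windows and validate them against a trace."""
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict) or sorted(raw) != list(SEGMENT_IDS):
        raise FormatError(
            f"{path}: expected exactly keys {list(SEGMENT_IDS)}, got {sorted(raw)}"
        )
    segments = []
    for sid in SEGMENT_IDS:
        window = raw[sid]
        if not (isinstance(window, list) and len(window) == 2):
            raise FormatError(f"{path}: {sid} must be a [k0, kf] pair")
        segments.append(SegmentAnnotation.from_indices(sid, window[0], window[1], trace))
    from .datatypes import validate_segment_set

    return validate_segment_set(segments)


def write_segments(segments: list[SegmentAnnotation], path) -> None:
    payload = {s.segment_id: [s.k0, s.kf] for s in segments}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# trial manifest

_TRIAL_FILES = {
    "left_kin": "left_kinematics.csv",
    "right_kin": "right_kinematics.csv",
    "left_force": "left_force.csv",
    "right_force": "right_force.csv",
    "segments": "segments.json",
}


def write_trial(trial: TrialRecording, directory) -> Path:
    """Write one trial's five data files plus its manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_kinematic_csv(trial.left_kin, directory / _TRIAL_FILES["left_kin"])
    write_kinematic_csv(trial.right_kin, directory / _TRIAL_FILES["right_kin"])
    if trial.left_force is not None:
        write_force_csv(trial.left_force, directory / _TRIAL_FILES["left_force"])
    if trial.right_force is not None:
        write_force_csv(trial.right_force, directory / _TRIAL_FILES["right_force"])
    write_segments(trial.segments, directory / _TRIAL_FILES["segments"])
    manifest = {
        "subject_id": trial.subject_id,
        "group": trial.group.value,
        "ali_score": trial.ali_score,
        "trial_index": trial.trial_index,
        "files": dict(_TRIAL_FILES),
    }
    manifest_path = directory / "trial.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return manifest_path


def read_trial(manifest_path) -> TrialRecording:
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = manifest_path.parent
    files = manifest["files"]
    left_kin = read_kinematic_csv(base / files["left_kin"], Instrument.LEFT_TWEEZERS)
    right_kin = read_kinematic_csv(
        base / files["right_kin"], Instrument.RIGHT_NEEDLE_HOLDER
    )
    def _force(key: str, hand: Hand) -> ForceTrace | None:
        fpath = base / files[key]
        if not fpath.exists():
            log.warning("%s: force file %s missing; tactile metrics will be NaN",
                        manifest_path, fpath.name)
            return None
        return read_force_csv(fpath, hand)

    left_force = _force("left_force", Hand.LEFT)
    right_force = _force("right_force", Hand.RIGHT)
    segments = read_segments(base / files["segments"], left_kin)
    return TrialRecording(
        subject_id=manifest["subject_id"],
        group=Group(manifest["group"]),
        ali_score=manifest.get("ali_score"),
        trial_index=int(manifest["trial_index"]),
        left_kin=left_kin,
        right_kin=right_kin,
        left_force=left_force,
        right_force=right_force,
        segments=segments,
    )


# ---------------------------------------------------------------------------
# result tables

_METRIC_COLS = ["subject_id", "group", "trial_index", "segment", "metric", "scope", "value"]


def metric_values_to_frame(values: list[MetricValue]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": v.subject_id,
            "group": v.group.value,
            "trial_index": v.trial_index,
            "segment": v.segment_id,
            "metric": v.metric,
            "scope": v.scope,
            "value": v.value,
        }
        for v in values
    ]
    return pd.DataFrame(rows, columns=_METRIC_COLS)


def write_metric_table(values: list[MetricValue] | pd.DataFrame, path) -> None:
    df = values if isinstance(values, pd.DataFrame) else metric_values_to_frame(values)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_metric_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _METRIC_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: metric table missing columns {missing}")
    return df


_COMPARISON_COLS = [
    "metric",
    "scope",
    "segment",
    "n_novice",
    "n_intermediate",
    "excluded_novice",
    "excluded_intermediate",
    "median_novice",
    "iqr_novice",
    "median_intermediate",
    "iqr_intermediate",
    "normal_novice",
    "normal_intermediate",
    "test",
    "statistic",
    "df",
    "p_value",
    "significant",
]


def comparison_results_to_frame(results: list[GroupComparisonResult]) -> pd.DataFrame:
    rows = [
        {
            "metric": r.metric,
            "scope": r.scope,
            "segment": r.segment_id,
            "n_novice": r.n_novice,
            "n_intermediate": r.n_intermediate,
            "excluded_novice": r.excluded_novice,
            "excluded_intermediate": r.excluded_intermediate,
            "median_novice": r.median_novice,
            "iqr_novice": r.iqr_novice,
            "median_intermediate": r.median_intermediate,
            "iqr_intermediate": r.iqr_intermediate,
            "normal_novice": r.normal_novice,
            "normal_intermediate": r.normal_intermediate,
            "test": r.test if r.test is not None else "",
            "statistic": r.statistic,
            "df": r.df,
            "p_value": r.p_value,
            "significant": r.significant,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=_COMPARISON_COLS)


def write_comparison_table(results: list[GroupComparisonResult] | pd.DataFrame, path) -> None:
    df = (
        results
        if isinstance(results, pd.DataFrame)
        else comparison_results_to_frame(results)
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_comparison_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _COMPARISON_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: comparison table missing columns {missing}")
    return df
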