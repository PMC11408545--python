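"""Time and instrument-motion metrics.

Per task segment the framework scores: completion time, idle time (tool
tip speed at or below a threshold v*), path length, motion smoothness as
the log dimensionless jerk, economy of volume (cube root of the swept
bounding-box volume over path length, in percent), and bimanual
dexterity (Pearson correlation of the two tool-tip speed series).

Degenerate inputs (motionless tool, zero-variance speed, zero bounding
volume) yield ``None`` rather than infinities; the pipeline records them
as missing values.
"""

from __future__ import annotations

import math

import numpy as np

from .config import MetricConfig, PeakConfig, SmoothingConfig
from .datatypes import (
    MetricValue,
    TrialRecording,
    ValidationError,
)
from .preprocessing import (
    DerivativeEstimates,
    estimate_kinematics,
    interpolate_gaps,
    slice_estimates,
    slice_force,
)

__all__ = [
    "completion_time",
    "idle_time",
    "path_length",
    "motion_smoothness",
    "bounding_volume",
    "economy_of_volume",
    "bimanual_dexterity",
    "compute_segment_metrics",
]


def completion_time(seg, rate: float) -> float:
    """Segment duration: (kf - k0) sampling periods, in seconds."""
    return (seg.kf - seg.k0) / rate


def idle_time(
    speeds: np.ndarray | list[np.ndarray], rate: float, cfg: MetricConfig | None = None
) -> float:
    """Total time every supplied tool-tip speed is at or below v*, in seconds.

    Pass one speed sequence for a single-instrument scope, or both
    sequences (same 120 Hz timeline) for the "both" scope, which counts
    only simultaneous idleness.
    """
    cfg = cfg or MetricConfig()
    if isinstance(speeds, np.ndarray) and speeds.ndim == 1:
        speeds = [speeds]
    arrays = [np.asarray(s, dtype=float) for s in speeds]
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValidationError(
            f"idle_time: speed sequences differ in length ({[a.size for a in arrays]})"
        )
    idle = np.ones(n, dtype=bool)
    for a in arrays:
        idle &= a <= cfg.v_star
    return float(idle.sum()) / rate


def path_length(positions: np.ndarray) -> float:
    """Total 3-D distance traversed by the tool tip: sum of ||Δp||₂, in cm."""
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 3 or positions.shape[0] < 2:
        raise ValidationError("path_length expects an (m >= 2) x 3 position array")
    return float(np.linalg.norm(np.diff(positions, axis=0), axis=1).sum())


def motion_smoothness(
    est: DerivativeEstimates,
    delta_t: float,
    rate: float | None = None,
    cfg: MetricConfig | None = None,
) -> float | None:
    """Log dimensionless jerk of a segment; larger (less negative) is smoother.

    -ln( ΔT³ / v_max² · Σ‖j(k)‖₂² · (1/rate) ), where the jerk sum times
    the sampling period approximates the continuous squared-jerk
    integral and v_max is the peak speed within the segment.  Returns
    ``None`` for degenerate (motionless) segments.
    """
    cfg = cfg or MetricConfig()
    rate = rate or est.sample_rate
    if delta_t <= 0:
        raise ValidationError("motion_smoothness requires delta_t > 0")
    v_max = est.v_max
    jerk_integral = float((np.linalg.norm(est.j, axis=1) ** 2).sum()) / rate
    if v_max <= 0 or jerk_integral <= cfg.ms_epsilon:
        return None
    return -math.log(delta_t**3 / v_max**2 * jerk_integral)


def bounding_volume(positions: np.ndarray) -> float:
    """Axis-aligned bounding-box volume swept by the tool tip, in cm³."""
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 3 or positions.shape[0] < 2:
        raise ValidationError("bounding_volume expects an (m >= 2) x 3 position array")
    ranges = positions.max(axis=0) - positions.min(axis=0)
    return float(np.abs(ranges).prod())


def economy_of_volume(
    positions: np.ndarray, cfg: MetricConfig | None = None
) -> float | None:
    """100 · cbrt(bounding volume) / path length, in percent.

    A zero bounding volume follows ``cfg.eov_zero_volume_policy``; a zero
    path length (all points identical) is degenerate and returns None.
    """
    cfg = cfg or MetricConfig()
    pl = path_length(positions)
    if pl <= 0:
        return None
    vol = bounding_volume(positions)
    if vol == 0 and cfg.eov_zero_volume_policy == "not_a_value":
        return None
    return 100.0 * vol ** (1.0 / 3.0) / pl


def bimanual_dexterity(speed_l: np.ndarray, speed_r: np.ndarray) -> float | None:
    """Pearson correlation of left- and right-tool speed series, in [-1, 1].

    Returns ``None`` when either series has zero variance.
    """
    speed_l = np.asarray(speed_l, dtype=float)
    speed_r = np.asarray(speed_r, dtype=float)
    if speed_l.size != speed_r.size:
        raise ValidationError("bimanual_dexterity: speed sequences differ in length")
    if speed_l.size < 3:
        raise ValidationError("bimanual_dexterity requires at least 3 samples")
    dl = speed_l - speed_l.mean()
    dr = speed_r - speed_r.mean()
    ssl = float(dl @ dl)
    ssr = float(dr @ dr)
    if ssl == 0 or ssr == 0:
        return None
    return float(dl @ dr) / math.sqrt(ssl * ssr)


# ---------------------------------------------------------------------------
# per-trial driver


def _nan_if_none(x: float | None) -> float:
    return float("nan") if x is None else float(x)


def compute_segment_metrics(
    trial: TrialRecording,
    smoothing: SmoothingConfig | None = None,
    metrics_cfg: MetricConfig | None = None,
    peaks: PeakConfig | None = None,
) -> list[MetricValue]:
    """Score one trial: 13 metric values per segment, 52 per trial.

    Emits the full descriptive-table scope set per segment — completion
    time (both), idle time (tweezers / needle holder / both), path
    length, motion smoothness and economy of volume per instrument,
    bimanual dexterity (both), and number of presses per hand.
    Degenerate metrics are emitted with NaN values, never dropped.
    """
    from .tactile import activity_signal, number_of_presses, trial_force_maxima

    smoothing = smoothing or SmoothingConfig()
    metrics_cfg = metrics_cfg or MetricConfig()
    peaks = peaks or PeakConfig()

    left_kin = interpolate_gaps(trial.left_kin, smoothing)
    right_kin = interpolate_gaps(trial.right_kin, smoothing)
    est_l = estimate_kinematics(left_kin, smoothing)
    est_r = estimate_kinematics(right_kin, smoothing)
    forces = {"left_hand": trial.left_force, "right_hand": trial.right_force}
    maxima = {
        scope: (trial_force_maxima(f) if f is not None else None)
        for scope, f in forces.items()
    }

    rate = left_kin.sample_rate
    out: list[MetricValue] = []

    def emit(metric: str, scope: str, seg, value: float | None):
        out.append(
            MetricValue(
                metric=metric,
                scope=scope,
                segment_id=seg.segment_id,
                subject_id=trial.subject_id,
                group=trial.group,
                trial_index=trial.trial_index,
                value=_nan_if_none(value),
            )
        )

    for seg in trial.segments:
        sl = slice_estimates(est_l, seg)
        sr = slice_estimates(est_r, seg)
        dt = completion_time(seg, rate)

        emit("completion_time", "both", seg, dt)
        emit("idle_time", "tweezers", seg, idle_time(sl.speed, rate, metrics_cfg))
        emit("idle_time", "needle_holder", seg, idle_time(sr.speed, rate, metrics_cfg))
        emit(
            "idle_time",
            "both",
            seg,
            idle_time([sl.speed, sr.speed], rate, metrics_cfg),
        )
        for scope, est_seg in (("tweezers", sl), ("needle_holder", sr)):
            emit("path_length", scope, seg, path_length(est_seg.positions))
            emit(
                "motion_smoothness",
                scope,
                seg,
                motion_smoothness(est_seg, dt, rate, metrics_cfg),
            )
            emit(
                "economy_of_volume",
                scope,
                seg,
                economy_of_volume(est_seg.positions, metrics_cfg),
            )
        emit("bimanual_dexterity", "both", seg, bimanual_dexterity(sl.speed, sr.speed))
        for scope in ("left_hand", "right_hand"):
            if forces[scope] is None:
                nop = float("nan")
            else:
                try:
                    fseg = slice_force(forces[scope], seg)
                    act = activity_signal(fseg, smoothing, channel_maxima=maxima[scope])
                    nop = float(number_of_presses(act, peaks))
                except ValidationError:
                    nop = float("nan")
            emit("number_of_presses", scope, seg, nop)
    return out
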