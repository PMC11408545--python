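"""Signal conditioning: gap repair, Savitzky-Golay derivatives, slicing.

Velocity, acceleration and jerk are estimated with a Savitzky-Golay
differentiator (order 3, window 5 by default) applied per coordinate and
scaled to physical units by the sampling period.  Derivatives are always
computed on the *full* trial and sliced to segments afterwards, so
segment boundaries carry no filter edge artefacts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .config import SmoothingConfig
from .datatypes import (
    ForceTrace,
    KinematicTrace,
    SegmentAnnotation,
    UnrecoverableGapError,
    ValidationError,
)

__all__ = [
    "DerivativeEstimates",
    "interpolate_gaps",
    "savgol_derivative",
    "estimate_kinematics",
    "slice_trace",
    "slice_estimates",
    "slice_force",
]


@dataclass
class DerivativeEstimates:
    """Velocity/acceleration/jerk estimates aligned with a kinematic trace.

    ``speed`` is the L2-norm of the velocity row-wise; ``v_max`` is the
    maximum speed over the represented window (cm/s).
    """

    sample_rate: float
    timestamps: np.ndarray
    positions: np.ndarray
    v: np.ndarray
    a: np.ndarray
    j: np.ndarray

    @property
    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.v, axis=1)

    @property
    def v_max(self) -> float:
        return float(self.speed.max())

    @property
    def n_samples(self) -> int:
        return self.timestamps.size


def interpolate_gaps(trace: KinematicTrace, cfg: SmoothingConfig) -> KinematicTrace:
    """Fill flagged dropouts by per-coordinate linear interpolation.

    Contiguous gaps longer than ``cfg.max_gap_s`` are unrecoverable and
    raise; a gap touching either end of the trace is likewise rejected
    (there is nothing to interpolate from).  Idempotent: a gap-free trace
    is returned unchanged.
    """
    if not trace.has_gaps:
        return trace
    n = trace.n_samples
    gap_mask = np.zeros(n, dtype=bool)
    gap_mask[trace.gap_indices] = True
    # locate contiguous runs of gaps
    padded = np.diff(np.concatenate(([0], gap_mask.view(np.int8), [0])))
    starts = np.nonzero(padded == 1)[0]
    ends = np.nonzero(padded == -1)[0]  # exclusive
    max_len = int(round(cfg.max_gap_s * trace.sample_rate))
    for s, e in zip(starts, ends):
        length = e - s
        if s == 0 or e == n:
            raise UnrecoverableGapError(
                f"gap of {length} samples touches trace boundary at index {s}",
                gap_start=int(s),
                gap_length=int(length),
            )
        if length > max_len:
            raise UnrecoverableGapError(
                f"gap of {length} samples ({length / trace.sample_rate:.3f} s) at "
                f"index {s} exceeds max_gap_s={cfg.max_gap_s}",
                gap_start=int(s),
                gap_length=int(length),
            )
    good = ~gap_mask
    positions = trace.positions.copy()
    for axis in range(3):
        positions[gap_mask, axis] = np.interp(
            trace.timestamps[gap_mask], trace.timestamps[good], positions[good, axis]
        )
    orientations = trace.orientations
    if orientations is not None:
        orientations = orientations.copy()
        ok = np.isfinite(orientations).all(axis=1)
        for axis in range(3):
            orientations[~ok, axis] = np.interp(
                trace.timestamps[~ok], trace.timestamps[ok], orientations[ok, axis]
            )
    return KinematicTrace(
        instrument=trace.instrument,
        sample_rate=trace.sample_rate,
        timestamps=trace.timestamps,
        positions=positions,
        orientations=orientations,
        gap_indices=np.empty(0, dtype=int),
    )


def savgol_derivative(
    series: np.ndarray,
    rate: float,
    cfg: SmoothingConfig,
    order_of_derivative: int,
) -> np.ndarray:
    """Savitzky-Golay estimate of the d-th time derivative of a scalar series.

    Output is in physical units (the filter output is scaled by
    ``rate**d``).  Under ``interp``/``mirror`` edge handling the output
    length equals the input length; ``truncate_to_valid`` drops half a
    window at each end.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValidationError("savgol_derivative expects a 1-D series")
    d = int(order_of_derivative)
    if not 1 <= d <= 3:
        raise ValidationError("order_of_derivative must be 1, 2 or 3")
    if d > cfg.sg_order:
        raise ValidationError(
            f"derivative order {d} exceeds polynomial order {cfg.sg_order}"
        )
    if series.size < cfg.sg_window:
        raise ValidationError(
            f"series of length {series.size} shorter than SG window {cfg.sg_window}"
        )
    mode = "mirror" if cfg.edge_mode == "mirror" else "interp"
    out = savgol_filter(
        series, cfg.sg_window, cfg.sg_order, deriv=d, delta=1.0 / rate, mode=mode
    )
    if cfg.edge_mode == "truncate_to_valid":
        half = cfg.sg_window // 2
        out = out[half : series.size - half]
    return out


def estimate_kinematics(
    trace: KinematicTrace, cfg: SmoothingConfig | None = None
) -> DerivativeEstimates:
    """Estimate velocity, acceleration and jerk for a gap-free trace."""
    cfg = cfg or SmoothingConfig()
    if trace.has_gaps:
        raise ValidationError("trace has unfilled gaps; run interpolate_gaps first")
    # derivative arrays must stay aligned with positions for slicing
    eff = cfg if cfg.edge_mode != "truncate_to_valid" else dataclasses.replace(
        cfg, edge_mode="interp"
    )
    derivs = {}
    for d in (1, 2, 3):
        derivs[d] = np.column_stack(
            [
                savgol_derivative(trace.positions[:, axis], trace.sample_rate, eff, d)
                for axis in range(3)
            ]
        )
    return DerivativeEstimates(
        sample_rate=trace.sample_rate,
        timestamps=trace.timestamps,
        positions=trace.positions,
        v=derivs[1],
        a=derivs[2],
        j=derivs[3],
    )


def slice_trace(trace: KinematicTrace, seg: SegmentAnnotation) -> KinematicTrace:
    """Restrict a kinematic trace to the [k0, kf) sample window."""
    if seg.kf > trace.n_samples:
        raise ValidationError(f"{seg.segment_id}: window exceeds trace length")
    sl = slice(seg.k0, seg.kf)
    if seg.kf - seg.k0 < 2:
        raise ValidationError(f"{seg.segment_id}: sliced trace would be empty")
    return KinematicTrace(
        instrument=trace.instrument,
        sample_rate=trace.sample_rate,
        timestamps=trace.timestamps[sl],
        positions=trace.positions[sl],
        orientations=None if trace.orientations is None else trace.orientations[sl],
        gap_indices=np.empty(0, dtype=int),
    )


def slice_estimates(
    est: DerivativeEstimates, seg: SegmentAnnotation
) -> DerivativeEstimates:
    """Restrict derivative estimates (computed on the full trial) to a segment."""
    if seg.kf > est.n_samples:
        raise ValidationError(f"{seg.segment_id}: window exceeds estimates length")
    sl = slice(seg.k0, seg.kf)
    return DerivativeEstimates(
        sample_rate=est.sample_rate,
        timestamps=est.timestamps[sl],
        positions=est.positions[sl],
        v=est.v[sl],
        a=est.a[sl],
        j=est.j[sl],
    )


def slice_force(force: ForceTrace, seg: SegmentAnnotation) -> ForceTrace:
    """Restrict a force trace to the segment's [t0, tf) time window.

    The force stream runs on its own (40 Hz) timeline; the segment window
    is defined in seconds from the kinematic annotation.
    """
    mask = (force.timestamps >= seg.t0) & (force.timestamps < seg.tf)
    if mask.sum() < 2:
        raise ValidationError(
            f"{seg.segment_id}: force window [{seg.t0:.3f}, {seg.tf:.3f}) s is empty"
        )
    return ForceTrace(
        hand=force.hand,
        sample_rate=force.sample_rate,
        timestamps=force.timestamps[mask],
        channels={f: ch[mask] for f, ch in force.channels.items()},
        n_clipped=0,
    )
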