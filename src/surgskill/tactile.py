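"""Fingertip-force analysis: the hand activity signal and press counting.

Each hand wears force sensors on thumb, index and middle finger.  Every
channel is normalized by its trial-level maximum (so all segments of a
trial share one scale), differentiated with the Savitzky-Golay filter,
and the three derivatives are summed into the hand's activity signal
A(t).  Pinching actions show up as positive peaks of A(t); the number of
presses is the count of sufficiently prominent, sufficiently separated
local maxima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .config import PeakConfig, SmoothingConfig
from .datatypes import FINGERS, ForceTrace, Hand, ValidationError
from .preprocessing import savgol_derivative

log = logging.getLogger(__name__)

__all__ = ["ActivitySignal", "activity_signal", "number_of_presses", "trial_force_maxima"]


@dataclass
class ActivitySignal:
    """Per-hand activity signal and its ingredients on the 40 Hz timeline."""

    hand: Hand
    sample_rate: float
    timestamps: np.ndarray
    normalized_channels: dict[str, np.ndarray]
    derivatives: dict[str, np.ndarray]
    activity: np.ndarray


def trial_force_maxima(force: ForceTrace) -> dict[str, float]:
    """Per-finger maximum absolute force over a whole trial (the
    normalization scale shared by all of the trial's segments)."""
    return {f: float(np.abs(ch).max()) for f, ch in force.channels.items()}


def activity_signal(
    force: ForceTrace,
    cfg: SmoothingConfig | None = None,
    channel_maxima: dict[str, float] | None = None,
) -> ActivitySignal:
    """Compute A(t) = Σ_i d/dt [ f_i(t) / max|f_i| ] over the three fingers.

    ``channel_maxima`` supplies the trial-level normalization scales when
    the trace is a segment slice; without it each channel is normalized
    by its own maximum over the given window.  An all-zero channel
    contributes zeros (guarded, logged).
    """
    cfg = cfg or SmoothingConfig()
    if force.n_samples < cfg.sg_window:
        raise ValidationError(
            f"force window of {force.n_samples} samples shorter than SG window"
        )
    maxima = channel_maxima or trial_force_maxima(force)
    normalized: dict[str, np.ndarray] = {}
    derivatives: dict[str, np.ndarray] = {}
    activity = np.zeros(force.n_samples)
    for finger in FINGERS:
        scale = maxima.get(finger, 0.0)
        if scale <= 0:
            log.warning("finger %s/%s: all-zero channel, contributes no activity",
                        force.hand.value, finger)
            normalized[finger] = np.zeros(force.n_samples)
            derivatives[finger] = np.zeros(force.n_samples)
            continue
        norm = force.channels[finger] / scale
        deriv = savgol_derivative(norm, force.sample_rate, cfg, 1)
        if deriv.size != norm.size:  # truncate_to_valid keeps lengths aligned here
            pad = (norm.size - deriv.size) // 2
            deriv = np.pad(deriv, (pad, norm.size - deriv.size - pad), mode="edge")
        normalized[finger] = norm
        derivatives[finger] = deriv
        activity = activity + deriv
    return ActivitySignal(
        hand=force.hand,
        sample_rate=force.sample_rate,
        timestamps=force.timestamps,
        normalized_channels=normalized,
        derivatives=derivatives,
        activity=activity,
    )


def number_of_presses(act: ActivitySignal, pcfg: PeakConfig | None = None) -> int:
    """Count pinch events: prominent, separated positive peaks of A(t).

    The prominence floor is ``min_prominence_fraction`` of the segment's
    activity maximum; peaks closer than ``min_separation_s`` merge into
    one (the larger survives).  A flat or non-positive activity signal
    yields 0.  Deterministic for a fixed configuration.
    """
    pcfg = pcfg or PeakConfig()
    a = np.asarray(act.activity, dtype=float)
    if pcfg.presmooth and a.size >= 5:
        a = savgol_filter(a, 5, 3, mode="interp")
    peak = a.max(initial=0.0)
    if peak <= 1e-9:  # numeric floor: flat signals carry only float noise
        return 0
    distance = max(1, int(round(pcfg.min_separation_s * act.sample_rate)))
    idx, _ = find_peaks(
        a,
        prominence=pcfg.min_prominence_fraction * peak,
        distance=distance,
        height=pcfg.min_prominence_fraction * peak,
    )
    return int(idx.size)
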