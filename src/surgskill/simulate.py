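"""Synthetic cohort generator with per-metric ground truth.

Trials are built the way skilled reaching is usually modelled: each task
segment is a chain of straight minimum-jerk submovements separated by
idle holds, with band-limited (8-12 Hz) physiological tremor added on
top.  Skill level is encoded in the submovement schedule — novices make
more, longer, noisier submovements, pause more, and tremble more — and
in pulse-train fingertip forces whose raised-cosine bumps plant an
unambiguous number of pinch events per hand.

Every generated trial carries a :class:`GroundTruth` record (planted
press counts, planted idle seconds, planted submovement path length) so
each metric can be validated against construction, and the whole cohort
is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    FINGERS,
    SEGMENT_IDS,
    ForceTrace,
    Group,
    Hand,
    Instrument,
    KinematicTrace,
    SegmentAnnotation,
    TrialRecording,
)
from .presets import SegmentParams, SkillProfile, default_profiles

__all__ = [
    "GroundTruth",
    "SegmentGroundTruth",
    "min_jerk_segment",
    "generate_trial",
    "generate_cohort",
]

KIN_RATE = 120.0
FORCE_RATE = 40.0


#: Reference idle-speed threshold used for ground-truth bookkeeping; matches
#: the MetricConfig default v*.
IDLE_REF_THRESHOLD = 0.5


@dataclass
class SegmentGroundTruth:
    """What was planted into one segment, per construction.

    ``hold_seconds`` is the scheduled stationary time between
    submovements.  ``idle_seconds`` is the total sub-threshold time of
    the noiseless trajectory at the reference threshold (holds plus the
    slow tails of each minimum-jerk reach) — the idle time actually
    planted in the emitted trace, measured by construction.
    """

    duration_s: float
    hold_seconds: float
    idle_seconds: dict[str, float]  # hand -> clean sub-threshold seconds
    press_counts: dict[str, int]  # hand -> count
    submovement_path_cm: dict[str, float]  # hand -> sum of planted amplitudes


@dataclass
class GroundTruth:
    subject_id: str
    trial_index: int
    segments: dict[str, SegmentGroundTruth] = field(default_factory=dict)


def min_jerk_segment(
    D: np.ndarray, T: float, rate: float = KIN_RATE, p0: np.ndarray | None = None
) -> np.ndarray:
    """Sample a minimum-jerk point-to-point reach, endpoints inclusive.

    p(τ) = p0 + D (10τ³ - 15τ⁴ + 6τ⁵) with τ = t/T; boundary velocity
    and acceleration are zero and the peak speed is 1.875·‖D‖/T.
    """
    if T <= 0:
        raise ValueError("reach duration must be positive")
    D = np.atleast_1d(np.asarray(D, dtype=float))
    p0 = np.zeros_like(D) if p0 is None else np.asarray(p0, dtype=float)
    n = int(round(T * rate))
    tau = np.arange(n + 1) / n
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    return p0[None, :] + s[:, None] * D[None, :]


def _min_jerk_steps(disp: np.ndarray, n: int) -> np.ndarray:
    """Positions 1..n of a minimum-jerk reach of n samples (start excluded)."""
    tau = np.arange(1, n + 1) / n
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    return s[:, None] * disp[None, :]


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else np.array([1.0, 0.0, 0.0])


def _build_hand_path(
    rng: np.random.Generator,
    p_start: np.ndarray,
    amplitudes: np.ndarray,
    move_samples: np.ndarray,
    hold_samples: np.ndarray,
    workspace: float,
) -> tuple[np.ndarray, float]:
    """Chain hold/move blocks into one position array; returns (positions, Σamp).

    Submovement directions point toward uniformly drawn targets in the
    ±workspace box, which keeps the path bounded without a hard wall.
    """
    p = p_start.copy()
    blocks = [p[None, :]]
    for i, n_move in enumerate(move_samples):
        n_hold = hold_samples[i]
        if n_hold:
            blocks.append(np.tile(p, (n_hold, 1)))
        target = rng.uniform(-workspace, workspace, size=3)
        direction = target - p
        dnorm = np.linalg.norm(direction)
        direction = direction / dnorm if dnorm > 1e-9 else _random_unit(rng)
        disp = amplitudes[i] * direction
        blocks.append(p + _min_jerk_steps(disp, int(n_move)))
        p = p + disp
    if hold_samples[-1]:
        blocks.append(np.tile(p, (hold_samples[-1], 1)))
    return np.vstack(blocks), float(amplitudes.sum())


def _add_tremor(
    rng: np.random.Generator,
    positions: np.ndarray,
    amp_cm: float,
    band_hz: tuple[float, float],
    rate: float,
) -> np.ndarray:
    if amp_cm <= 0:
        return positions
    n = positions.shape[0]
    t = np.arange(n) / rate
    out = positions.copy()
    for axis in range(3):
        a = amp_cm * rng.uniform(0.5, 1.5)
        f = rng.uniform(*band_hz)
        phi = rng.uniform(0, 2 * np.pi)
        out[:, axis] += a * np.sin(2 * np.pi * f * t + phi)
    return out


def _plan_press_times(
    rng: np.random.Generator, T_seg: float, target: int, width_s: float
) -> np.ndarray:
    """Press centre times: near-even spacing with jitter, min gap enforced.

    The planted count is capped by what fits in the segment; callers
    must take the returned size as the ground truth.
    """
    if target <= 0:
        return np.empty(0)
    min_gap = max(0.8, width_s + 0.5)
    margin = width_s
    span = T_seg - 2 * margin
    if span <= 0:
        return np.empty(0)
    n = min(target, int(span // min_gap) + 1)
    if n == 1:
        return np.array([margin + span * rng.uniform(0.3, 0.7)])
    base = margin + np.linspace(0, span, n)
    gap = span / (n - 1)
    jitter = rng.uniform(-1, 1, size=n) * min(0.2 * gap, (gap - min_gap) / 2 * 0.9)
    return np.clip(base + jitter, margin, margin + span)


def _gen_force_channels(
    rng: np.random.Generator,
    n_samples: int,
    press_times: np.ndarray,
    width_s: float,
    rate: float = FORCE_RATE,
) -> dict[str, np.ndarray]:
    t = np.arange(n_samples) / rate
    weights = {"thumb": 1.0, "index": 0.9, "middle": 0.6}
    channels = {}
    for finger in FINGERS:
        baseline = rng.uniform(0.3, 0.8)
        sig = np.full(n_samples, baseline)
        for c in press_times:
            amp = rng.uniform(1.5, 4.0) * weights[finger]
            mask = np.abs(t - c) <= width_s / 2
            sig[mask] += amp * 0.5 * (1 + np.cos(2 * np.pi * (t[mask] - c) / width_s))
        sig += rng.normal(0, 0.01, n_samples)
        channels[finger] = np.clip(sig, 0.0, None)
    return channels


def _generate_segment(
    rng: np.random.Generator,
    params: SegmentParams,
    profile: SkillProfile,
    p0_left: np.ndarray,
    p0_right: np.ndarray,
    subject_factor: float = 1.0,
):
    """One task segment for both hands; returns kinematics, forces, truth."""
    n_sub = max(1, int(round(rng.normal(params.n_sub_mean * subject_factor, params.n_sub_sd))))
    durations = np.clip(
        rng.normal(params.dur_mean_s, params.dur_sd_s, n_sub), 0.15, None
    )
    amp_r = np.clip(rng.normal(params.amp_mean_cm, params.amp_sd_cm, n_sub), 0.2, None)
    amp_l = np.clip(
        rng.normal(0.9 * params.amp_mean_cm, params.amp_sd_cm, n_sub), 0.2, None
    )

    idle_frac = min(0.9, params.idle_fraction * subject_factor)
    T_move = float(durations.sum())
    T_idle = idle_frac / (1.0 - idle_frac) * T_move
    gaps = T_idle * rng.dirichlet(np.ones(n_sub + 1))

    move_samples = np.maximum(4, np.round(durations * KIN_RATE).astype(int))
    hold_samples = np.round(gaps * KIN_RATE).astype(int)

    pos_r, path_r = _build_hand_path(
        rng, p0_right, amp_r, move_samples, hold_samples, profile.workspace_halfwidth_cm
    )
    pos_l, path_l = _build_hand_path(
        rng, p0_left, amp_l, move_samples, hold_samples, profile.workspace_halfwidth_cm
    )
    # the left hand trails the right by the inter-hand lag
    shift = int(round(profile.inter_hand_lag_s * KIN_RATE))
    if shift > 0 and shift < pos_l.shape[0]:
        pos_l = np.vstack([np.tile(pos_l[0], (shift, 1)), pos_l[:-shift]])

    # pad to a common length divisible by 3 so the 40 Hz force stream aligns
    n = max(pos_r.shape[0], pos_l.shape[0])
    n += (-n) % 3
    pos_r = np.vstack([pos_r, np.tile(pos_r[-1], (n - pos_r.shape[0], 1))])
    pos_l = np.vstack([pos_l, np.tile(pos_l[-1], (n - pos_l.shape[0], 1))])

    hold_seconds = float(hold_samples.sum()) / KIN_RATE
    idle_seconds = {}
    for hand, pos in (("left", pos_l), ("right", pos_r)):
        speed = np.linalg.norm(np.diff(pos, axis=0), axis=1) * KIN_RATE
        idle_seconds[hand] = float((speed <= IDLE_REF_THRESHOLD).sum() + 1) / KIN_RATE

    pos_r = _add_tremor(rng, pos_r, profile.tremor_amp_cm, profile.tremor_band_hz, KIN_RATE)
    pos_l = _add_tremor(rng, pos_l, profile.tremor_amp_cm, profile.tremor_band_hz, KIN_RATE)

    T_seg = n / KIN_RATE
    n_force = n // 3
    forces = {}
    press_counts = {}
    for hand, (mean, sd) in (
        ("left", (params.press_left_mean, params.press_left_sd)),
        ("right", (params.press_right_mean, params.press_right_sd)),
    ):
        target = max(0, int(round(rng.normal(mean * subject_factor, sd))))
        times = _plan_press_times(rng, T_seg, target, profile.press_width_s)
        forces[hand] = _gen_force_channels(rng, n_force, times, profile.press_width_s)
        press_counts[hand] = int(times.size)

    truth = SegmentGroundTruth(
        duration_s=T_seg,
        hold_seconds=hold_seconds,
        idle_seconds=idle_seconds,
        press_counts=press_counts,
        submovement_path_cm={"left": path_l, "right": path_r},
    )
    return pos_l, pos_r, forces, truth


def generate_trial(
    profile: SkillProfile,
    subject_id: str,
    trial_index: int,
    seed: int | np.random.Generator = 0,
    group: Group | str | None = None,
    ali_score: int | None = None,
    subject_factor: float = 1.0,
) -> tuple[TrialRecording, GroundTruth]:
    """Generate one four-segment trial and its construction ground truth.

    ``group`` defaults to the profile's label but may be overridden (a
    null cohort draws both labels from one profile).  Deterministic for
    a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    group = Group(group) if group is not None else Group(profile.label)
    if ali_score is None:
        ali_score = (
            int(rng.integers(7, 11)) if group is Group.NOVICE else int(rng.integers(3, 7))
        )

    p_left = np.array([-2.0, 0.0, 0.0]) + rng.uniform(-0.3, 0.3, 3)
    p_right = np.array([2.0, 0.0, 0.0]) + rng.uniform(-0.3, 0.3, 3)

    truth = GroundTruth(subject_id=subject_id, trial_index=trial_index)
    pos_l_parts, pos_r_parts = [], []
    force_parts = {"left": [], "right": []}
    boundaries = [0]
    for sid in SEGMENT_IDS:
        pos_l, pos_r, forces, seg_truth = _generate_segment(
            rng, profile.segments[sid], profile, p_left, p_right, subject_factor
        )
        truth.segments[sid] = seg_truth
        pos_l_parts.append(pos_l)
        pos_r_parts.append(pos_r)
        for hand in ("left", "right"):
            force_parts[hand].append(forces[hand])
        p_left = pos_l[-1].copy()
        p_right = pos_r[-1].copy()
        boundaries.append(boundaries[-1] + pos_l.shape[0])

    pos_l_all = np.vstack(pos_l_parts)
    pos_r_all = np.vstack(pos_r_parts)
    n = pos_l_all.shape[0]
    t_kin = np.arange(n) / KIN_RATE

    left_kin = KinematicTrace(
        Instrument.LEFT_TWEEZERS, KIN_RATE, t_kin, pos_l_all
    )
    right_kin = KinematicTrace(
        Instrument.RIGHT_NEEDLE_HOLDER, KIN_RATE, t_kin, pos_r_all
    )

    force_traces = {}
    for hand in ("left", "right"):
        chans = {
            f: np.concatenate([part[f] for part in force_parts[hand]]) for f in FINGERS
        }
        nf = chans["thumb"].size
        force_traces[hand] = ForceTrace(
            Hand(hand), FORCE_RATE, np.arange(nf) / FORCE_RATE, chans
        )

    segments = [
        SegmentAnnotation.from_indices(sid, boundaries[i], boundaries[i + 1], left_kin)
        for i, sid in enumerate(SEGMENT_IDS)
    ]
    trial = TrialRecording(
        subject_id=subject_id,
        group=group,
        ali_score=ali_score,
        trial_index=trial_index,
        left_kin=left_kin,
        right_kin=right_kin,
        left_force=force_traces["left"],
        right_force=force_traces["right"],
        segments=segments,
    )
    return trial, truth


def generate_cohort(
    n_novice: int = 5,
    n_intermediate: int = 6,
    trials: int = 3,
    seed: int = 0,
    profiles: dict[str, SkillProfile] | None = None,
    null_mode: bool = False,
    subject_sd: float = 0.10,
) -> list[tuple[TrialRecording, GroundTruth]]:
    """Generate a full study cohort (defaults: 5 novice + 6 intermediate
    subjects, 3 trials each — the effective study size).

    Each subject carries a lognormal skill multiplier (sd ``subject_sd``
    on the log scale) applied to submovement counts, idle fraction and
    press counts, giving between-subject variability on top of
    trial-to-trial noise.  In ``null_mode`` every subject is drawn from
    the novice profile and the group labels carry no signal.
    """
    profiles = profiles or default_profiles()
    ss = np.random.SeedSequence(seed)
    out = []
    plan = [("N", Group.NOVICE, n_novice), ("I", Group.INTERMEDIATE, n_intermediate)]
    subject_seeds = ss.spawn(n_novice + n_intermediate)
    k = 0
    for prefix, group, count in plan:
        for i in range(count):
            sub_ss = subject_seeds[k]
            k += 1
            sub_rng = np.random.default_rng(sub_ss)
            factor = float(np.exp(sub_rng.normal(0.0, subject_sd)))
            profile = profiles["novice" if null_mode else group.value]
            subject_id = f"{prefix}{i + 1:02d}"
            ali = (
                int(sub_rng.integers(7, 11))
                if group is Group.NOVICE
                else int(sub_rng.integers(3, 7))
            )
            for trial_index in range(1, trials + 1):
                trial_rng = np.random.default_rng(sub_ss.spawn(1)[0])
                out.append(
                    generate_trial(
                        profile,
                        subject_id,
                        trial_index,
                        seed=trial_rng,
                        group=group,
                        ali_score=ali,
                        subject_factor=factor,
                    )
                )
    return out


def write_cohort(cohort, directory) -> None:
    """Write every trial of a cohort plus a manifest and ground-truth JSON."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    from .io import write_trial

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    truths = {}
    for trial, truth in cohort:
        name = f"{trial.subject_id}_t{trial.trial_index}"
        write_trial(trial, directory / name)
        manifest.append(str(Path(name) / "trial.json"))
        truths[name] = asdict(truth)
    with open(directory / "cohort.json", "w") as fh:
        json.dump({"trials": manifest}, fh, indent=2)
        fh.write("\n")
    with open(directory / "ground_truth.json", "w") as fh:
        json.dump(truths, fh, indent=2)
        fh.write("\n")
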