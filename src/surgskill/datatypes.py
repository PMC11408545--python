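"""Core domain containers for bimanual microsurgical skill assessment.

The framework analyses one suturing trial at a time.  A trial carries two
instrument trajectories (tweezers in the left hand, needle holder in the
right), two per-finger force recordings, and four annotated task segments
(S1..S4: needle through the first vessel wall, through the second wall,
first knot, second knot).  Kinematics are sampled nominally at 120 Hz,
forces at 40 Hz; segment windows are defined on the kinematic timeline.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Instrument",
    "Hand",
    "Group",
    "SEGMENT_IDS",
    "FINGERS",
    "KinematicTrace",
    "ForceTrace",
    "SegmentAnnotation",
    "TrialRecording",
    "MetricValue",
    "GroupComparisonResult",
    "METRIC_SCOPES",
    "METRIC_UNITS",
    "FormatError",
    "ValidationError",
    "UnrecoverableGapError",
]


class FormatError(ValueError):
    """A file does not follow the expected on-disk layout."""


class ValidationError(ValueError):
    """Parsed data violates a domain invariant."""


class UnrecoverableGapError(ValidationError):
    """A kinematic dropout is too long to interpolate."""

    def __init__(self, message: str, gap_start: int, gap_length: int):
        super().__init__(message)
        self.gap_start = gap_start
        self.gap_length = gap_length


class Instrument(str, enum.Enum):
    LEFT_TWEEZERS = "left_tweezers"
    RIGHT_NEEDLE_HOLDER = "right_needle_holder"


class Hand(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class Group(str, enum.Enum):
    NOVICE = "novice"
    INTERMEDIATE = "intermediate"


SEGMENT_IDS = ("S1", "S2", "S3", "S4")
FINGERS = ("thumb", "index", "middle")

#: Legal (metric, scope) pairs, mirroring the descriptive-table row layout.
METRIC_SCOPES: dict[str, tuple[str, ...]] = {
    "completion_time": ("both",),
    "idle_time": ("tweezers", "needle_holder", "both"),
    "path_length": ("tweezers", "needle_holder"),
    "motion_smoothness": ("tweezers", "needle_holder"),
    "economy_of_volume": ("tweezers", "needle_holder"),
    "bimanual_dexterity": ("both",),
    "number_of_presses": ("left_hand", "right_hand"),
}

METRIC_UNITS: dict[str, str] = {
    "completion_time": "s",
    "idle_time": "s",
    "path_length": "cm",
    "motion_smoothness": "-",
    "economy_of_volume": "%",
    "bimanual_dexterity": "-",
    "number_of_presses": "#",
}

#: Canonical row order for per-segment metric emission (13 rows per segment).
METRIC_SCOPE_ORDER: tuple[tuple[str, str], ...] = tuple(
    (metric, scope) for metric, scopes in METRIC_SCOPES.items() for scope in scopes
)


def _as_float_array(x, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != ndim:
        raise ValidationError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    return arr


def _check_strictly_increasing(t: np.ndarray, what: str) -> None:
    dt = np.diff(t)
    bad = np.nonzero(dt <= 0)[0]
    if bad.size:
        raise ValidationError(
            f"{what} timestamps not strictly increasing at index {int(bad[0]) + 1} "
            f"(t[{int(bad[0])}]={t[bad[0]]:.6f}, t[{int(bad[0]) + 1}]={t[bad[0] + 1]:.6f})"
        )


@dataclass
class KinematicTrace:
    """Uniformly sampled 3-D tool-tip pose series for one instrument.

    Positions are Cartesian coordinates in cm; optional orientations are
    Euler-style angle triplets in radians, stored pass-through (no metric
    uses them).  Samples whose coordinates were missing at ingestion are
    recorded in ``gap_indices`` and must be interpolated before derivative
    estimation.
    """

    instrument: Instrument
    sample_rate: float
    timestamps: np.ndarray
    positions: np.ndarray
    orientations: np.ndarray | None = None
    gap_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self):
        self.instrument = Instrument(self.instrument)
        self.timestamps = _as_float_array(self.timestamps, "timestamps", 1)
        self.positions = _as_float_array(self.positions, "positions", 2)
        n = self.timestamps.size
        if n < 2:
            raise ValidationError(f"kinematic trace needs >= 2 samples, got {n}")
        if self.positions.shape != (n, 3):
            raise ValidationError(
                f"positions shape {self.positions.shape} does not match ({n}, 3)"
            )
        _check_strictly_increasing(self.timestamps, "kinematic")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        nominal = 1.0 / self.sample_rate
        dev = np.abs(np.diff(self.timestamps) - nominal)
        if dev.max() > 0.01 * nominal:
            k = int(np.argmax(dev))
            raise ValidationError(
                f"inter-sample interval deviates {dev.max() / nominal:.1%} from "
                f"1/{self.sample_rate} Hz at index {k} (tolerance 1%)"
            )
        if self.orientations is not None:
            self.orientations = _as_float_array(self.orientations, "orientations", 2)
            if self.orientations.shape != (n, 3):
                raise ValidationError("orientations shape must match (n, 3)")
        self.gap_indices = np.asarray(self.gap_indices, dtype=int)
        non_gap = np.setdiff1d(np.arange(n), self.gap_indices)
        if not np.isfinite(self.positions[non_gap]).all():
            raise ValidationError("positions contain non-finite values outside flagged gaps")

    @property
    def n_samples(self) -> int:
        return self.timestamps.size

    @property
    def duration(self) -> float:
        return (self.n_samples - 1) / self.sample_rate

    @property
    def has_gaps(self) -> bool:
        return self.gap_indices.size > 0


@dataclass
class ForceTrace:
    """Per-finger (thumb, index, middle) force channels for one hand, in N."""

    hand: Hand
    sample_rate: float
    timestamps: np.ndarray
    channels: dict[str, np.ndarray]
    n_clipped: int = 0

    def __post_init__(self):
        self.hand = Hand(self.hand)
        self.timestamps = _as_float_array(self.timestamps, "timestamps", 1)
        _check_strictly_increasing(self.timestamps, "force")
        missing = [f for f in FINGERS if f not in self.channels]
        if missing:
            raise ValidationError(f"force trace missing finger channels: {missing}")
        n = self.timestamps.size
        chans = {}
        for finger in FINGERS:
            arr = _as_float_array(self.channels[finger], f"channel {finger}", 1)
            if arr.size != n:
                raise ValidationError(
                    f"channel {finger} length {arr.size} != timestamps length {n}"
                )
            if not np.isfinite(arr).all():
                raise ValidationError(f"channel {finger} contains non-finite values")
            if (arr < 0).any():
                raise ValidationError(
                    f"channel {finger} contains negative forces (clip at ingestion)"
                )
            chans[finger] = arr
        self.channels = chans

    @property
    def n_samples(self) -> int:
        return self.timestamps.size

    @property
    def duration(self) -> float:
        return (self.n_samples - 1) / self.sample_rate


@dataclass(frozen=True)
class SegmentAnnotation:
    """Half-open sample window [k0, kf) on the kinematic timeline."""

    segment_id: str
    k0: int
    kf: int
    t0: float
    tf: float

    def __post_init__(self):
        if self.segment_id not in SEGMENT_IDS:
            raise ValidationError(f"unknown segment id {self.segment_id!r}")
        if not (0 <= self.k0 < self.kf):
            raise ValidationError(
                f"{self.segment_id}: need 0 <= k0 < kf, got [{self.k0}, {self.kf})"
            )

    @classmethod
    def from_indices(cls, segment_id: str, k0: int, kf: int, trace: KinematicTrace):
        if kf > trace.n_samples:
            raise ValidationError(
                f"{segment_id}: kf={kf} exceeds trace length {trace.n_samples}"
            )
        t0 = float(trace.timestamps[k0])
        tf = float(trace.timestamps[kf - 1]) + 1.0 / trace.sample_rate
        return cls(segment_id, int(k0), int(kf), t0, tf)

    @property
    def n_samples(self) -> int:
        return self.kf - self.k0


def validate_segment_set(segments: list[SegmentAnnotation]) -> list[SegmentAnnotation]:
    """Check the four-segment invariant: S1..S4 present, ordered, disjoint."""
    ids = [s.segment_id for s in segments]
    if sorted(ids) != list(SEGMENT_IDS):
        raise ValidationError(f"expected exactly segments {SEGMENT_IDS}, got {ids}")
    ordered = sorted(segments, key=lambda s: SEGMENT_IDS.index(s.segment_id))
    for a, b in zip(ordered, ordered[1:]):
        if b.k0 < a.kf:
            raise ValidationError(
                f"segments overlap/out of order: {a.segment_id} ends at {a.kf}, "
                f"{b.segment_id} starts at {b.k0}"
            )
    return ordered


@dataclass
class TrialRecording:
    """One complete suturing trial: both instruments, both hands, four segments.

    Force traces may be ``None`` (e.g. a sensor failure); tactile metrics
    are then reported as missing while kinematic metrics still compute.
    """

    subject_id: str
    group: Group
    trial_index: int
    left_kin: KinematicTrace
    right_kin: KinematicTrace
    left_force: ForceTrace | None
    right_force: ForceTrace | None
    segments: list[SegmentAnnotation]
    ali_score: int | None = None

    def __post_init__(self):
        self.group = Group(self.group)
        if self.trial_index not in (1, 2, 3):
            raise ValidationError(f"trial_index must be 1..3, got {self.trial_index}")
        if self.ali_score is not None:
            if self.group is Group.NOVICE and not self.ali_score > 6:
                raise ValidationError(
                    f"novice requires ALI score > 6, got {self.ali_score}"
                )
            if self.group is Group.INTERMEDIATE and not 3 <= self.ali_score <= 6:
                raise ValidationError(
                    f"intermediate requires 3 <= ALI score <= 6, got {self.ali_score}"
                )
        self.segments = validate_segment_set(list(self.segments))
        for seg in self.segments:
            for trace in (self.left_kin, self.right_kin):
                if seg.kf > trace.n_samples:
                    raise ValidationError(
                        f"{seg.segment_id} window exceeds {trace.instrument.value} trace"
                    )


@dataclass(frozen=True)
class MetricValue:
    """One metric evaluated for one (subject, trial, segment, scope).

    ``value`` is NaN when the underlying signal is degenerate for that
    metric (e.g. a motionless tool has no defined smoothness).
    """

    metric: str
    scope: str
    segment_id: str
    subject_id: str
    group: Group
    trial_index: int
    value: float

    def __post_init__(self):
        if self.metric not in METRIC_SCOPES:
            raise ValidationError(f"unknown metric {self.metric!r}")
        if self.scope not in METRIC_SCOPES[self.metric]:
            raise ValidationError(
                f"scope {self.scope!r} is not legal for metric {self.metric!r} "
                f"(allowed: {METRIC_SCOPES[self.metric]})"
            )
        if self.segment_id not in SEGMENT_IDS:
            raise ValidationError(f"unknown segment id {self.segment_id!r}")
        object.__setattr__(self, "group", Group(self.group))

    @property
    def units(self) -> str:
        return METRIC_UNITS[self.metric]


@dataclass
class GroupComparisonResult:
    """Descriptives + normality-routed two-sample test for one metric cell."""

    metric: str
    scope: str
    segment_id: str
    n_novice: int
    n_intermediate: int
    excluded_novice: int
    excluded_intermediate: int
    median_novice: float
    iqr_novice: float
    median_intermediate: float
    iqr_intermediate: float
    normal_novice: bool
    normal_intermediate: bool
    test: str | None  # "t_test" | "wilcoxon_rank_sum" | None (not testable)
    statistic: float
    df: int
    p_value: float
    significant: bool

    @property
    def testable(self) -> bool:
        return self.test is not None
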