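"""Skill-profile presets for the synthetic cohort generator.

The shipped YAML (``presets/profiles.yaml``) holds the editable default
parameters: per-segment submovement schedules, idle fractions, tremor
amplitude, inter-hand lag and press-count distributions for the novice
and intermediate profiles.  ``default_profiles()`` loads them; pass a
different file to study other contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .datatypes import SEGMENT_IDS, ValidationError

__all__ = ["SegmentParams", "SkillProfile", "default_profiles", "load_profiles"]


@dataclass
class SegmentParams:
    """Submovement / idle / press parameters for one task segment."""

    n_sub_mean: float
    n_sub_sd: float
    amp_mean_cm: float
    amp_sd_cm: float
    dur_mean_s: float
    dur_sd_s: float
    idle_fraction: float
    press_left_mean: float
    press_left_sd: float
    press_right_mean: float
    press_right_sd: float

    def __post_init__(self):
        for name in ("n_sub_mean", "amp_mean_cm", "dur_mean_s"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"segment parameter {name} must be positive")
        if not 0 <= self.idle_fraction <= 0.9:
            raise ValidationError("idle_fraction must lie in [0, 0.9]")


@dataclass
class SkillProfile:
    """Everything the generator needs to emulate one proficiency level."""

    label: str
    tremor_amp_cm: float
    inter_hand_lag_s: float
    segments: dict[str, SegmentParams]
    tremor_band_hz: tuple[float, float] = (8.0, 12.0)
    press_width_s: float = 0.3
    workspace_halfwidth_cm: float = 1.5

    def __post_init__(self):
        missing = [s for s in SEGMENT_IDS if s not in self.segments]
        if missing:
            raise ValidationError(f"profile {self.label!r} missing segments {missing}")
        if self.tremor_amp_cm < 0 or self.press_width_s <= 0:
            raise ValidationError("tremor amplitude must be >= 0, press width > 0")


def _profile_from_dict(label: str, d: dict) -> SkillProfile:
    segs = {
        sid: SegmentParams(**params) for sid, params in d.get("segments", {}).items()
    }
    kwargs = {k: v for k, v in d.items() if k != "segments"}
    if "tremor_band_hz" in kwargs:
        kwargs["tremor_band_hz"] = tuple(kwargs["tremor_band_hz"])
    return SkillProfile(label=label, segments=segs, **kwargs)


def load_profiles(path) -> dict[str, SkillProfile]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {label: _profile_from_dict(label, d) for label, d in raw.items()}


def default_profiles() -> dict[str, SkillProfile]:
    ref = resources.files("surgskill") / "presets" / "profiles.yaml"
    with resources.as_file(ref) as path:
        return load_profiles(Path(path))
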