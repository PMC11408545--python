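"""Configuration blocks for the analysis pipeline.

All knobs the framework exposes live here, grouped by stage.  Every block
validates itself on construction and can be round-tripped through a plain
dict, so a single YAML file configures the whole run and is echoed into
every output for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field path."""


@dataclass
class SmoothingConfig:
    """Savitzky-Golay differentiation and gap-repair settings.

    The derivative filter uses polynomial order 3 over a 5-sample window;
    ``edge_mode`` selects how the half-window at each end is handled:
    ``interp`` fits the edge polynomial (length-preserving, default),
    ``mirror`` reflects the signal, ``truncate_to_valid`` drops the edges.
    """

    sg_order: int = 3
    sg_window: int = 5
    max_gap_s: float = 0.1
    edge_mode: str = "interp"

    def __post_init__(self):
        if self.sg_window % 2 == 0:
            raise ConfigError(f"smoothing.sg_window must be odd, got {self.sg_window}")
        if self.sg_window <= self.sg_order:
            raise ConfigError(
                f"smoothing.sg_window ({self.sg_window}) must exceed "
                f"smoothing.sg_order ({self.sg_order})"
            )
        if self.max_gap_s <= 0:
            raise ConfigError("smoothing.max_gap_s must be positive")
        if self.edge_mode not in ("interp", "mirror", "truncate_to_valid"):
            raise ConfigError(f"smoothing.edge_mode invalid: {self.edge_mode!r}")


@dataclass
class MetricConfig:
    """Kinematic-metric thresholds.

    ``v_star`` is the idle-speed threshold in cm/s below which a tool tip
    counts as motionless.  ``eov_zero_volume_policy`` decides whether a
    degenerate (zero-volume) bounding box yields economy-of-volume 0
    (``zero``) or a missing value (``not_a_value``).
    """

    v_star: float = 0.5
    ms_epsilon: float = 1e-12
    eov_zero_volume_policy: str = "zero"

    def __post_init__(self):
        if self.v_star <= 0:
            raise ConfigError("metrics.v_star must be positive")
        if self.eov_zero_volume_policy not in ("zero", "not_a_value"):
            raise ConfigError(
                f"metrics.eov_zero_volume_policy invalid: {self.eov_zero_volume_policy!r}"
            )


@dataclass
class PeakConfig:
    """Pinch-event detection on the hand activity signal."""

    min_prominence_fraction: float = 0.10
    min_separation_s: float = 0.25
    presmooth: bool = True

    def __post_init__(self):
        if not 0 < self.min_prominence_fraction < 1:
            raise ConfigError("peaks.min_prominence_fraction must lie in (0, 1)")
        if self.min_separation_s <= 0:
            raise ConfigError("peaks.min_separation_s must be positive")


@dataclass
class StatsConfig:
    """Group-comparison settings.

    ``pooling`` chooses the per-cell sample: every trial of every subject
    (``all_trials``, default, matching the study's implied n of 15 vs 18)
    or one mean per subject (``per_subject_mean``).  ``multiple_testing``
    optionally applies Benjamini-Hochberg across cells (off by default,
    matching the original analysis).

    ``outlier_scope`` sets where the Tukey fences come from:
    ``pooled_cell`` (default) derives one pair of fences from the cell's
    combined two-group sample — exclusion against the cell's overall
    pattern, which keeps the downstream tests calibrated at small n —
    while ``per_group`` fences each group by its own quartiles, which is
    known to inflate the false-positive rate of a subsequent two-sample
    test at these group sizes.
    """

    alpha: float = 0.05
    outlier_fence: float = 1.5
    outlier_scope: str = "pooled_cell"
    quantile_method: str = "linear"
    pooling: str = "all_trials"
    multiple_testing: str | None = None

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ConfigError("stats.alpha must lie in (0, 1)")
        if self.outlier_fence <= 0:
            raise ConfigError("stats.outlier_fence must be positive")
        if self.outlier_scope not in ("pooled_cell", "per_group"):
            raise ConfigError(f"stats.outlier_scope invalid: {self.outlier_scope!r}")
        if self.pooling not in ("all_trials", "per_subject_mean"):
            raise ConfigError(f"stats.pooling invalid: {self.pooling!r}")
        if self.multiple_testing not in (None, "fdr_bh"):
            raise ConfigError(f"stats.multiple_testing invalid: {self.multiple_testing!r}")


@dataclass
class RunConfig:
    """Aggregate configuration for a full pipeline run."""

    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    metrics: MetricConfig = field(default_factory=MetricConfig)
    peaks: PeakConfig = field(default_factory=PeakConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0

    _BLOCKS = {
        "smoothing": SmoothingConfig,
        "metrics": MetricConfig,
        "peaks": PeakConfig,
        "stats": StatsConfig,
    }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        for key, value in d.items():
            if key == "seed":
                kwargs["seed"] = int(value)
                continue
            block_cls = cls._BLOCKS.get(key)
            if block_cls is None:
                raise ConfigError(f"unknown config block {key!r}")
            if not isinstance(value, dict):
                raise ConfigError(f"{key}: expected a mapping of fields")
            names = {f.name for f in dataclasses.fields(block_cls)}
            for fname in value:
                if fname not in names:
                    raise ConfigError(f"{key}.{fname}: unknown field")
            kwargs[key] = block_cls(**value)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping at top level")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Short stable hash of the full configuration, for provenance."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
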