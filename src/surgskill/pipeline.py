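"""End-to-end drivers tying generation, metric extraction and statistics."""

from __future__ import annotations

import pandas as pd

from .config import RunConfig
from .datatypes import TrialRecording
from .io import metric_values_to_frame
from .kinematics import compute_segment_metrics
from .stats import SkillComparison, SkillComparisonResults

__all__ = ["trial_metric_frame", "cohort_metric_table", "compare_cohort"]


def trial_metric_frame(trial: TrialRecording, config: RunConfig | None = None) -> pd.DataFrame:
    """Score one trial into a 52-row long-format metric frame."""
    config = config or RunConfig()
    values = compute_segment_metrics(
        trial, config.smoothing, config.metrics, config.peaks
    )
    return metric_values_to_frame(values)


def cohort_metric_table(
    trials: list[TrialRecording], config: RunConfig | None = None
) -> pd.DataFrame:
    """Score every trial of a cohort into one long-format metric table."""
    config = config or RunConfig()
    frames = [trial_metric_frame(t, config) for t in trials]
    return pd.concat(frames, ignore_index=True)


def compare_cohort(
    metric_table: pd.DataFrame, config: RunConfig | None = None
) -> SkillComparisonResults:
    """Fit the group-comparison model on a metric table."""
    config = config or RunConfig()
    return SkillComparison(metric_table, config.stats).fit()
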