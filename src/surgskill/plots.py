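"""Box-plot reporting of per-cell metric distributions.

Mirrors the study's figure style: one box per (segment, group), red "+"
markers for Tukey outliers and filled green triangles for group means.
"""

from __future__ import annotations

import numpy as np

from .datatypes import METRIC_SCOPES, METRIC_UNITS, SEGMENT_IDS


def plot_metric_boxplots(metric_table, metric: str, scope: str, ax=None):
    """Per-segment novice/intermediate box plots for one metric cell."""
    import matplotlib.pyplot as plt

    if scope not in METRIC_SCOPES.get(metric, ()):
        raise ValueError(f"illegal scope {scope!r} for metric {metric!r}")
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    data, positions, colors = [], [], []
    for i, seg in enumerate(SEGMENT_IDS):
        for j, group in enumerate(("novice", "intermediate")):
            sel = metric_table[
                (metric_table["metric"] == metric)
                & (metric_table["scope"] == scope)
                & (metric_table["segment"] == seg)
                & (metric_table["group"] == group)
            ]["value"].to_numpy()
            data.append(sel[np.isfinite(sel)])
            positions.append(i * 2.5 + j)
            colors.append("tab:blue" if group == "novice" else "tab:orange")
    bp = ax.boxplot(
        data,
        positions=positions,
        widths=0.8,
        showmeans=True,
        patch_artist=True,
        flierprops=dict(marker="+", markeredgecolor="red"),
        meanprops=dict(
            marker="^", markerfacecolor="green", markeredgecolor="green"
        ),
    )
    for patch, color in zip(bp["boxes"], colors):
        patch.set_facecolor(color)
        patch.set_alpha(0.4)
    ax.set_xticks([i * 2.5 + 0.5 for i in range(len(SEGMENT_IDS))])
    ax.set_xticklabels([s.replace("S", "S.") for s in SEGMENT_IDS])
    ax.set_ylabel(f"{metric} [{METRIC_UNITS[metric]}]")
    ax.set_title(f"{metric} — {scope} (blue: novice, orange: intermediate)")
    return ax
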