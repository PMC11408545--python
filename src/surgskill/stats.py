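"""Group-comparison statistics: novice vs intermediate per metric cell.

For each (metric, scope, segment) cell the pipeline pools metric values
across subjects and trials, excludes Tukey-fence outliers (one pass),
summarises each group by median and interquartile range, gates on
Shapiro-Wilk normality, and routes to a two-sided independent t-test
(both groups normal) or a two-sided Wilcoxon rank-sum / Mann-Whitney
test otherwise.  Degrees of freedom are reported as n_N + n_I - 2 for
both routes, and significance is declared at alpha (default .05).

The model-style entry point is :class:`SkillComparison`, whose ``fit``
returns a :class:`SkillComparisonResults` with a summary table; the
functional surface (``compare_groups``, ``run_comparison_study``) wraps
the same machinery.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import StatsConfig
from .datatypes import (
    METRIC_SCOPE_ORDER,
    SEGMENT_IDS,
    GroupComparisonResult,
    ValidationError,
)
from .io import comparison_results_to_frame

__all__ = [
    "exclude_outliers",
    "exclude_outliers_pooled",
    "descriptives",
    "normality",
    "compare_groups",
    "run_comparison_study",
    "SkillComparison",
    "SkillComparisonResults",
]


def exclude_outliers(
    values: np.ndarray, cfg: StatsConfig | None = None
) -> tuple[np.ndarray, int]:
    """Drop values outside the Tukey fences [Q1 - c·IQR, Q3 + c·IQR].

    Single pass (fences are not recomputed after exclusion).  Samples
    with fewer than 4 values are returned unchanged with a warning.
    """
    cfg = cfg or StatsConfig()
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 4:
        warnings.warn(
            f"sample of n={values.size} too small for outlier exclusion; kept as is",
            stacklevel=2,
        )
        return values, 0
    q1, q3 = np.quantile(values, [0.25, 0.75], method=cfg.quantile_method)
    iqr = q3 - q1
    lo, hi = q1 - cfg.outlier_fence * iqr, q3 + cfg.outlier_fence * iqr
    keep = (values >= lo) & (values <= hi)
    return values[keep], int((~keep).sum())


def exclude_outliers_pooled(
    a: np.ndarray, b: np.ndarray, cfg: StatsConfig | None = None
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Exclude by Tukey fences computed on the combined two-group sample.

    One pair of fences for the whole cell: a value is an outlier if it is
    extreme relative to the cell's overall distribution.  Unlike fencing
    each group by its own quartiles, this leaves the false-positive rate
    of the downstream two-sample test at its nominal level for the small
    group sizes used here.  Single pass; pooled n < 4 excludes nothing.
    """
    cfg = cfg or StatsConfig()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    pool = np.concatenate([a, b])
    if pool.size < 4:
        return a, b, 0, 0
    q1, q3 = np.quantile(pool, [0.25, 0.75], method=cfg.quantile_method)
    iqr = q3 - q1
    lo, hi = q1 - cfg.outlier_fence * iqr, q3 + cfg.outlier_fence * iqr
    keep_a = (a >= lo) & (a <= hi)
    keep_b = (b >= lo) & (b <= hi)
    return a[keep_a], b[keep_b], int((~keep_a).sum()), int((~keep_b).sum())


def descriptives(
    values: np.ndarray, cfg: StatsConfig | None = None
) -> tuple[float, float]:
    """Median and interquartile range under the configured quantile convention."""
    cfg = cfg or StatsConfig()
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ValidationError("descriptives requires at least one value")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], method=cfg.quantile_method)
    return float(med), float(q3 - q1)


def normality(
    values: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, bool | None]:
    """Shapiro-Wilk normality check: (W, p, is_normal).

    ``is_normal`` is ``None`` when the test cannot be computed (n < 3 or
    a constant sample); the caller then routes to the rank-sum test.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3 or values.size > 5000 or np.ptp(values) == 0:
        return float("nan"), float("nan"), None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w, p = sps.shapiro(values)
    return float(w), float(p), bool(p > alpha)


def _ranksum_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Rank-sum z statistic (continuity- and tie-corrected) and its U1."""
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0, u1
    cc = 0.5 * np.sign(u1 - mu)
    z = (u1 - mu - cc) / math.sqrt(var)
    return float(z), float(u1)


def compare_groups(
    novice_values: np.ndarray,
    intermediate_values: np.ndarray,
    cfg: StatsConfig | None = None,
    metric: str = "",
    scope: str = "",
    segment_id: str = "S1",
    force_route: str | None = None,
) -> GroupComparisonResult:
    """Full comparison of one metric cell.

    Order of operations: outlier exclusion (pooled-cell fences by
    default, see :class:`StatsConfig`), descriptives,
    Shapiro-Wilk per group, then the routed two-sided test.  The t-route
    uses the pooled-variance independent t-test; the rank-sum route
    reports a z statistic (normal approximation with continuity and tie
    corrections) but takes its p-value from the exact null distribution
    whenever both samples are small and tie-free.

    ``force_route`` ("t_test" or "wilcoxon_rank_sum") bypasses the
    normality gate, e.g. to study the routes on a common fixture.
    """
    cfg = cfg or StatsConfig()
    if cfg.outlier_scope == "pooled_cell":
        nov, inter, excl_n, excl_i = exclude_outliers_pooled(
            novice_values, intermediate_values, cfg
        )
    else:
        nov, excl_n = exclude_outliers(novice_values, cfg)
        inter, excl_i = exclude_outliers(intermediate_values, cfg)
    n1, n2 = nov.size, inter.size
    df = n1 + n2 - 2

    med_n, iqr_n = descriptives(nov, cfg) if n1 else (float("nan"), float("nan"))
    med_i, iqr_i = descriptives(inter, cfg) if n2 else (float("nan"), float("nan"))

    base = dict(
        metric=metric,
        scope=scope,
        segment_id=segment_id,
        n_novice=n1,
        n_intermediate=n2,
        excluded_novice=excl_n,
        excluded_intermediate=excl_i,
        median_novice=med_n,
        iqr_novice=iqr_n,
        median_intermediate=med_i,
        iqr_intermediate=iqr_i,
    )
    if n1 < 3 or n2 < 3:
        return GroupComparisonResult(
            **base,
            normal_novice=False,
            normal_intermediate=False,
            test=None,
            statistic=float("nan"),
            df=df,
            p_value=float("nan"),
            significant=False,
        )

    _, _, norm_n = normality(nov, cfg.alpha)
    _, _, norm_i = normality(inter, cfg.alpha)
    both_normal = bool(norm_n) and bool(norm_i)
    if force_route is not None:
        if force_route not in ("t_test", "wilcoxon_rank_sum"):
            raise ValidationError(f"unknown route {force_route!r}")
        both_normal = force_route == "t_test"

    if both_normal:
        test = "t_test"
        stat, p = sps.ttest_ind(nov, inter, equal_var=True)
        stat, p = float(stat), float(p)
    else:
        test = "wilcoxon_rank_sum"
        res = sps.mannwhitneyu(nov, inter, alternative="two-sided", method="auto")
        p = float(res.pvalue)
        stat, _ = _ranksum_z(nov, inter)
    return GroupComparisonResult(
        **base,
        normal_novice=bool(norm_n),
        normal_intermediate=bool(norm_i),
        test=test,
        statistic=stat,
        df=df,
        p_value=p,
        significant=bool(p < cfg.alpha),
    )


def _pool(cell: pd.DataFrame, group: str, cfg: StatsConfig) -> np.ndarray:
    sub = cell[cell["group"] == group]
    if cfg.pooling == "per_subject_mean":
        vals = sub.groupby("subject_id")["value"].mean().to_numpy()
    else:
        vals = sub["value"].to_numpy()
    return vals[np.isfinite(vals)]


def run_comparison_study(
    metric_table: pd.DataFrame, cfg: StatsConfig | None = None
) -> list[GroupComparisonResult]:
    """Compare groups for every (metric, scope, segment) cell — 52 rows.

    Cells where either group is missing or too small are emitted as
    not-testable rows rather than dropped.  With ``multiple_testing``
    set to ``fdr_bh``, significance flags are recomputed from
    Benjamini-Hochberg-adjusted p-values across all testable cells.
    """
    cfg = cfg or StatsConfig()
    groups = set(metric_table["group"].unique())
    if not {"novice", "intermediate"} <= groups:
        raise ValidationError(
            f"metric table must contain both groups, found {sorted(groups)}"
        )
    results = []
    for metric, scope in METRIC_SCOPE_ORDER:
        for seg in SEGMENT_IDS:
            cell = metric_table[
                (metric_table["metric"] == metric)
                & (metric_table["scope"] == scope)
                & (metric_table["segment"] == seg)
            ]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                results.append(
                    compare_groups(
                        _pool(cell, "novice", cfg),
                        _pool(cell, "intermediate", cfg),
                        cfg,
                        metric=metric,
                        scope=scope,
                        segment_id=seg,
                    )
                )
    if cfg.multiple_testing == "fdr_bh":
        _apply_fdr(results, cfg.alpha)
    return results


def _apply_fdr(results: list[GroupComparisonResult], alpha: float) -> None:
    testable = [r for r in results if r.testable and np.isfinite(r.p_value)]
    m = len(testable)
    if not m:
        return
    order = np.argsort([r.p_value for r in testable])
    adjusted = np.empty(m)
    prev = 1.0
    for rank_pos, idx in enumerate(reversed(order), start=0):
        k = m - rank_pos
        val = min(prev, testable[idx].p_value * m / k)
        adjusted[idx] = val
        prev = val
    for r, p_adj in zip(testable, adjusted):
        r.significant = bool(p_adj < alpha)


# ---------------------------------------------------------------------------
# model-style wrapper


class SkillComparison:
    """Novice-vs-intermediate comparison model over a long-format metric table.

    Parameters
    ----------
    metric_table : DataFrame with columns subject_id, group, trial_index,
        segment, metric, scope, value (as written by the metrics stage).
    config : StatsConfig, optional.

    ``fit()`` runs the per-cell pipeline and returns a
    :class:`SkillComparisonResults`.
    """

    def __init__(self, metric_table: pd.DataFrame, config: StatsConfig | None = None):
        required = {"subject_id", "group", "segment", "metric", "scope", "value"}
        missing = required - set(metric_table.columns)
        if missing:
            raise ValidationError(f"metric table missing columns {sorted(missing)}")
        self.metric_table = metric_table
        self.config = config or StatsConfig()

    @classmethod
    def from_csv(cls, path, config: StatsConfig | None = None) -> "SkillComparison":
        from .io import read_metric_table

        return cls(read_metric_table(path), config)

    def fit(self) -> "SkillComparisonResults":
        results = run_comparison_study(self.metric_table, self.config)
        return SkillComparisonResults(self, results)


class SkillComparisonResults:
    """Fitted comparison study: 52 per-cell results with descriptives and tests."""

    def __init__(self, model: SkillComparison, results: list[GroupComparisonResult]):
        self.model = model
        self.results = results

    @property
    def frame(self) -> pd.DataFrame:
        return comparison_results_to_frame(self.results)

    def significant_cells(self) -> pd.DataFrame:
        df = self.frame
        return df[df["significant"]]

    def summary(self) -> str:
        """Human-readable per-cell table in M (IQR) style."""
        df = self.frame.copy()

        def fmt(row):
            return (
                f"{row['median_novice']:.2f} ({row['iqr_novice']:.2f}) vs "
                f"{row['median_intermediate']:.2f} ({row['iqr_intermediate']:.2f})"
            )

        df["novice vs intermediate, M (IQR)"] = df.apply(fmt, axis=1)
        df["p"] = df["p_value"].map(lambda p: f"{p:.3g}" if np.isfinite(p) else "n/a")
        df["sig"] = np.where(df["significant"], "*", "")
        cols = [
            "metric",
            "scope",
            "segment",
            "novice vs intermediate, M (IQR)",
            "test",
            "statistic",
            "df",
            "p",
            "sig",
        ]
        out = df[cols].copy()
        out["statistic"] = out["statistic"].map(
            lambda s: f"{s:.3f}" if np.isfinite(s) else "n/a"
        )
        alpha = self.model.config.alpha
        header = (
            "Skill group comparison (novice vs intermediate)\n"
            f"alpha={alpha}, pooling={self.model.config.pooling}, "
            f"quantiles={self.model.config.quantile_method}, "
            f"outlier fence={self.model.config.outlier_fence}xIQR\n"
        )
        return header + out.to_string(index=False)

    def to_csv(self, path) -> None:
        from .io import write_comparison_table

        write_comparison_table(self.results, path)

    def plot_boxplots(self, metric: str, scope: str, ax=None):
        from .plots import plot_metric_boxplots

        return plot_metric_boxplots(self.model.metric_table, metric, scope, ax=ax)
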