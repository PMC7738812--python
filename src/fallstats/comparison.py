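"""Between-dataset comparison of the mobility statistics.

For each movement slice (all ADLs vs falls, a generic movement class, a
single label such as "walking", or a body position) and each of the twelve
statistics, the feature series of the datasets are summarized with boxplot
statistics (1.5*IQR fences) and compared with a one-way ANOVA followed by
Tukey-Kramer post-hoc comparison intervals at confidence 1 - alpha: each
group mean is drawn with a half-width such that, for equal group sizes, two
means are declared significantly different exactly when the Tukey-Kramer
test rejects for that pair, i.e. when the intervals are disjoint.

Undefined feature values (NaN, from constant windows) are excluded listwise
per feature with a logged count; groups left with fewer than two defined
values are dropped with a logged reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "BoxplotStats",
    "AnovaResult",
    "PosthocComparison",
    "SliceResult",
    "ComparisonReport",
    "boxplot_stats",
    "one_way_anova",
    "posthoc_intervals",
    "compare_datasets",
]


@dataclass(frozen=True)
class BoxplotStats:
    """Five-number boxplot summary with 1.5*IQR outlier fences."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple
    n: int

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


@dataclass(frozen=True)
class AnovaResult:
    """Classical one-way between/within decomposition."""

    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    group_names: tuple
    group_means: tuple
    group_sizes: tuple
    degenerate: bool = False  # all values identical in every group


@dataclass(frozen=True)
class PosthocComparison:
    """Per-group comparison intervals and pairwise significance matrix."""

    group_names: tuple
    means: tuple
    half_widths: tuple
    alpha: float
    q_crit: float
    significant: np.ndarray  # boolean (k, k), symmetric, False diagonal

    def interval(self, i: int) -> tuple:
        return (self.means[i] - self.half_widths[i],
                self.means[i] + self.half_widths[i])


@dataclass(frozen=True)
class SliceResult:
    """All comparison output for one (slice, feature) cell."""

    slice_name: str
    feature: str
    boxplots: dict
    anova: AnovaResult
    posthoc: PosthocComparison
    n_undefined_excluded: int
    dropped_groups: tuple = ()


@dataclass
class ComparisonReport:
    """Comparison results over every slice x feature combination."""

    group_by: str
    alpha: float
    results: dict = field(default_factory=dict)  # (slice, feature) -> SliceResult
    skipped_slices: dict = field(default_factory=dict)  # slice -> reason

    def get(self, slice_name: str, feature: str) -> SliceResult:
        return self.results[(slice_name, feature)]

    @property
    def n_tests(self) -> int:
        return len(self.results)

    def to_frame(self) -> pd.DataFrame:
        """Flat table of test results (one row per slice x feature)."""
        rows = []
        for (slice_name, feature), res in self.results.items():
            rows.append(
                {
                    "slice": slice_name,
                    "feature": feature,
                    "f_stat": res.anova.f_stat,
                    "df_between": res.anova.df_between,
                    "df_within": res.anova.df_within,
                    "p_value": res.anova.p_value,
                    "groups": ";".join(res.anova.group_names),
                    "n_per_group": ";".join(str(n) for n in res.anova.group_sizes),
                    "n_undefined_excluded": res.n_undefined_excluded,
                    "n_significant_pairs": int(res.posthoc.significant.sum() // 2),
                }
            )
        return pd.DataFrame(rows)


def boxplot_stats(values) -> BoxplotStats:
    """Quartiles by linear interpolation of order statistics, 1.5*IQR fences.

    Whiskers attach to the most extreme data points inside the fences;
    everything strictly outside is an outlier.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("boxplot_stats needs at least one defined value")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    outliers = values[(values < lo_fence) | (values > hi_fence)]
    return BoxplotStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=tuple(float(v) for v in np.sort(outliers)),
        n=int(values.size),
    )


def _clean_groups(groups, names=None):
    cleaned, kept_names = [], []
    names = list(names) if names is not None else [str(i) for i in range(len(groups))]
    for name, g in zip(names, groups):
        arr = np.asarray(g, dtype=float)
        arr = arr[~np.isnan(arr)]
        cleaned.append(arr)
        kept_names.append(name)
    return cleaned, kept_names


def one_way_anova(groups, names=None) -> AnovaResult:
    """One-way fixed-effects ANOVA over ``groups`` (NaN entries dropped).

    When every value in every group is identical the decomposition is
    degenerate (0/0); the result is flagged rather than raised.
    """
    groups, names = _clean_groups(groups, names)
    if len(groups) < 2:
        raise ValueError("one_way_anova needs at least two groups")
    for name, g in zip(names, groups):
        if g.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 defined values")
    k = len(groups)
    sizes = tuple(int(g.size) for g in groups)
    means = tuple(float(g.mean()) for g in groups)
    df_between = k - 1
    df_within = int(sum(sizes)) - k
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return AnovaResult(
            f_stat=float("nan"), df_between=df_between, df_within=df_within,
            p_value=float("nan"), group_names=tuple(names), group_means=means,
            group_sizes=sizes, degenerate=True,
        )
    f_stat, p_value = stats.f_oneway(*groups)
    return AnovaResult(
        f_stat=float(f_stat), df_between=df_between, df_within=df_within,
        p_value=float(p_value), group_names=tuple(names), group_means=means,
        group_sizes=sizes,
    )


def posthoc_intervals(groups, alpha: float = 0.05, names=None) -> PosthocComparison:
    """Tukey-Kramer comparison intervals and disjoint-interval significance.

    Each group mean gets the half-width (q_crit / 2) * s_pooled / sqrt(n_i),
    with q_crit the studentized-range quantile at level alpha for k groups
    and the within-group degrees of freedom.  For equal group sizes the sum
    of two half-widths equals the Tukey-Kramer critical difference
    (q_crit / sqrt(2)) * s_pooled * sqrt(1/n_i + 1/n_j), so interval
    disjointness reproduces the pairwise test exactly; for unequal sizes it
    is the standard graphical approximation.  Significance is defined by
    disjointness.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    groups, names = _clean_groups(groups, names)
    if len(groups) < 2:
        raise ValueError("posthoc_intervals needs at least two groups")
    for name, g in zip(names, groups):
        if g.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 defined values")
    k = len(groups)
    sizes = np.array([g.size for g in groups])
    means = np.array([g.mean() for g in groups])
    df_within = int(sizes.sum()) - k
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    s_pooled = np.sqrt(ssw / df_within) if df_within > 0 else 0.0
    q_crit = float(stats.studentized_range.ppf(1.0 - alpha, k, df_within))
    half = (q_crit / 2.0) * s_pooled / np.sqrt(sizes)
    gap = np.abs(means[:, None] - means[None, :])
    significant = gap > (half[:, None] + half[None, :])
    np.fill_diagonal(significant, False)
    return PosthocComparison(
        group_names=tuple(names),
        means=tuple(float(m) for m in means),
        half_widths=tuple(float(h) for h in half),
        alpha=alpha,
        q_crit=q_crit,
        significant=significant,
    )


_ADL_CLASSES = {"basic", "standard", "sporting", "near_fall"}


def _slice_values(table: pd.DataFrame, group_by: str):
    """Yield (slice name, row mask) pairs for the requested grouping."""
    if group_by == "adl_fall":
        is_fall = table["activity_class"] == "fall"
        yield "adl", ~is_fall
        yield "fall", is_fall
        return
    column = {
        "activity_class": "activity_class",
        "activity_label": "activity_label",
        "position": "position",
    }.get(group_by)
    if column is None:
        raise ValueError(
            "group_by must be one of 'adl_fall', 'activity_class', "
            f"'activity_label', 'position'; got {group_by!r}"
        )
    for value in sorted(table[column].astype(str).unique()):
        yield value, table[column].astype(str) == value


def compare_datasets(
    feature_table: pd.DataFrame,
    group_by: str = "activity_class",
    alpha: float = 0.05,
    features=None,
    min_group_size: int = 2,
) -> ComparisonReport:
    """Run the full boxplot + ANOVA + post-hoc comparison per slice x feature.

    ``feature_table`` is the output of the extraction stage (one row per
    trace with a ``dataset`` column).  Slices with fewer than two eligible
    datasets are skipped with a logged reason.
    """
    if len(feature_table) == 0:
        raise ValueError("feature table is empty")
    features = list(features) if features is not None else list(FEATURE_NAMES)
    report = ComparisonReport(group_by=group_by, alpha=alpha)
    for slice_name, mask in _slice_values(feature_table, group_by):
        sub = feature_table[mask]
        datasets = sorted(sub["dataset"].astype(str).unique())
        if len(datasets) < 2:
            reason = (
                f"slice {slice_name!r}: only {len(datasets)} dataset(s) present"
            )
            logger.info("skipping %s", reason)
            report.skipped_slices[slice_name] = reason
            continue
        for feature in features:
            series = {
                d: sub.loc[sub["dataset"].astype(str) == d, feature].to_numpy()
                for d in datasets
            }
            n_undef = int(sum(np.isnan(v).sum() for v in series.values()))
            defined = {d: v[~np.isnan(v)] for d, v in series.items()}
            eligible = {d: v for d, v in defined.items() if v.size >= min_group_size}
            dropped = tuple(d for d in datasets if d not in eligible)
            if dropped:
                logger.info(
                    "slice %r feature %s: dropping %s (fewer than %d defined values)",
                    slice_name, feature, list(dropped), min_group_size,
                )
            if len(eligible) < 2:
                reason = (
                    f"slice {slice_name!r} feature {feature}: fewer than two "
                    "groups with enough defined values"
                )
                logger.info("skipping %s", reason)
                report.skipped_slices[f"{slice_name}/{feature}"] = reason
                continue
            names = list(eligible)
            groups = [eligible[d] for d in names]
            report.results[(slice_name, feature)] = SliceResult(
                slice_name=slice_name,
                feature=feature,
                boxplots={d: boxplot_stats(eligible[d]) for d in names},
                anova=one_way_anova(groups, names=names),
                posthoc=posthoc_intervals(groups, alpha=alpha, names=names),
                n_undefined_excluded=n_undef,
                dropped_groups=dropped,
            )
    return report
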