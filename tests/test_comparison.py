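"""Boxplot summaries, one-way ANOVA, and Tukey-Kramer post-hoc intervals."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fallstats.comparison import (
    boxplot_stats,
    compare_datasets,
    one_way_anova,
    posthoc_intervals,
)


def test_boxplot_hand_example():
    b = boxplot_stats([1, 2, 3, 4, 100])
    assert (b.median, b.q1, b.q3) == (3.0, 2.0, 4.0)
    assert b.outliers == (100.0,)  # upper fence 4 + 1.5*2 = 7
    assert (b.whisker_low, b.whisker_high) == (1.0, 4.0)


def test_boxplot_constant_series():
    b = boxplot_stats([2.5] * 9)
    assert b.median == b.q1 == b.q3 == 2.5
    assert b.outliers == ()


def test_boxplot_symmetric_series_median_equals_mean(rng):
    half = rng.normal(0, 1, 200)
    values = np.concatenate([half, -half])
    b = boxplot_stats(values)
    assert b.median == pytest.approx(values.mean(), abs=1e-12)
    assert b.q1 <= b.median <= b.q3


def test_boxplot_empty_errors():
    with pytest.raises(ValueError):
        boxplot_stats([])
    with pytest.raises(ValueError):
        boxplot_stats([np.nan])


def test_anova_closed_form_two_groups():
    res = one_way_anova([[1, 2, 3], [4, 5, 6]])
    assert res.f_stat == pytest.approx(13.5)
    assert (res.df_between, res.df_within) == (1, 4)
    assert res.group_means == (2.0, 5.0)


def test_anova_identical_groups_gives_zero_f():
    res = one_way_anova([[1, 2, 3], [1, 2, 3]])
    assert res.f_stat == pytest.approx(0.0)


def test_anova_all_constant_is_degenerate_not_exception():
    res = one_way_anova([[2, 2, 2], [2, 2, 2]])
    assert res.degenerate
    assert np.isnan(res.f_stat)


def test_anova_shift_invariant_and_scale_invariant(rng):
    groups = [rng.normal(m, 1, 15) for m in (0, 0.5, 1)]
    base = one_way_anova(groups).f_stat
    shifted = one_way_anova([g + 100 for g in groups]).f_stat
    scaled = one_way_anova([3 * g for g in groups]).f_stat
    assert shifted == pytest.approx(base, rel=1e-9)
    assert scaled == pytest.approx(base, rel=1e-9)


def test_anova_two_groups_equals_squared_t(rng):
    a, b = rng.normal(0, 1, 20), rng.normal(0.7, 1, 25)
    f = one_way_anova([a, b]).f_stat
    t = stats.ttest_ind(a, b, equal_var=True).statistic
    assert f == pytest.approx(t**2, rel=1e-9)


def test_anova_type_one_error_within_binomial_ci(rng):
    # 2000 homogeneous replicates, k=4 groups of 10 standard normals
    reps, k, n = 2000, 4, 10
    data = rng.normal(size=(k, n, reps))
    f, p = stats.f_oneway(*data, axis=0)
    rate = float(np.mean(p < 0.05))
    half = 2.576 * np.sqrt(0.05 * 0.95 / reps)
    assert abs(rate - 0.05) <= half


def test_posthoc_identical_groups_not_significant():
    ph = posthoc_intervals([[1, 2, 3, 4], [1, 2, 3, 4]])
    assert not ph.significant.any()


def test_posthoc_large_separation_is_significant(rng):
    a = rng.normal(0, 1, 100)
    b = rng.normal(10, 1, 100)  # ten pooled SDs apart
    ph = posthoc_intervals([a, b])
    assert ph.significant[0, 1] and ph.significant[1, 0]


def test_posthoc_matrix_symmetric_false_diagonal(rng):
    groups = [rng.normal(m, 1, 12) for m in (0, 0.3, 2.5)]
    ph = posthoc_intervals(groups)
    assert np.array_equal(ph.significant, ph.significant.T)
    assert not ph.significant.diagonal().any()


def test_posthoc_disjointness_matches_tukey_for_equal_n(rng):
    """Interval-disjointness decisions replicate pairwise Tukey HSD tests."""
    alpha = 0.05
    for _ in range(40):
        k = int(rng.integers(2, 6))
        n = int(rng.integers(5, 30))
        spread = rng.uniform(0, 2)
        groups = [rng.normal(rng.normal(0, spread), 1, n) for _ in range(k)]
        ph = posthoc_intervals(groups, alpha=alpha)
        oracle = stats.tukey_hsd(*groups)
        for i in range(k):
            for j in range(i + 1, k):
                assert bool(ph.significant[i, j]) == bool(
                    oracle.pvalue[i, j] < alpha
                ), (k, n, i, j)


def test_posthoc_significance_implies_positive_interval_gap(rng):
    groups = [rng.normal(m, 1, 14) for m in (0, 1, 2, 5)]
    ph = posthoc_intervals(groups)
    for i in range(4):
        for j in range(4):
            if ph.significant[i, j]:
                lo_i, hi_i = ph.interval(i)
                lo_j, hi_j = ph.interval(j)
                assert max(lo_i, lo_j) > min(hi_i, hi_j)


def _feature_frame(rng, datasets, shift=0.0, n=30):
    rows = []
    for d_idx, name in enumerate(datasets):
        mu = shift if d_idx == 0 else 0.0
        for i in range(n):
            rows.append(
                dict(trace_id=f"{name}-{i}", dataset=name, position="waist",
                     activity_label="fall forward", activity_class="fall",
                     smv_max=rng.normal(5 + mu, 1), energy=rng.normal(40, 5),
                     mu_smv=rng.normal(1.5, 0.2))
            )
    return pd.DataFrame(rows)


def test_compare_datasets_flags_shifted_dataset(rng):
    table = _feature_frame(rng, ["A", "B", "C"], shift=4.0)
    report = compare_datasets(table, group_by="adl_fall",
                              features=["smv_max", "energy", "mu_smv"])
    res = report.get("fall", "smv_max")
    i = res.posthoc.group_names.index("A")
    assert all(res.posthoc.significant[i, j]
               for j in range(3) if j != i)


def test_compare_datasets_single_dataset_slice_is_skipped(rng, caplog):
    import logging

    table = _feature_frame(rng, ["only"], n=10)
    with caplog.at_level(logging.INFO, logger="fallstats.comparison"):
        report = compare_datasets(table, features=["smv_max"])
    assert report.n_tests == 0
    assert report.skipped_slices


def test_compare_datasets_excludes_undefined_values(rng):
    table = _feature_frame(rng, ["A", "B"], n=20)
    table.loc[table.index[:5], "smv_max"] = np.nan
    report = compare_datasets(table, group_by="adl_fall", features=["smv_max"])
    res = report.get("fall", "smv_max")
    assert res.n_undefined_excluded == 5
    assert res.anova.group_sizes == (15, 20)


def test_compare_datasets_empty_table_errors():
    with pytest.raises(ValueError):
        compare_datasets(pd.DataFrame())
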