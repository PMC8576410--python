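"""Statistical battery: exactness, calibration, and definitional checks."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from vtsubstrate.stats import (
    dunn_bonferroni,
    group_summary,
    kruskal_wallis,
    mann_whitney,
    normality_test,
    paired_t,
    pearson,
)


def test_shapiro_on_normal_quantiles():
    q = sps.norm.ppf((np.arange(50) + 0.5) / 50)
    res = normality_test(q)
    assert res.statistic > 0.99
    assert res.method == "shapiro-wilk"


def test_shapiro_detects_uniform():
    x = np.random.default_rng(8).uniform(size=500)
    assert normality_test(x).p_value < 0.05


def test_shapiro_input_validation():
    with pytest.raises(ValueError):
        normality_test([1.0, 2.0])
    with pytest.raises(ValueError):
        normality_test(np.ones(10))


def test_mann_whitney_exact_separated_groups():
    """Fully separated groups of 3: U=0, exact two-tailed p = 2/20 = 0.1."""
    res = mann_whitney([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(0.1)
    assert res.method == "mann-whitney-exact"


def test_mann_whitney_identical_groups():
    x = np.arange(30.0)
    res = mann_whitney(x, x)
    assert res.p_value == pytest.approx(1.0, abs=0.01)


def test_mann_whitney_exact_matches_independent_enumeration():
    """Cross-check the exact p against a U-statistic-counting oracle."""
    rng = np.random.default_rng(17)
    for trial in range(5):
        a = np.round(rng.uniform(0, 10, size=7), 1)
        b = np.round(rng.uniform(0, 10, size=6), 1)
        res = mann_whitney(a, b)
        # oracle: U counted as #pairs a>b + half-ties, over all C(13,7) splits
        pooled = np.concatenate([a, b])

        def u_stat(group_a, group_b):
            diff = group_a[:, None] - group_b[None, :]
            return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))

        u_obs = u_stat(a, b)
        n = len(pooled)
        us = []
        for idx in combinations(range(n), len(a)):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            us.append(u_stat(pooled[mask], pooled[~mask]))
        us = np.asarray(us)
        lo = np.mean(us <= u_obs + 1e-12)
        hi = np.mean(us >= u_obs - 1e-12)
        p_oracle = min(1.0, 2.0 * min(lo, hi))
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)


def test_mann_whitney_exact_close_to_normal_approximation():
    rng = np.random.default_rng(18)
    a = rng.normal(size=8)
    b = rng.normal(0.5, 1.0, size=8)
    exact = mann_whitney(a, b).p_value
    approx = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    assert abs(exact - float(approx.pvalue)) < 0.02


def test_kruskal_identical_groups_and_dunn():
    g = [1.0, 2.0, 3.0]
    res = kruskal_wallis([g, g, g])
    assert res.statistic == pytest.approx(0.0)
    table = dunn_bonferroni([g, g, g])
    assert np.allclose(table.p_adjusted, 1.0)
    assert np.allclose(table.z, 0.0)


def test_kruskal_against_direct_rank_formula():
    groups = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]]
    res = kruskal_wallis(groups)
    # direct computation: no ties, H = 12/(N(N+1)) * sum n_i (Rbar_i - Rbar)^2
    n = 9
    rank_sums = [6, 15, 24]
    h_direct = 12.0 / (n * (n + 1)) * sum(rs**2 / 3 for rs in rank_sums) - 3 * (n + 1)
    assert res.statistic == pytest.approx(h_direct)
    table = dunn_bonferroni(groups)
    # mean-rank ordering is preserved in the z signs
    assert table.z.iloc[0] < 0  # group0 vs group1
    assert table.z.iloc[1] < 0  # group0 vs group2
    assert np.all(table.p_adjusted == np.minimum(1.0, table.p_raw * 3))
    assert np.all(table.p_adjusted >= table.p_raw)


def test_dunn_requires_three_groups():
    with pytest.raises(ValueError):
        dunn_bonferroni([[1.0], [2.0]])


def test_paired_t_definitions():
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    b = a - np.array([0.5, 1.5, 0.2, 0.8, 1.0])
    res = paired_t(a, b)
    d = a - b
    assert res.extra["mean_difference"] == pytest.approx(d.mean())
    lo, hi = res.extra["ci95"]
    assert lo < d.mean() < hi
    with pytest.raises(ValueError):
        paired_t(a, a)  # zero-variance differences
    with pytest.raises(ValueError):
        paired_t(a, b[:3])


def test_paired_t_ci_coverage():
    """The 95% CI covers the true mean difference ~95% of the time."""
    rng = np.random.default_rng(19)
    mu = 0.7
    n_rep, n = 10000, 10
    d = rng.normal(mu, 1.0, size=(n_rep, n))
    mean = d.mean(axis=1)
    se = d.std(axis=1, ddof=1) / np.sqrt(n)
    tcrit = sps.t.ppf(0.975, n - 1)
    covered = np.mean((mean - tcrit * se <= mu) & (mu <= mean + tcrit * se))
    assert abs(covered - 0.95) < 0.01
    # spot-check that paired_t produces the same CI construction
    res = paired_t(d[0], np.zeros(n))
    lo, hi = res.extra["ci95"]
    assert lo == pytest.approx(mean[0] - tcrit * se[0])
    assert hi == pytest.approx(mean[0] + tcrit * se[0])


def test_pearson_perfect_negative():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    res = pearson(x, -2.0 * x)
    assert res.statistic == pytest.approx(-1.0)
    assert res.extra["r2"] == pytest.approx(1.0)


def test_group_summary_medians_and_iqr():
    import pandas as pd

    values = pd.Series([1.0, 2.0, 3.0, 10.0, 20.0, 30.0])
    groups = pd.Series(["a", "a", "a", "b", "b", "b"])
    table = group_summary(values, groups).set_index("group")
    assert table.loc["a", "median"] == 2.0
    assert table.loc["b", "median"] == 20.0
    assert table.loc["a", "n"] == 3
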