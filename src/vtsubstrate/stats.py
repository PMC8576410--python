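"""Statistical battery for comparing structural metrics across point groups.

Continuous metrics pooled over mapped points are rarely normal, so the
workflow is: Shapiro–Wilk for normality, medians with interquartile ranges
for description, Mann–Whitney U (two groups) or Kruskal–Wallis H (three or
more) for comparison, with Dunn's (1964) pairwise z-tests under a
Bonferroni correction when the omnibus test is followed up.  Paired normal
data use the paired t-test; association uses Pearson's r.

Ties are handled with mid-ranks and tie-corrected variances throughout.
The Mann–Whitney p-value is computed by exact enumeration of all
C(n1+n2, n1) group assignments for combined samples up to 16 observations
(valid under ties as well), and by the tie-corrected normal approximation
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_ENUMERATION_MAX_N = 16


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    extra: dict | None = None


def normality_test(sample) -> TestResult:
    """Shapiro–Wilk W and p for a single sample (3 <= n <= 5000)."""
    x = np.asarray(sample, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError(f"Shapiro–Wilk requires 3 <= n <= 5000, got n={len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("sample is constant; normality test undefined")
    w, p = sps.shapiro(x)
    return TestResult(float(w), float(p), "shapiro-wilk")


def mann_whitney(group_a, group_b) -> TestResult:
    """Two-tailed Mann–Whitney U test.

    Exact enumeration for n1 + n2 <= 16; tie-corrected normal
    approximation (with continuity correction) above that.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = len(a), len(b)
    if n1 + n2 <= EXACT_ENUMERATION_MAX_N:
        u, p = _mann_whitney_exact(a, b)
        return TestResult(u, p, "mann-whitney-exact")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return TestResult(float(res.statistic), float(res.pvalue), "mann-whitney-normal")


def _mann_whitney_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-tailed p by enumerating every split of the pooled sample.

    Mid-ranks make the enumeration valid in the presence of ties.  The
    two-tailed p doubles the smaller tail probability (capped at 1).
    """
    pooled = np.concatenate([a, b])
    n = len(pooled)
    n1 = len(a)
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    u_values = []
    for idx in combinations(range(n), n1):
        u_values.append(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0)
    u_values = np.asarray(u_values)
    m = len(u_values)
    lo = float(np.sum(u_values <= u_obs + 1e-12)) / m
    hi = float(np.sum(u_values >= u_obs - 1e-12)) / m
    p = min(1.0, 2.0 * min(lo, hi))
    return u_obs, p


def kruskal_wallis(groups: list) -> TestResult:
    """Kruskal–Wallis H with tie correction and chi-square p-value."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in arrays):
        raise ValueError("all groups must be nonempty")
    h, p = sps.kruskal(*arrays)
    return TestResult(float(h), float(p), "kruskal-wallis")


def dunn_bonferroni(groups: list, labels: list | None = None) -> pd.DataFrame:
    """Dunn's (1964) pairwise post-hoc z-tests with Bonferroni correction.

    z for groups i, j compares mean ranks in the pooled ranking with the
    pooled tie-corrected variance; adjusted p = min(1, raw * k) with k the
    number of pairs, as reported alongside a significant Kruskal–Wallis H.
    """
    if len(groups) < 3:
        raise ValueError("Dunn post-hoc requires at least 3 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in arrays):
        raise ValueError("all groups must be nonempty")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]

    pooled = np.concatenate(arrays)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    sizes = [len(g) for g in arrays]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(arrays))
    ]
    # tie correction term: sum over tied groups of (t^3 - t)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))

    k = len(arrays) * (len(arrays) - 1) // 2
    rows = []
    for i, j in combinations(range(len(arrays)), 2):
        se = np.sqrt(
            (n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1)))
            * (1.0 / sizes[i] + 1.0 / sizes[j])
        )
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "z": float(z),
                "p_raw": float(p_raw),
                "p_adjusted": float(min(1.0, p_raw * k)),
            }
        )
    return pd.DataFrame(rows)


def paired_t(sample_a, sample_b) -> TestResult:
    """Two-tailed paired t-test with the 95% CI of the mean difference."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    if len(a) < 3:
        raise ValueError("need n >= 3 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("differences have zero variance; t undefined")
    t, p = sps.ttest_rel(a, b)
    df = len(d) - 1
    se = d.std(ddof=1) / np.sqrt(len(d))
    tcrit = sps.t.ppf(0.975, df)
    ci = (float(d.mean() - tcrit * se), float(d.mean() + tcrit * se))
    return TestResult(
        float(t),
        float(p),
        "paired-t",
        extra={"df": df, "mean_difference": float(d.mean()), "ci95": ci},
    )


def pearson(x, y) -> TestResult:
    """Pearson correlation: r, r² and two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples of equal length, n >= 3")
    r, p = sps.pearsonr(x, y)
    return TestResult(float(r), float(p), "pearson", extra={"r2": float(r**2)})


def group_summary(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Medians with IQRs per group, the field's standard descriptive table."""
    df = pd.DataFrame({"value": values, "group": groups}).dropna()
    df = df[np.isfinite(df["value"])]
    out = (
        df.groupby("group")["value"]
        .agg(
            n="count",
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
            mean="mean",
            sd="std",
        )
        .reset_index()
    )
    return out
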