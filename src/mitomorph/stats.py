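"""Normality-driven two-group comparison and related tests.

The routing rule used for every cell- or animal-level metric:

1. test each sample for normality — Shapiro–Wilk when n < 50,
   D'Agostino–Pearson when n ≥ 50 (alpha 0.05);
2. if both samples pass, compare variances with an F test: equal variances →
   two-tailed unpaired t-test, unequal → Welch's t-test;
3. if either sample fails normality → two-tailed Mann–Whitney U.

Every decision is recorded in an ordered trace so a comparison can be
audited.  Cumulative length distributions are compared with the two-sample
Kolmogorov–Smirnov test, and fold-change data across ≥3 groups with
Kruskal–Wallis followed by Dunn's post-hoc test (Bonferroni-adjusted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "compare_groups", "ks_compare", "kruskal_dunn", "significance_stars"]


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    decision_trace: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)


def significance_stars(p: float) -> str:
    """Star notation at the conventional 0.05 / 0.01 / 0.001 thresholds."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _normality(x: np.ndarray, alpha: float, trace: list[str], label: str) -> bool:
    n = len(x)
    if np.ptp(x) == 0:
        trace.append(f"{label}: constant sample (n={n}) -> treated non-Gaussian")
        return False
    if n < 50:
        stat, p = sps.shapiro(x)
        test = "shapiro_wilk"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p = sps.normaltest(x)
        test = "dagostino_pearson"
    gaussian = p > alpha
    trace.append(
        f"{label}: {test} n={n} p={p:.4g} -> {'Gaussian' if gaussian else 'non-Gaussian'}"
    )
    return gaussian


def _f_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided F test of equality of variances."""
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if vx >= vy:
        f, dfn, dfd = vx / vy, len(x) - 1, len(y) - 1
    else:
        f, dfn, dfd = vy / vx, len(y) - 1, len(x) - 1
    p = 2.0 * sps.f.sf(f, dfn, dfd)
    return float(f), float(min(p, 1.0))


def compare_groups(x, y, alpha: float = 0.05) -> TestResult:
    """Compare two independent samples with the routing rule above."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError(f"each sample needs n >= 3, got {len(x)} and {len(y)}")
    trace: list[str] = []
    gx = _normality(x, alpha, trace, "sample_x")
    gy = _normality(y, alpha, trace, "sample_y")
    if gx and gy:
        fstat, fp = _f_test(x, y)
        equal_var = fp > alpha
        trace.append(
            f"f_test p={fp:.4g} -> {'equal' if equal_var else 'unequal'} variances"
        )
        stat, p = sps.ttest_ind(x, y, equal_var=equal_var)
        name = "t_test" if equal_var else "welch_t"
        trace.append(f"selected {name}")
        extra = {"f_statistic": fstat, "f_p": fp}
    else:
        stat, p = sps.mannwhitneyu(x, y, alternative="two-sided")
        name = "mann_whitney"
        trace.append("selected mann_whitney (non-Gaussian sample)")
        extra = {}
    return TestResult(
        test_name=name,
        statistic=float(stat),
        p_value=float(p),
        n_per_group=(len(x), len(y)),
        decision_trace=trace,
        extra=extra,
    )


def ks_compare(x, y) -> TestResult:
    """Two-sample Kolmogorov–Smirnov test on cumulative distributions."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError(f"each sample needs n >= 3, got {len(x)} and {len(y)}")
    res = sps.ks_2samp(x, y, method="asymp")
    return TestResult(
        test_name="ks",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group=(len(x), len(y)),
        decision_trace=["two-sample KS on cumulative distributions"],
    )


def kruskal_dunn(groups: dict[str, np.ndarray], alpha: float = 0.05) -> TestResult:
    """Kruskal–Wallis across ≥3 groups with Dunn's Bonferroni post-hoc.

    Dunn's z statistics are computed from mean ranks of the pooled sample
    with the standard tie correction; pairwise p-values are Bonferroni
    adjusted and returned in ``extra['dunn']``.
    """
    names = list(groups)
    if len(names) < 3:
        raise ValueError("Kruskal–Wallis + Dunn path expects >= 3 groups")
    samples = [np.asarray(groups[k], dtype=float) for k in names]
    hstat, hp = sps.kruskal(*samples)
    pooled = np.concatenate(samples)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    # tie correction term for the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1))
    idx = np.cumsum([0] + [len(s) for s in samples])
    mean_ranks = {
        k: float(ranks[idx[i] : idx[i + 1]].mean()) for i, k in enumerate(names)
    }
    m = len(names) * (len(names) - 1) // 2
    dunn: dict[str, dict[str, float]] = {}
    for a, b in combinations(names, 2):
        na, nb = len(groups[a]), len(groups[b])
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p_adj = min(1.0, 2.0 * sps.norm.sf(abs(z)) * m)
        dunn[f"{a}|{b}"] = {"z": float(z), "p_adj": float(p_adj)}
    trace = [
        f"kruskal_wallis H={hstat:.4g} p={hp:.4g}",
        f"dunn post-hoc, bonferroni x{m}",
    ]
    return TestResult(
        test_name="kruskal_dunn",
        statistic=float(hstat),
        p_value=float(hp),
        n_per_group=tuple(len(s) for s in samples),
        decision_trace=trace,
        extra={"dunn": dunn, "mean_ranks": mean_ranks},
    )
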