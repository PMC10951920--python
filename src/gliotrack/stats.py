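"""Nonparametric group comparison: summaries, KS, Kruskal-Wallis, Dunn.

The analysis never assumes normality (a one-sample KS screen against a
fitted Normal is provided to justify that choice); group location is
summarized as median + IQR with a distribution-free 95% CI for the median,
multi-group differences are tested by Kruskal-Wallis with Dunn's post hoc,
and whole distributions are compared pairwise by the two-sample KS test with
a Bonferroni-corrected alpha.

Two replication levels are supported by the callers: per-particle (tracks as
replicates) and per-cell (cell medians as replicates); a single test never
mixes them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "group_summary",
    "ks_two_sample",
    "ks_normality",
    "kruskal_wallis",
    "dunns_posthoc",
    "bonferroni_alpha",
]


@dataclass(frozen=True)
class GroupSummary:
    n: int
    median: float
    q1: float
    q3: float
    ci95_lo: float
    ci95_hi: float


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: int | None = None
    alpha_used: float | None = None
    corrected: bool = False
    name: str = ""


def group_summary(values) -> GroupSummary:
    """Median, IQR (linear-interpolation quartiles) and a distribution-free
    95% CI for the median.

    The CI uses the binomial order-statistic method: the widest symmetric
    pair of order statistics (x_(k), x_(n+1-k)) whose binomial coverage is
    >= 95%.  It is conservative; for very small n the sample extremes are
    returned (coverage may then fall below 95%, which is unavoidable).
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n == 0:
        raise ValueError("group_summary needs n >= 1")
    median = float(np.median(v))
    q1, q3 = (float(q) for q in np.quantile(v, [0.25, 0.75]))
    if n == 1:
        return GroupSummary(1, median, q1, q3, median, median)
    # largest k with P(k <= X <= n-k) >= 0.95, X ~ Bin(n, 1/2)
    k_best = 1
    for k in range(1, n // 2 + 1):
        cover = sps.binom.cdf(n - k, n, 0.5) - sps.binom.cdf(k - 1, n, 0.5)
        if cover >= 0.95:
            k_best = k
        else:
            break
    return GroupSummary(n, median, q1, q3, float(v[k_best - 1]), float(v[n - k_best]))


def ks_two_sample(a, b, alpha: float | None = None, corrected: bool = False) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p).

    D is the supremum over the pooled sample of |ECDF_a - ECDF_b|; the
    p-value comes from the asymptotic Kolmogorov distribution at the
    effective sample size n_a*n_b/(n_a+n_b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("ks_two_sample needs both samples non-empty")
    res = sps.ks_2samp(a, b, method="asymp")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        alpha_used=alpha,
        corrected=corrected,
        name="ks_two_sample",
    )


def ks_normality(values) -> TestResult:
    """One-sample KS screen against a Normal fitted to the sample.

    The p-value is approximate (no Lilliefors correction for the estimated
    parameters) and intentionally so: it is only a routing screen toward
    nonparametric tests, never a reported inference.  A constant sample is
    degenerate and rejects outright.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 4:
        raise ValueError("ks_normality needs n >= 4")
    sd = v.std(ddof=1)
    if sd == 0:
        return TestResult(statistic=1.0, p_value=0.0, name="ks_normality")
    res = sps.kstest(v, "norm", args=(v.mean(), sd))
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue), name="ks_normality")


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H (mid-rank ties, tie-corrected), chi-square p, k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("kruskal_wallis needs >= 2 non-empty groups")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult(statistic=0.0, p_value=1.0, df=df, name="kruskal_wallis")
    h, p = sps.kruskal(*groups)
    return TestResult(statistic=float(h), p_value=float(p), df=df, name="kruskal_wallis")


def dunns_posthoc(groups, labels=None, alpha: float = 0.05) -> dict[tuple, TestResult]:
    """Dunn's multiple-comparison test after Kruskal-Wallis.

    For each pair (i, j): z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) *
    (1/n_i + 1/n_j)) with tie term T = sum(t^3 - t) / (12 (N - 1)); two-sided
    normal p, Bonferroni-adjusted over all k(k-1)/2 pairs (standard Dunn).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("dunns_posthoc: every group must be non-empty")
    if labels is None:
        labels = list(range(len(groups)))
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)  # mid-ranks
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        start += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1))) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term

    n_pairs = len(groups) * (len(groups) - 1) // 2
    out: dict[tuple, TestResult] = {}
    for i, j in combinations(range(len(groups)), 2):
        se = math.sqrt(var_base * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = 2.0 * sps.norm.sf(abs(z))
        out[(labels[i], labels[j])] = TestResult(
            statistic=float(z),
            p_value=float(min(p_raw * n_pairs, 1.0)),
            alpha_used=alpha,
            corrected=True,
            name="dunn",
        )
    return out


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """Corrected significance level: alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
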