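"""Nonparametric group comparisons for clonal statistics.

The battery mirrors common practice for small clonal cohorts: a
Lilliefors-corrected Kolmogorov-Smirnov normality gate (Dallal-Wilkinson
p-value approximation), then rank tests — Mann-Whitney U for two groups,
Kruskal-Wallis H for more.  The gate is informative only: the reported
comparisons are always the nonparametric ones, since clonal size and
dispersion data are typically non-Gaussian.  Significance stars follow the
usual 0.05 / 0.01 / 0.001 levels.

Small samples get exact p-values: Mann-Whitney by the exact U distribution
(n <= 8 per group, no ties), Kruskal-Wallis by exhaustive permutation of
group assignments (total n <= 10).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

EXACT_MW_MAX_N = 8
EXACT_KW_MAX_N = 10


@dataclass(frozen=True)
class TestResult:
    """Outcome of one statistical test."""

    method: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    exact: bool
    assessable: bool = True

    @property
    def stars(self) -> str:
        if not self.assessable or not np.isfinite(self.p_value):
            return "n/a"
        if self.p_value < 0.001:
            return "***"
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return "ns"

    def __str__(self) -> str:  # CLI-friendly one-liner
        n = ",".join(str(v) for v in self.n)
        kind = "exact" if self.exact else "approx"
        if not self.assessable:
            return f"{self.method} (n={n}): not assessable"
        return (
            f"{self.method} (n={n}, {kind}): statistic={self.statistic:.4g}, "
            f"p={self.p_value:.4g} {self.stars}"
        )


def normality_gate(sample) -> TestResult:
    """Lilliefors-corrected KS test against the normal family.

    Uses the Dallal-Wilkinson approximation for the p-value.  Samples with
    n < 4 or zero variance are "not assessable" and default the pipeline to
    the nonparametric branch.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4 or np.ptp(x) == 0.0:
        return TestResult(
            method="lilliefors", statistic=float("nan"), p_value=float("nan"),
            n=(int(x.size),), exact=False, assessable=False,
        )
    stat, p = lilliefors(x, dist="norm", pvalmethod="approx")
    return TestResult(
        method="lilliefors", statistic=float(stat), p_value=float(min(p, 1.0)),
        n=(int(x.size),), exact=False,
    )


def mann_whitney(sample_a, sample_b, sidedness: str = "two-sided") -> TestResult:
    """Mann-Whitney U comparison of two independent groups.

    Exact p by the null U distribution when both groups have at most 8
    observations and there are no ties; normal approximation with tie
    correction (and continuity correction) otherwise.  ``sidedness`` is one
    of "two-sided", "less", "greater" (referring to sample_a vs sample_b).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    exact = a.size <= EXACT_MW_MAX_N and b.size <= EXACT_MW_MAX_N and not ties
    res = sps.mannwhitneyu(
        a, b, alternative=sidedness, method="exact" if exact else "asymptotic"
    )
    return TestResult(
        method="mann-whitney", statistic=float(res.statistic),
        p_value=float(res.pvalue), n=(int(a.size), int(b.size)), exact=exact,
    )


def _kw_h(groups: list[np.ndarray]) -> float:
    """Kruskal-Wallis H with tie correction, from first principles."""
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + g.size]
        h += g.size * (r.mean() - (n_total + 1) / 2.0) ** 2
        start += g.size
    h *= 12.0 / (n_total * (n_total + 1))
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(tie_counts**3 - tie_counts) / (n_total**3 - n_total)
    if correction == 0.0:
        raise ValueError("all values identical; H undefined")
    return h / correction


def _kw_exact_p(groups: list[np.ndarray]) -> float:
    """Exhaustive-permutation p-value for Kruskal-Wallis (small total n).

    Enumerates all assignments of the pooled observations to groups of the
    given sizes and counts assignments with H at least as large as
    observed.
    """
    sizes = [g.size for g in groups]
    pooled = np.concatenate(groups)
    h_obs = _kw_h(groups)
    n_total = pooled.size

    count_ge = 0
    total = 0

    def recurse(remaining: tuple[int, ...], size_idx: int, chosen: list[np.ndarray]):
        nonlocal count_ge, total
        if size_idx == len(sizes) - 1:
            grp = [*chosen, pooled[list(remaining)]]
            h = _kw_h(grp)
            total += 1
            if h >= h_obs - 1e-12:
                count_ge += 1
            return
        for sel in combinations(remaining, sizes[size_idx]):
            rest = tuple(i for i in remaining if i not in sel)
            recurse(rest, size_idx + 1, [*chosen, pooled[list(sel)]])

    recurse(tuple(range(n_total)), 0, [])
    return count_ge / total


def kruskal_wallis(*samples) -> TestResult:
    """Kruskal-Wallis H test across k groups.

    Chi-square approximation with k-1 degrees of freedom; exact by
    exhaustive permutation when the pooled size is at most 10.  Tie
    correction is applied in both branches.
    """
    groups = [np.asarray(s, dtype=float) for s in samples]
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty sample")
    n_total = sum(g.size for g in groups)
    if n_total <= EXACT_KW_MAX_N:
        h = _kw_h(groups)
        p = _kw_exact_p(groups)
        exact = True
    else:
        h, p = sps.kruskal(*groups)
        exact = False
    return TestResult(
        method="kruskal-wallis", statistic=float(h), p_value=float(p),
        n=tuple(int(g.size) for g in groups), exact=exact,
    )


def compare_groups(groups: dict[str, np.ndarray]) -> list[TestResult]:
    """Gate + rank-test battery over named groups.

    Runs the normality gate per group (informative), then Mann-Whitney for
    two groups or Kruskal-Wallis for more.  Returns all results, rank test
    last.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    results = [normality_gate(v) for v in groups.values()]
    vals = list(groups.values())
    if len(vals) == 2:
        results.append(mann_whitney(vals[0], vals[1]))
    else:
        results.append(kruskal_wallis(*vals))
    return results
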