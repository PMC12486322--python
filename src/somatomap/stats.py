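"""Group statistics, including recomputation from printed summaries.

Published group comparisons are typically reported as mean ± SEM with a
sample size. This module recomputes unpaired t statistics and one-way
ANOVA F statistics either from raw samples or from such summary triples
(SD is reconstructed as SEM·√n), plus two-sided Fisher's exact tests on
2×2 counts and Tukey/Bonferroni post hoc comparisons.

Raw-sample paths delegate to scipy.stats; summary paths are computed
explicitly so that a table of printed means, SEMs and group sizes is
sufficient input. The two paths agree to machine precision when the
summaries are computed from the raw samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Sequence, Union

import numpy as np
from scipy import stats as sps

__all__ = [
    "SummaryStats",
    "ContingencyTable",
    "TestResult",
    "t_test",
    "one_way_anova",
    "fisher_exact",
    "pairwise_posthoc",
]

#: relative slack when comparing hypergeometric point probabilities
_FISHER_SLACK = 1e-7


@dataclass(frozen=True)
class SummaryStats:
    """Printed group summary: mean ± SEM with sample size."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("summary statistics require n >= 2")
        if self.sem < 0:
            raise ValueError("SEM must be non-negative")

    @property
    def sd(self) -> float:
        """Sample SD reconstructed as SEM·√n."""
        return self.sem * sqrt(self.n)

    @property
    def var(self) -> float:
        return self.sd**2

    @classmethod
    def from_sample(cls, sample: Sequence[float]) -> "SummaryStats":
        arr = np.asarray(sample, dtype=float)
        if arr.size < 2:
            raise ValueError("need at least two observations")
        sd = float(arr.std(ddof=1))
        return cls(mean=float(arr.mean()), sem=sd / sqrt(arr.size), n=int(arr.size))


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 non-negative integer counts with row/column labels."""

    counts: np.ndarray
    row_labels: tuple[str, str] = ("group1", "group2")
    col_labels: tuple[str, str] = ("outcome1", "outcome2")

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (2, 2):
            raise ValueError("contingency table must be 2x2")
        if counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if counts.sum() == 0:
            raise ValueError("table must contain at least one observation")


@dataclass(frozen=True)
class TestResult:
    """Statistic, degrees of freedom, two-sided p and a method label."""

    statistic: float
    df: Union[float, tuple[float, float]]
    p: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError("p-value out of range")


GroupInput = Union[SummaryStats, Sequence[float], np.ndarray]


def _as_summary(group: GroupInput) -> SummaryStats:
    if isinstance(group, SummaryStats):
        return group
    return SummaryStats.from_sample(group)


def _is_raw(group: GroupInput) -> bool:
    return not isinstance(group, SummaryStats)


def _variances_unequal(a: SummaryStats, b: SummaryStats, alpha: float = 0.05) -> bool:
    """Two-sided F-ratio test of equal variances at ``alpha``."""
    if a.var == 0 and b.var == 0:
        return False
    hi, lo = (a, b) if a.var >= b.var else (b, a)
    if lo.var == 0:
        return True
    f = hi.var / lo.var
    p = 2.0 * min(
        sps.f.sf(f, hi.n - 1, lo.n - 1), sps.f.cdf(f, hi.n - 1, lo.n - 1)
    )
    return min(p, 1.0) < alpha


def t_test(
    group1: GroupInput, group2: GroupInput, welch: str = "off"
) -> TestResult:
    """Two-tailed unpaired t test from raw samples or summary statistics.

    ``welch`` is ``"off"`` (pooled variance, df = n1+n2−2, the default used
    when reproducing printed statistics), ``"on"`` (Welch with
    Satterthwaite df) or ``"auto"`` (Welch when an F-ratio test finds the
    variances unequal at α = 0.05).
    """
    if welch not in ("off", "on", "auto"):
        raise ValueError("welch must be 'off', 'on' or 'auto'")
    s1, s2 = _as_summary(group1), _as_summary(group2)
    use_welch = welch == "on" or (welch == "auto" and _variances_unequal(s1, s2))

    if _is_raw(group1) and _is_raw(group2):
        res = sps.ttest_ind(
            np.asarray(group1, float), np.asarray(group2, float),
            equal_var=not use_welch,
        )
        return TestResult(
            statistic=float(res.statistic), df=float(res.df),
            p=float(res.pvalue), method="welch" if use_welch else "student",
        )

    if use_welch:
        se2 = s1.var / s1.n + s2.var / s2.n
        df = se2**2 / (
            (s1.var / s1.n) ** 2 / (s1.n - 1) + (s2.var / s2.n) ** 2 / (s2.n - 1)
        )
        t = (s1.mean - s2.mean) / sqrt(se2)
        method = "welch"
    else:
        df = s1.n + s2.n - 2
        sp2 = ((s1.n - 1) * s1.var + (s2.n - 1) * s2.var) / df
        t = (s1.mean - s2.mean) / sqrt(sp2 * (1 / s1.n + 1 / s2.n))
        method = "student"
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=float(df), p=float(min(p, 1.0)), method=method)


def one_way_anova(groups: Sequence[GroupInput]) -> TestResult:
    """One-way ANOVA from raw samples or per-group summary statistics.

    On the summary path the within-group sum of squares is reconstructed
    from the per-group variances (SEM·√n)².
    """
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least two groups")
    if all(_is_raw(g) for g in groups):
        arrays = [np.asarray(g, float) for g in groups]
        if any(a.size < 2 for a in arrays):
            raise ValueError("every group needs n >= 2")
        res = sps.f_oneway(*arrays)
        k = len(arrays)
        n_total = sum(a.size for a in arrays)
        return TestResult(
            statistic=float(res.statistic), df=(k - 1, n_total - k),
            p=float(res.pvalue), method="anova",
        )

    summaries = [_as_summary(g) for g in groups]
    k = len(summaries)
    n_total = sum(s.n for s in summaries)
    grand = sum(s.n * s.mean for s in summaries) / n_total
    ss_between = sum(s.n * (s.mean - grand) ** 2 for s in summaries)
    ss_within = sum((s.n - 1) * s.var for s in summaries)
    df_b, df_w = k - 1, n_total - k
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w
    if ms_within == 0:
        f = np.inf if ms_between > 0 else 0.0
    else:
        f = ms_between / ms_within
    p = float(sps.f.sf(f, df_b, df_w))
    return TestResult(statistic=float(f), df=(df_b, df_w), p=p, method="anova")


def fisher_exact(table: ContingencyTable | np.ndarray) -> TestResult:
    """Two-sided Fisher's exact test on a 2×2 table.

    Point-probability method with margins fixed: the p-value sums the
    hypergeometric probabilities of every table no more probable than the
    observed one (with a small relative slack absorbing floating-point
    error in the pmf). The statistic is the sample odds ratio.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(counts=np.asarray(table))
    (a, b), (c, d) = table.counts
    r1, c1, n = a + b, a + c, a + b + c + d
    kmin = max(0, c1 - (c + d))
    kmax = min(c1, r1)
    support = np.arange(kmin, kmax + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - kmin]
    p = float(pmf[pmf <= p_obs * (1.0 + _FISHER_SLACK)].sum())
    if p > 1.0 - 1e-9:  # full-support sums drift below 1 by float error
        p = 1.0
    odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
    return TestResult(statistic=float(odds), df=1.0, p=min(p, 1.0), method="fisher")


def pairwise_posthoc(
    groups: Sequence[GroupInput],
    method: str = "tukey",
    labels: Sequence[str] | None = None,
) -> list[tuple[str, str, TestResult]]:
    """Pairwise post hoc comparisons after a one-way design.

    ``tukey``: studentized-range q on the pooled within-group mean square
    (Tukey–Kramer for unequal n). ``bonferroni``: pairwise pooled t tests
    with p multiplied by the number of comparisons, capped at 1.
    """
    if method not in ("tukey", "bonferroni"):
        raise ValueError("method must be 'tukey' or 'bonferroni'")
    summaries = [_as_summary(g) for g in groups]
    k = len(summaries)
    if method == "tukey" and k < 3:
        raise ValueError("Tukey's test requires at least three groups")
    if k < 2:
        raise ValueError("need at least two groups")
    names = list(labels) if labels is not None else [f"group{i+1}" for i in range(k)]
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    results: list[tuple[str, str, TestResult]] = []
    if method == "tukey":
        df_w = sum(s.n - 1 for s in summaries)
        ms_within = sum((s.n - 1) * s.var for s in summaries) / df_w
        for i, j in pairs:
            si, sj = summaries[i], summaries[j]
            se = sqrt(ms_within / 2.0 * (1 / si.n + 1 / sj.n))
            q = abs(si.mean - sj.mean) / se if se > 0 else np.inf
            p = float(sps.studentized_range.sf(q, k, df_w)) if np.isfinite(q) else 0.0
            if q == 0:
                p = 1.0
            results.append(
                (names[i], names[j],
                 TestResult(statistic=float(q), df=float(df_w), p=min(p, 1.0),
                            method="tukey"))
            )
    else:
        m = len(pairs)
        for i, j in pairs:
            base = t_test(summaries[i], summaries[j], welch="off")
            results.append(
                (names[i], names[j],
                 TestResult(statistic=base.statistic, df=base.df,
                            p=min(base.p * m, 1.0), method="bonferroni"))
            )
    return results
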