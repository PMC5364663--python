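"""Nonparametric two-group comparison and summary statistics.

The Mann–Whitney–Wilcoxon (MWW) rank-sum test is the workhorse: entropy
values across subjects or segments are not normally distributed, so group
differences are assessed by ranks, two-sided, at the 0.05 level.  Exact
p-values (full enumeration of rank arrangements) are used for small
tie-free samples (combined n <= 12); larger or tied samples use the normal
approximation with tie and continuity corrections.  p-values map onto the
significance tiers used in the result tables.  No multiple-testing
correction is applied across electrodes or thresholds (none is used in the
analysis this package implements); callers needing familywise control
should apply their own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "SummaryStat",
    "BestSetting",
    "EXACT_MAX_COMBINED_N",
    "mww_test",
    "paired_test",
    "significance_tier",
    "summarize",
    "best_setting",
    "significant_ranges",
]

#: exact-enumeration / normal-approximation switchover (combined sample size)
EXACT_MAX_COMBINED_N = 12

_TIER_ORDER = {"strictly": 4, "very": 3, "just": 2, "almost": 1, "ns": 0}


@dataclass(frozen=True)
class GroupComparison:
    """Result of a two-group rank test on one metric at one setting."""

    name_a: str
    name_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    u_stat: float
    p_value: float
    tier: str
    method: str = "mww"

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value must lie in (0, 1]")
        if not (0.0 <= self.u_stat <= self.n_a * self.n_b):
            raise ValueError("U must lie in [0, n_a * n_b]")


@dataclass(frozen=True)
class SummaryStat:
    """Mean, sample SD and standard error SD/sqrt(n)."""

    mean: float
    sd: float
    standard_error: float
    n: int


@dataclass(frozen=True)
class BestSetting:
    """Most-discriminating grid setting (minimum p; ties -> smaller setting)."""

    setting: float
    comparison: GroupComparison
    max_median_a: float
    max_median_b: float
    ns: bool  # True when no setting reaches p < 0.05


def mww_test(a: Sequence[float], b: Sequence[float],
             name_a: str = "A", name_b: str = "B") -> GroupComparison:
    """Two-sided Mann–Whitney–Wilcoxon rank-sum test.

    Exact p by full enumeration of rank arrangements when the combined
    sample size is at most :data:`EXACT_MAX_COMBINED_N` and there are no
    ties; otherwise the normal approximation with tie correction and
    continuity correction.  Two identical samples give U = n_a·n_b/2 and
    p = 1 rather than an error.
    """
    x = np.asarray(list(a), dtype=float)
    y = np.asarray(list(b), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = int(x.size), int(y.size)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        u, p, method = n_a * n_b / 2.0, 1.0, "degenerate"
    else:
        has_ties = np.unique(pooled).size < pooled.size
        if n_a + n_b <= EXACT_MAX_COMBINED_N and not has_ties:
            method = "exact"
            res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        else:
            method = "asymptotic"
            res = sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="asymptotic", use_continuity=True)
        u, p = float(res.statistic), float(min(res.pvalue, 1.0))
    return GroupComparison(
        name_a=name_a, name_b=name_b, n_a=n_a, n_b=n_b,
        median_a=float(np.median(x)), median_b=float(np.median(y)),
        u_stat=u, p_value=p, tier=significance_tier(p), method=method,
    )


def paired_test(a: Sequence[float], b: Sequence[float],
                name_a: str = "A", name_b: str = "B") -> GroupComparison:
    """Wilcoxon signed-rank test on per-subject pairs (a_i, b_i); for designs
    where the two conditions are measured on the same subjects."""
    x = np.asarray(list(a), dtype=float)
    y = np.asarray(list(b), dtype=float)
    if x.size != y.size or x.size == 0:
        raise ValueError("paired test needs equal-length non-empty samples")
    d = x - y
    if np.all(d == 0):
        p = 1.0
        w = 0.0
    else:
        res = sps.wilcoxon(x, y, alternative="two-sided", zero_method="wilcox")
        w, p = float(res.statistic), float(min(res.pvalue, 1.0))
    n = int(x.size)
    # report W in the U slot, clipped into the documented range for reuse
    u = min(max(w, 0.0), float(n * n))
    return GroupComparison(
        name_a=name_a, name_b=name_b, n_a=n, n_b=n,
        median_a=float(np.median(x)), median_b=float(np.median(y)),
        u_stat=u, p_value=p, tier=significance_tier(p), method="wilcoxon-paired",
    )


def significance_tier(p: float) -> str:
    """Tier label for a p-value.

    ``strictly`` (p < 0.0001), ``very`` (0.0001 <= p < 0.01), ``just``
    (0.01 <= p < 0.05), ``almost`` (0.05 <= p < 0.1), else ``ns``.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError("p-value must lie in (0, 1]")
    if p < 0.0001:
        return "strictly"
    if p < 0.01:
        return "very"
    if p < 0.05:
        return "just"
    if p < 0.1:
        return "almost"
    return "ns"


def summarize(values: Sequence[float]) -> SummaryStat:
    """Mean, sample SD (ddof=1; 0 for a single value) and SE = SD/sqrt(n)."""
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty sample")
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return SummaryStat(mean=float(x.mean()), sd=sd,
                       standard_error=sd / math.sqrt(x.size), n=int(x.size))


def best_setting(settings: Sequence[float],
                 comparisons: Sequence[GroupComparison]) -> BestSetting:
    """Pick the grid setting with minimum p (ties -> smaller setting) and
    report each group's maximum median over the whole grid.

    The returned ``ns`` flag is True when no setting is significant at 0.05.
    """
    settings = [float(s) for s in settings]
    comparisons = list(comparisons)
    if not comparisons or len(settings) != len(comparisons):
        raise ValueError("need one comparison per setting, at least one")
    order = sorted(range(len(settings)),
                   key=lambda i: (comparisons[i].p_value, settings[i]))
    best = order[0]
    return BestSetting(
        setting=settings[best],
        comparison=comparisons[best],
        max_median_a=max(c.median_a for c in comparisons),
        max_median_b=max(c.median_b for c in comparisons),
        ns=all(c.p_value >= 0.05 for c in comparisons),
    )


def significant_ranges(settings: Sequence[float],
                       p_values: Sequence[float],
                       alpha: float = 0.05) -> list[tuple[float, float]]:
    """Maximal contiguous runs of grid settings with p < alpha, as
    (first, last) setting pairs — the 'significance range' column of the
    result tables."""
    runs: list[tuple[float, float]] = []
    start: Optional[float] = None
    prev: Optional[float] = None
    for s, p in zip(settings, p_values):
        if not math.isnan(p) and p < alpha:
            if start is None:
                start = float(s)
            prev = float(s)
        elif start is not None:
            runs.append((start, prev))  # type: ignore[arg-type]
            start = prev = None
    if start is not None:
        runs.append((start, prev))  # type: ignore[arg-type]
    return runs
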