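"""Randomization tests, Welch's t-test and Tukey boxplot summaries.

The randomization (permutation) test compares two groups by the
difference of their means: group labels are shuffled, the difference
recomputed, and the two-sided p-value is the fraction of relabelings at
least as extreme as the observed difference.  When the number of
distinct relabelings is small the null distribution is enumerated
exhaustively and the p-value is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "RandomizationResult",
    "TukeySummary",
    "randomization_test",
    "welch_t_test",
    "tukey_summary",
    "EXACT_ENUMERATION_LIMIT",
]

#: exhaustive enumeration is used when C(n1+n2, n1) does not exceed this
EXACT_ENUMERATION_LIMIT = 20_000


@dataclass(frozen=True)
class RandomizationResult:
    """Outcome of a two-group randomization test.

    ``observed_diff`` is mean(group2) − mean(group1); ``effect_size``
    repeats it (the difference of means is the reported effect size),
    with ``cohen_d`` as the standardized companion.  ``exact`` marks
    exhaustive enumeration, in which case ``n_permutations`` is the
    number of distinct relabelings and ``seed`` is irrelevant.
    """

    observed_diff: float
    p_value: float
    n_permutations: int
    effect_size: float
    cohen_d: float
    seed: int | None
    exact: bool


@dataclass(frozen=True)
class TukeySummary:
    """Tukey boxplot numbers: quartiles, 1.5·IQR whiskers, outliers."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def _cohen_d(g1: np.ndarray, g2: np.ndarray) -> float:
    n1, n2 = g1.size, g2.size
    if n1 < 2 or n2 < 2:
        return float("nan")
    pooled = ((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) / (n1 + n2 - 2)
    return float((g2.mean() - g1.mean()) / math.sqrt(pooled)) if pooled > 0 else float("nan")


def randomization_test(
    group1,
    group2,
    n_permutations: int = 1000,
    seed: int = 0,
) -> RandomizationResult:
    """Two-sided permutation test for a difference of means.

    When the total number of group-1/group-2 relabelings C(n1+n2, n1)
    is at most ``EXACT_ENUMERATION_LIMIT`` the null distribution is
    enumerated exactly and p = #{relabelings with |diff| >= |observed|}
    / total.  Otherwise ``n_permutations`` random relabelings are drawn
    and p = (1 + #{|diff| >= |observed|}) / (n_permutations + 1) — the
    add-one convention counts the observed labeling itself and keeps
    p > 0.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be nonempty")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")

    pooled = np.concatenate([g1, g2])
    n1, n = g1.size, g1.size + g2.size
    observed = float(g2.mean() - g1.mean())
    # relative tolerance guards against float jitter at |diff| == |observed|
    tol = 1e-12 * max(1.0, abs(observed))
    total = math.comb(n, n1)

    if total <= EXACT_ENUMERATION_LIMIT:
        grand = pooled.sum()
        hits = 0
        for idx in combinations(range(n), n1):
            s1 = pooled[list(idx)].sum()
            diff = (grand - s1) / (n - n1) - s1 / n1
            if abs(diff) >= abs(observed) - tol:
                hits += 1
        p = hits / total
        return RandomizationResult(observed, p, total, observed, _cohen_d(g1, g2), None, True)

    rng = np.random.default_rng(seed)
    # each row is one permuted pooled sample; first n1 entries -> group 1
    perms = rng.permuted(np.tile(pooled, (n_permutations, 1)), axis=1)
    diffs = perms[:, n1:].mean(axis=1) - perms[:, :n1].mean(axis=1)
    hits = int(np.count_nonzero(np.abs(diffs) >= abs(observed) - tol))
    p = (1 + hits) / (n_permutations + 1)
    return RandomizationResult(
        observed, p, n_permutations, observed, _cohen_d(g1, g2), seed, False
    )


def welch_t_test(group1, group2) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, two-sided p).

    The t statistic uses mean(group2) − mean(group1) and the
    Welch–Satterthwaite degrees of freedom.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least 2 values")
    if g1.var(ddof=1) == 0 and g2.var(ddof=1) == 0:
        raise ValueError("degenerate variance: both groups are constant")
    res = sps.ttest_ind(g2, g1, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def tukey_summary(values) -> TukeySummary:
    """Tukey boxplot summary with linear-interpolation quartiles.

    Whiskers extend to the most extreme data points no further from the
    box than 1.5× the interquartile range; points beyond are outliers.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = tuple(np.sort(v[(v < lo_fence) | (v > hi_fence)]))
    return TukeySummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=outliers,
    )
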