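"""Rank-based hypothesis tests used throughout the pipeline.

Small samples are handled by exact enumeration of the permutation
distribution (Wilcoxon rank-sum and Kruskal-Wallis), falling back to the
usual large-sample approximations — normal with tie correction for the
rank-sum test, chi-square for Kruskal-Wallis — when enumeration would be
too large. All tests operate on ranks, so every downstream result is
invariant to monotone transforms of the inputs.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import scipy.stats

__all__ = [
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "spearman",
    "bh_adjust",
]

# enumeration budget: n-choose-k / multinomial arrangements above this use
# the asymptotic approximation instead
_MAX_EXACT_ARRANGEMENTS = 500_000


def _rank_sum_exact(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p for the rank-sum test by full enumeration.

    Enumerates every assignment of the pooled values to the two groups and
    computes a two-tailed p as 2 * min tail of the rank-sum distribution
    (capped at 1), which is correct in the presence of ties.
    """
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    n_x = len(x)
    obs = ranks[:n_x].sum()
    stats = np.array([
        ranks[list(idx)].sum()
        for idx in itertools.combinations(range(len(pooled)), n_x)
    ])
    p_le = np.mean(stats <= obs + 1e-9)
    p_ge = np.mean(stats >= obs - 1e-9)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_rank_sum(
    x: np.ndarray, y: np.ndarray, *, method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns ``(statistic, p_value)`` where the statistic is the U of the
    first sample. ``method`` is ``auto`` (exact by enumeration when the
    number of arrangements is tractable, asymptotic otherwise), ``exact``
    or ``asymptotic``. The asymptotic path applies the normal approximation
    with tie correction and no continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    u = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    if method == "auto":
        method = (
            "exact"
            if math.comb(len(x) + len(y), len(x)) <= _MAX_EXACT_ARRANGEMENTS
            else "asymptotic"
        )
    if method == "exact":
        return float(u.statistic), _rank_sum_exact(x, y)
    return float(u.statistic), float(u.pvalue)


def _kw_h(rank_sums: list[float], sizes: list[int], n: int, tie_term: float) -> float:
    h = 12.0 / (n * (n + 1)) * sum(
        rs * rs / sz for rs, sz in zip(rank_sums, sizes)
    ) - 3 * (n + 1)
    return h / tie_term if tie_term > 0 else 0.0


def _kw_exact(groups: list[np.ndarray]) -> tuple[float, float]:
    """Exact permutation p (upper tail of H) by enumerating group assignments.

    Only per-group rank sums enter H, so the recursion carries partial rank
    sums rather than full arrangements.
    """
    pooled = np.concatenate(groups)
    ranks = scipy.stats.rankdata(pooled)
    n = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    sizes = [len(g) for g in groups]
    start = 0
    obs_sums = []
    for sz in sizes:
        obs_sums.append(float(ranks[start:start + sz].sum()))
        start += sz
    obs = _kw_h(obs_sums, sizes, n, tie_term)
    total_rank = float(ranks.sum())

    count_ge = 0
    total = 0

    def recurse(remaining: tuple[int, ...], gi: int, partial: list[float]) -> None:
        nonlocal count_ge, total
        if gi == len(sizes) - 1:
            stat = _kw_h(partial + [total_rank - sum(partial)], sizes, n, tie_term)
            total += 1
            if stat >= obs - 1e-9:
                count_ge += 1
            return
        for idx in itertools.combinations(remaining, sizes[gi]):
            chosen = set(idx)
            rest = tuple(i for i in remaining if i not in chosen)
            recurse(rest, gi + 1, partial + [float(ranks[list(idx)].sum())])

    recurse(tuple(range(n)), 0, [])
    return obs, count_ge / total


def kruskal_wallis(
    groups: list[np.ndarray], *, method: str = "auto"
) -> tuple[float, float]:
    """Kruskal-Wallis H test across >= 2 groups.

    Returns ``(H, p_value)``. Exact enumeration of the permutation
    distribution (one-sided upper tail of H, the standard convention) when
    the arrangement count is tractable, chi-square approximation otherwise.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    n = sum(len(g) for g in groups)
    arrangements = math.factorial(n)
    for g in groups:
        arrangements //= math.factorial(len(g))
    if method == "auto":
        method = "exact" if arrangements <= _MAX_EXACT_ARRANGEMENTS else "asymptotic"
    if method == "exact":
        return _kw_exact(groups)
    h, p = scipy.stats.kruskal(*groups)
    return float(h), float(p)


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Returns ``(rho, p_value)``; degenerate (constant) inputs yield
    ``(nan, nan)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        return float("nan"), float("nan")
    res = scipy.stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
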