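"""Rank statistics used across the pipeline.

Implemented directly from the textbook definitions: Kruskal-Wallis with tie
correction, the Siegel-Castellan critical-difference post hoc on mean ranks
(Bonferroni or Holm adjusted), step-down Holm p-value adjustment, and the
two-sample Wilcoxon rank-sum test (exact by enumeration for small tie-free
samples, otherwise normal approximation with tie and continuity
correction).  Only tail probabilities of the reference distributions come
from scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations as _combinations
from typing import Sequence

import numpy as np
from scipy.stats import chi2, norm

__all__ = [
    "average_ranks",
    "kruskal_wallis",
    "kruskal_posthoc",
    "PairwiseComparison",
    "holm_adjust",
    "wilcoxon_ranksum",
    "format_p",
]

#: Reporting floor for p-values, finer than the conventional "<0.001".
P_FLOOR = 1e-15


def format_p(p: float) -> str:
    """Human-readable p with a hard floor at machine-precision scale."""
    return "<1e-15" if p < P_FLOOR else f"{p:.6g}"


def average_ranks(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..n with ties assigned the average of their rank range."""
    x = np.asarray(values, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def _tie_correction(pooled: np.ndarray) -> float:
    _, cnt = np.unique(pooled, return_counts=True)
    n = len(pooled)
    if n < 2:
        return 1.0
    return 1.0 - (cnt**3 - cnt).sum() / (n**3 - n)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p on k-1 df."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = len(pooled)
    if n < 3:
        raise ValueError("need at least three observations in total")
    ranks = average_ranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        ni = len(g)
        rbar = ranks[start : start + ni].mean()
        h += ni * (rbar - (n + 1) / 2) ** 2
        start += ni
    h *= 12 / (n * (n + 1))
    corr = _tie_correction(pooled)
    if corr == 0.0:
        # every observation tied: no evidence of any difference
        return 0.0, 1.0
    h /= corr
    p = float(chi2.sf(h, df=len(groups) - 1))
    return float(h), p


@dataclass(frozen=True)
class PairwiseComparison:
    """One post hoc contrast of mean ranks between two groups."""

    group_i: int
    group_j: int
    observed_diff: float
    critical_diff: float
    significant: bool


def kruskal_posthoc(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> list[PairwiseComparison]:
    """Siegel-Castellan multiple-comparison post hoc on mean ranks.

    Pair (i, j) is significant when |Rbar_i - Rbar_j| exceeds
    z_{1-a'/2} * sqrt(N(N+1)/12 * (1/n_i + 1/n_j)) with a' adjusted by
    plain Bonferroni (default) or a Holm step-down over the pairs.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = len(pooled)
    ranks = average_ranks(pooled)
    means, sizes = [], []
    start = 0
    for g in groups:
        means.append(ranks[start : start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)

    pairs = list(_combinations(range(len(groups)), 2))
    m = len(pairs)

    def cd(i: int, j: int, a_eff: float) -> float:
        z = norm.ppf(1 - a_eff / 2)
        return float(z * math.sqrt(n * (n + 1) / 12 * (1 / sizes[i] + 1 / sizes[j])))

    if correction == "bonferroni":
        out = []
        for i, j in pairs:
            diff = abs(means[i] - means[j])
            crit = cd(i, j, alpha / m)
            out.append(PairwiseComparison(i, j, diff, crit, diff > crit))
        return out
    if correction == "holm":
        # step-down: most extreme standardized difference tested at alpha/m,
        # next at alpha/(m-1), ...; stop at the first non-rejection
        stats = []
        for i, j in pairs:
            diff = abs(means[i] - means[j])
            se = math.sqrt(n * (n + 1) / 12 * (1 / sizes[i] + 1 / sizes[j]))
            stats.append((diff / se, i, j, diff))
        order = sorted(range(m), key=lambda k: -stats[k][0])
        results: dict[tuple[int, int], PairwiseComparison] = {}
        rejecting = True
        for rank, k in enumerate(order):
            zstat, i, j, diff = stats[k]
            a_eff = alpha / (m - rank)
            crit = cd(i, j, a_eff)
            sig = rejecting and diff > crit
            if not sig:
                rejecting = False
            results[(i, j)] = PairwiseComparison(i, j, diff, crit, sig)
        return [results[p] for p in pairs]
    raise ValueError(f"unknown correction {correction!r}")


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Step-down Holm-adjusted p values, monotone, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, k in enumerate(order):
        val = min(1.0, (m - rank) * p[k])
        running = max(running, val)
        adj[k] = running
    return adj.tolist()


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p by enumeration of rank assignments (no ties)."""
    nx, ny = len(x), len(y)
    n = nx + ny
    ranks = average_ranks(np.concatenate([x, y]))
    w_obs = ranks[:nx].sum()
    mean_w = nx * (n + 1) / 2
    dev = abs(w_obs - mean_w)
    count = 0
    total = 0
    all_ranks = np.arange(1, n + 1)
    for comb in _combinations(range(n), nx):
        w = all_ranks[list(comb)].sum()
        total += 1
        if abs(w - mean_w) >= dev - 1e-9:
            count += 1
    return count / total


def wilcoxon_ranksum(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> tuple[float, float]:
    """Two-sample two-sided Wilcoxon rank-sum test.

    Returns (W, p) with W the rank sum of ``x``.  With ``method="auto"``,
    exact enumeration is used when n_x + n_y <= 12 and there are no ties;
    otherwise the normal approximation with tie and continuity correction.
    ``method`` may force ``"exact"`` or ``"approx"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    if method not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown method {method!r}")
    nx, ny = len(x), len(y)
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = average_ranks(pooled)
    w = float(ranks[:nx].sum())
    has_ties = len(np.unique(pooled)) < n
    if method == "exact" or (method == "auto" and n <= 12 and not has_ties):
        if has_ties:
            raise ValueError("exact method requires tie-free data")
        return w, float(_exact_ranksum_p(x, y))
    mean_w = nx * (n + 1) / 2
    _, cnt = np.unique(pooled, return_counts=True)
    # tie-corrected variance of the rank sum
    var_w = nx * ny * (n + 1) / 12 - nx * ny * (cnt**3 - cnt).sum() / (12 * n * (n - 1))
    if var_w <= 0:
        return w, 1.0
    dev = abs(w - mean_w)
    z = max(0.0, dev - 0.5) / math.sqrt(var_w)
    return w, float(min(1.0, 2 * norm.sf(z)))
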