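"""Summary statistics and tumor-area threshold analysis.

The threshold analysis finds the tumor-area cutpoint that best separates
slices with high and low segmentation accuracy using maximally selected rank
statistics: every candidate cutpoint of the covariate induces a two-sample
split of the responses, a standardized Wilcoxon rank-sum statistic is
computed at each, and the cutpoint maximizing the absolute statistic is
selected. Because the maximum is selected over many candidate splits, its
p-value is adjusted by a seeded permutation scheme that recomputes the
maximal statistic under random re-pairings of covariate and response,
bounding the family-wise error over all candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats


class SummaryStats(NamedTuple):
    mean: float
    iqr_low: float
    iqr_high: float
    n: int


def summarize(values: Sequence[float]) -> SummaryStats:
    """Arithmetic mean and interquartile range (25th/75th percentiles,
    linear interpolation between order statistics)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value list")
    q25, q75 = np.percentile(v, [25, 75])
    return SummaryStats(float(v.mean()), float(q25), float(q75), int(v.size))


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midranks for ties; two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def compare_groups(a, b, paired: bool = False) -> tuple[float, float]:
    """Two-sided Wilcoxon test: signed-rank when paired, rank-sum otherwise.

    Uses the normal approximation with tie and continuity corrections as
    implemented in scipy. Paired mode drops zero differences; raises if all
    differences are zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal lengths")
        diffs = a - b
        nonzero = np.count_nonzero(diffs)
        if nonzero == 0:
            raise ValueError("all paired differences are zero")
        if nonzero < 5:
            raise ValueError("need >= 5 nonzero paired differences")
        res = stats.wilcoxon(a, b, alternative="two-sided", method="approx")
    else:
        if min(a.size, b.size) < 5:
            raise ValueError("need >= 5 observations per group")
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


@dataclass
class ThresholdResult:
    """Outcome of the maximally-selected-rank-statistics cutpoint search."""

    best_cutpoint: float
    max_standardized_statistic: float
    adjusted_p: float
    candidate_cutpoints: np.ndarray
    group_means: tuple  # (mean response below/at cutpoint, above cutpoint)
    n: int


def _standardized_rank_statistics(
    a_ordered: np.ndarray, left_counts: np.ndarray
) -> np.ndarray:
    """Standardized linear rank statistics for all candidate splits.

    ``a_ordered`` are midrank scores ordered by ascending covariate;
    ``left_counts[k]`` is the size of the low group for candidate k. Under
    the hypergeometric sampling of a rank-sum split,
    E(S) = n1 * mean(a) and Var(S) = n1 (N - n1) / (N (N-1)) * sum((a-mean)^2).
    """
    a2 = np.atleast_2d(np.asarray(a_ordered, dtype=float))  # (B, N)
    N = a2.shape[1]
    abar = a2.mean(axis=1)  # (B,)
    ss = ((a2 - abar[:, None]) ** 2).sum(axis=1)  # (B,)
    csum = np.cumsum(a2, axis=1)
    S = csum[:, left_counts - 1]  # (B, K)
    n1 = left_counts.astype(float)[None, :]
    E = n1 * abar[:, None]
    var = n1 * (N - n1) / (N * (N - 1)) * ss[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (S - E) / np.sqrt(var)
    z = np.nan_to_num(z, nan=0.0)
    return z[0] if np.ndim(a_ordered) == 1 else z


def maxstat_threshold(
    x,
    y,
    min_quantile: float = 0.10,
    max_quantile: float = 0.90,
    n_permutations: int = 1000,
    seed: int = 0,
    min_group: int = 2,
) -> ThresholdResult:
    """Optimal covariate cutpoint by maximally selected Wilcoxon statistics.

    Candidate cutpoints are the distinct values of ``x`` inside the
    [``min_quantile``, ``max_quantile``] band that leave at least
    ``min_group`` observations on each side. For each candidate ``mu`` the
    responses ``y`` where ``x <= mu`` are compared with those where
    ``x > mu`` via the standardized rank-sum statistic; the cutpoint with the
    largest absolute statistic wins (ties: smallest cutpoint). ``adjusted_p``
    is the seeded-permutation probability that the maximal absolute statistic
    under a random x-y re-pairing reaches the observed one.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    N = x.size
    if N < 10:
        raise ValueError("need at least 10 observations")

    order = np.argsort(x, kind="stable")
    xs = x[order]
    a = stats.rankdata(y)  # midrank scores
    a_ord = a[order]

    lo, hi = np.quantile(x, [min_quantile, max_quantile])
    distinct = np.unique(xs)
    left_counts = np.searchsorted(xs, distinct, side="right")
    keep = (
        (distinct >= lo)
        & (distinct <= hi)
        & (left_counts >= min_group)
        & (N - left_counts >= min_group)
    )
    candidates = distinct[keep]
    left_counts = left_counts[keep]
    if candidates.size == 0:
        raise ValueError(
            "no candidate cutpoint leaves >= 2 observations on both sides "
            "within the quantile band"
        )

    z = _standardized_rank_statistics(a_ord, left_counts)
    best_k = int(np.argmax(np.abs(z)))  # first max -> smallest cutpoint
    best_cut = float(candidates[best_k])
    max_abs = float(np.abs(z[best_k]))

    rng = np.random.default_rng(seed)
    # permute the x-y pairing: equivalent to permuting the ordered scores
    perm_scores = np.empty(n_permutations)
    batch = max(1, min(n_permutations, 200))
    done = 0
    while done < n_permutations:
        b = min(batch, n_permutations - done)
        A = rng.permuted(np.tile(a_ord, (b, 1)), axis=1)
        zp = _standardized_rank_statistics(A, left_counts)
        perm_scores[done : done + b] = np.abs(zp).max(axis=1)
        done += b
    adjusted_p = float((1 + np.sum(perm_scores >= max_abs - 1e-12)) / (n_permutations + 1))

    low = y[x <= best_cut]
    high = y[x > best_cut]
    return ThresholdResult(
        best_cutpoint=best_cut,
        max_standardized_statistic=float(z[best_k]),
        adjusted_p=adjusted_p,
        candidate_cutpoints=candidates,
        group_means=(float(low.mean()), float(high.mean())),
        n=N,
    )
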