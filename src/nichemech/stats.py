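"""Nonparametric two-sample and paired tests with exact small-sample branches.

Every comparison in the pipeline funnels through this module: group
differences in adhesion force, migration speed, distance to the ventricle,
and signature scores use the two-tailed Mann-Whitney U test; proportions of
force-producing cells use the two-sided Fisher exact test; paired
knockout/control designs use the Wilcoxon matched-pairs signed-rank test.

Each test carries an exact branch that enumerates the full permutation null
when the enumeration is small enough, and falls back to a tie- and
continuity-corrected normal approximation otherwise.  The branch actually
used is recorded in the result so downstream reports can state it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb, sqrt

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm, rankdata

__all__ = [
    "GroupComparison",
    "mann_whitney_two_tailed",
    "fisher_exact_two_sided",
    "wilcoxon_signed_rank_two_tailed",
    "normalize_to_reference_mean",
]

#: Exact Mann-Whitney enumeration is used when C(n+m, n) does not exceed this.
MAX_EXACT_LABELINGS = 200_000

#: Exact Wilcoxon sign enumeration is used when the number of nonzero
#: differences does not exceed this (2**n sign assignments).
MAX_EXACT_SIGNS = 20


@dataclass(frozen=True)
class GroupComparison:
    """Result of a two-group (or paired) nonparametric comparison.

    Attributes
    ----------
    test : str
        Test name, e.g. ``"mann-whitney"``.
    statistic : float
        The test statistic (U, the 2x2 table's odds ratio, or W+).
    pvalue : float
        Two-sided p-value in [0, 1].
    n : tuple of int
        Sample size per group (or pairs retained after dropping zeros).
    method : str
        ``"exact"`` or ``"normal-approximation"``.
    """

    test: str
    statistic: float
    pvalue: float
    n: tuple
    method: str


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _rank_sum_count_distribution(n: int, m: int) -> np.ndarray:
    """Number of ways to pick ``n`` of the ranks ``1..n+m`` for each rank sum.

    Classical counting recursion; entry ``s`` of the returned array is the
    number of n-subsets of {1, ..., n+m} whose sum is ``s``.  Summing over the
    array reproduces C(n+m, n), i.e. this is exactly the tie-free labeling
    enumeration, just counted instead of listed.
    """
    total = n + m
    max_sum = n * total  # loose upper bound on achievable rank sums
    counts = np.zeros((n + 1, max_sum + 1), dtype=np.float64)
    counts[0, 0] = 1.0
    for rank in range(1, total + 1):
        kmax = min(rank, n)
        for k in range(kmax, 0, -1):
            counts[k, rank:] += counts[k - 1, : max_sum + 1 - rank]
    return counts[n]


_RANK_SUM_CACHE: dict = {}


def _exact_mwu_pvalue_tiefree(u: float, n: int, m: int) -> float:
    key = (n, m)
    if key not in _RANK_SUM_CACHE:
        _RANK_SUM_CACHE[key] = _rank_sum_count_distribution(n, m)
    counts = _RANK_SUM_CACHE[key]
    total = counts.sum()
    offset = n * (n + 1) / 2.0  # U = rank_sum - offset
    u_all = np.arange(counts.size) - offset
    p_low = counts[u_all <= u + 1e-9].sum() / total
    p_high = counts[u_all >= u - 1e-9].sum() / total
    return min(1.0, 2.0 * min(p_low, p_high))


def _exact_mwu_pvalue_ties(pooled_ranks: np.ndarray, u: float, n: int) -> float:
    """Exact p by explicit enumeration of all labelings of the pooled values."""
    from itertools import combinations

    total_n = pooled_ranks.size
    m = total_n - n
    offset = n * (n + 1) / 2.0
    idx = np.fromiter(
        (i for combo in combinations(range(total_n), n) for i in combo),
        dtype=np.intp,
    ).reshape(-1, n)
    u_all = pooled_ranks[idx].sum(axis=1) - offset
    p_low = np.mean(u_all <= u + 1e-9)
    p_high = np.mean(u_all >= u - 1e-9)
    return min(1.0, 2.0 * min(p_low, p_high))


def mann_whitney_two_tailed(x, y) -> GroupComparison:
    """Two-tailed Mann-Whitney U test.

    The statistic is ``U = #{x_i > y_j} + 0.5 * #{x_i == y_j}``, computed via
    mid-ranks.  When the number of group labelings ``C(n+m, n)`` is at most
    ``MAX_EXACT_LABELINGS`` the p-value is exact: the smaller of the two
    observed tail probabilities under the permutation null is doubled and
    capped at 1.  Ties are handled exactly in the exact branch
    (the actual values are enumerated); the approximate branch applies the
    usual tie correction to the variance plus a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u = ranks[:n].sum() - n * (n + 1) / 2.0

    has_ties = np.unique(pooled).size < pooled.size
    if comb(n + m, n) <= MAX_EXACT_LABELINGS:
        if has_ties:
            p = _exact_mwu_pvalue_ties(ranks, u, n)
        else:
            p = _exact_mwu_pvalue_tiefree(u, n, m)
        method = "exact"
    else:
        mean = n * m / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum())
        total = n + m
        var = n * m / 12.0 * ((total + 1) - tie_term / (total * (total - 1)))
        if var <= 0:
            p = 1.0
        else:
            z = (abs(u - mean) - 0.5) / sqrt(var)
            z = max(z, 0.0)
            p = min(1.0, 2.0 * norm.sf(z))
        method = "normal-approximation"
    return GroupComparison("mann-whitney", float(u), float(p), (n, m), method)


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------

def _log_hypergeom_pmf(a, r1, r2, c1):
    n_total = r1 + r2
    return (
        gammaln(r1 + 1)
        - gammaln(a + 1)
        - gammaln(r1 - a + 1)
        + gammaln(r2 + 1)
        - gammaln(c1 - a + 1)
        - gammaln(r2 - c1 + a + 1)
        - (gammaln(n_total + 1) - gammaln(c1 + 1) - gammaln(n_total - c1 + 1))
    )


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> GroupComparison:
    """Two-sided Fisher exact test on the 2x2 table [[a, b], [c, d]].

    The two-sided p-value sums the hypergeometric probabilities, with the
    margins fixed, of every table at most as probable as the observed one
    (relative tolerance 1e-7 on the probability comparison, guarding against
    floating-point asymmetry between equally probable tables).
    """
    table = (a, b, c, d)
    if any(v < 0 or int(v) != v for v in table):
        raise ValueError("table entries must be non-negative integers")
    a, b, c, d = (int(v) for v in table)
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("every margin of the 2x2 table must be positive")
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    log_pmf = _log_hypergeom_pmf(support, r1, r2, c1)
    pmf = np.exp(log_pmf - log_pmf.max())
    pmf /= pmf.sum()
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    return GroupComparison(
        "fisher-exact", float(odds), min(1.0, p), (r1, r2), "exact"
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank_two_tailed(x, y) -> GroupComparison:
    """Two-tailed Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped; |differences| are mid-ranked.  With at most
    ``MAX_EXACT_SIGNS`` nonzero pairs all 2**n sign assignments are
    enumerated; beyond that a tie-corrected normal approximation with
    continuity correction is used.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size == 0:
        raise ValueError("paired samples must have equal positive length")
    diff = x - y
    diff = diff[diff != 0]
    n = diff.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return GroupComparison("wilcoxon-signed-rank", 0.0, 1.0, (0,), "exact")
    ranks = rankdata(np.abs(diff))
    w_plus = float(ranks[diff > 0].sum())
    rank_total = float(ranks.sum())

    if n <= MAX_EXACT_SIGNS:
        signs = (np.arange(2**n, dtype=np.uint32)[:, None] >> np.arange(n)) & 1
        w_all = signs.astype(np.float64) @ ranks
        p_low = np.mean(w_all <= w_plus + 1e-9)
        p_high = np.mean(w_all >= w_plus - 1e-9)
        p = min(1.0, 2.0 * min(p_low, p_high))
        method = "exact"
    else:
        mean = rank_total / 2.0
        _, tie_counts = np.unique(np.abs(diff), return_counts=True)
        var = (
            n * (n + 1) * (2 * n + 1) / 24.0
            - float((tie_counts**3 - tie_counts).sum()) / 48.0
        )
        z = (abs(w_plus - mean) - 0.5) / sqrt(var)
        z = max(z, 0.0)
        p = min(1.0, 2.0 * norm.sf(z))
        method = "normal-approximation"
    return GroupComparison("wilcoxon-signed-rank", w_plus, float(p), (n,), method)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_to_reference_mean(values, groups, reference, blocks=None):
    """Divide every value by the reference group's mean, per experiment block.

    Mirrors the convention of normalizing fluorescence values to the young
    mean within each independent experiment: within each block, every value
    (all groups) is divided by the mean of the ``reference`` group in that
    block.

    Parameters
    ----------
    values : array-like of float
    groups : array-like of labels, same length
    reference : label
        The group whose per-block mean becomes 1 after normalization.
    blocks : array-like of labels, optional
        Experiment/batch identifiers; one block if omitted.
    """
    values = np.asarray(values, dtype=float).ravel()
    groups = np.asarray(groups).ravel()
    if values.size != groups.size:
        raise ValueError("values and groups must have equal length")
    if blocks is None:
        blocks = np.zeros(values.size, dtype=int)
    else:
        blocks = np.asarray(blocks).ravel()
        if blocks.size != values.size:
            raise ValueError("blocks must match values in length")
    out = np.empty_like(values)
    for block in np.unique(blocks):
        sel = blocks == block
        ref = values[sel & (groups == reference)]
        if ref.size == 0:
            raise ValueError(f"reference group {reference!r} empty in block {block!r}")
        ref_mean = ref.mean()
        if ref_mean == 0:
            raise ValueError(f"reference mean is zero in block {block!r}")
        out[sel] = values[sel] / ref_mean
    return out
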