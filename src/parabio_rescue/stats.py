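"""Statistical primitives: Wilcoxon rank-sum test, Benjamini-Hochberg
step-up adjustment, and the single-cell log2 fold-change convention.

The rank-sum test is exact by enumeration of all C(m+n, m) group-label
assignments when that count is small, and otherwise uses the normal
approximation with midranks, tie correction and continuity correction.
The two-sided p-value in both regimes is the permutation-null probability
P(|W - E[W]| >= |w - E[W]|) for the rank sum W of the first sample; the
midrank multiset is symmetric about its mean, so this coincides with the
usual doubled one-sided tail.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
from scipy.stats import norm, rankdata

from .datatypes import ValidationError

#: Enumerate the exact permutation null only while C(m+n, m) stays below this.
EXACT_ENUMERATION_LIMIT = 200_000

_EPS = 1e-9


def rank_sum_test(
    x: np.ndarray,
    y: np.ndarray,
    exact_limit: int = EXACT_ENUMERATION_LIMIT,
) -> tuple[float, float]:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test.

    Returns ``(statistic, p_value)`` where the statistic is the rank sum
    of ``x`` in the pooled midranked sample.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank_sum_test requires non-empty samples")
    m, n = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[:m].sum())
    if comb(m + n, m) <= exact_limit:
        p = _exact_two_sided_p(ranks, m, w)
    else:
        p = _approx_two_sided_p(ranks, m, n, w)
    return w, p


def _exact_two_sided_p(ranks: np.ndarray, m: int, w: float) -> float:
    """P(|W - E| >= |w - E|) by enumerating every m-subset of the ranks."""
    N = ranks.size
    expected = m * (N + 1) / 2.0
    observed_dev = abs(w - expected)
    total = 0
    extreme = 0
    for combo in itertools.combinations(range(N), m):
        s = ranks[list(combo)].sum()
        total += 1
        if abs(s - expected) >= observed_dev - _EPS:
            extreme += 1
    return extreme / total


def _tie_term(values: np.ndarray) -> float:
    """sum over tie groups of (t^3 - t)."""
    _, counts = np.unique(values, return_counts=True)
    t = counts.astype(np.float64)
    return float(np.sum(t**3 - t))


def _approx_two_sided_p(ranks: np.ndarray, m: int, n: int, w: float) -> float:
    N = m + n
    expected = m * (N + 1) / 2.0
    tie = _tie_term(ranks)
    var = m * n / 12.0 * ((N + 1) - tie / (N * (N - 1)))
    if var <= 0:  # all pooled values identical
        return 1.0
    dev = abs(w - expected)
    z = max(dev - 0.5, 0.0) / np.sqrt(var)  # continuity correction
    return float(min(1.0, 2.0 * norm.sf(z)))


def rank_sum_test_bulk(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized normal-approximation rank-sum test over gene columns.

    ``X`` (m x G) and ``Y`` (n x G) hold per-cell values per gene; returns
    per-gene ``(statistics, p_values)`` identical to the scalar
    approximation path.  Used when the exact enumeration is infeasible.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    m, n = X.shape[0], Y.shape[0]
    if m == 0 or n == 0:
        raise ValidationError("rank_sum_test_bulk requires non-empty groups")
    N = m + n
    Z = np.vstack([X, Y])
    ranks = rankdata(Z, axis=0)
    w = ranks[:m].sum(axis=0)
    expected = m * (N + 1) / 2.0
    ties = np.empty(Z.shape[1])
    for g in range(Z.shape[1]):
        ties[g] = _tie_term(Z[:, g])
    var = m * n / 12.0 * ((N + 1) - ties / (N * (N - 1)))
    dev = np.abs(w - expected)
    z = np.zeros_like(dev)
    pos = var > 0
    z[pos] = np.maximum(dev[pos] - 0.5, 0.0) / np.sqrt(var[pos])
    p = np.minimum(1.0, 2.0 * norm.sf(z))
    p[~pos] = 1.0
    return w, p


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order.

    Sort ascending, scale p_(i) by n/i, enforce monotonicity by a
    cumulative minimum from the largest rank, cap at 1.
    """
    p = np.asarray(pvals, dtype=np.float64).ravel()
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    adjusted_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(n)
    out[order] = adjusted_sorted
    return out


def log2_fold_change(
    x_norm: np.ndarray, y_norm: np.ndarray, pseudo: float = 1.0
) -> float:
    """log2 ratio of back-transformed group means with a pseudocount.

    Inputs are normalized-layer values (natural-log scale); the fold
    change compares mean(exp(v) - 1), i.e. mean counts-per-scale, between
    the groups.  The pseudocount keeps the ratio finite for all-zero
    groups.
    """
    x_norm = np.asarray(x_norm, dtype=np.float64)
    y_norm = np.asarray(y_norm, dtype=np.float64)
    mx = float(np.mean(np.expm1(x_norm)))
    my = float(np.mean(np.expm1(y_norm)))
    return float(np.log2((mx + pseudo) / (my + pseudo)))


def log2_fold_change_bulk(
    X: np.ndarray, Y: np.ndarray, pseudo: float = 1.0
) -> np.ndarray:
    """Column-wise :func:`log2_fold_change` over gene matrices."""
    mx = np.mean(np.expm1(np.asarray(X, dtype=np.float64)), axis=0)
    my = np.mean(np.expm1(np.asarray(Y, dtype=np.float64)), axis=0)
    return np.log2((mx + pseudo) / (my + pseudo))
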