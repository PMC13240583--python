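"""Two-sample Wilcoxon rank-sum testing used throughout the pipeline.

Two code paths share one contract:

* an *exact* permutation path used whenever both groups have <= ``exact_max``
  observations. The permutation distribution of the rank-sum statistic
  (midranks, so ties are handled naturally) is built by a generating-function
  dynamic program over the pooled ranks, and the two-sided p-value is
  ``min(1, 2 * min(P(W <= w), P(W >= w)))``;
* a normal approximation with tie correction for larger groups (no
  continuity correction).

Constant pooled samples give p = 1 by convention.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

__all__ = ["rank_sum_test", "rank_sum_matrix", "bh_adjust"]

_EXACT_MAX = 8


def _exact_two_sided(ranks2: np.ndarray, n1: int, w2: int) -> float:
    """Exact two-sided p for rank-sum w2 (doubled integer midranks).

    ``ranks2`` are the pooled midranks times two (hence integers);
    the DP counts, for every subset size k <= n1 and rank total s, the
    number of subsets achieving it.
    """
    total = int(ranks2.sum())
    # dp[k][s] = number of k-subsets of processed ranks summing to s
    dp = np.zeros((n1 + 1, total + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        dp[1:, r:] += dp[:-1, : total + 1 - r]
    dist = dp[n1]
    n_comb = dist.sum()
    lo = dist[: w2 + 1].sum() / n_comb
    hi = dist[w2:].sum() / n_comb
    return float(min(1.0, 2.0 * min(lo, hi)))


def rank_sum_test(x: np.ndarray, y: np.ndarray, exact_max: int = _EXACT_MAX) -> float:
    """Two-sided Wilcoxon rank-sum p-value for samples ``x`` vs ``y``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    ranks = rankdata(pooled)
    w = ranks[:n1].sum()
    if n1 <= exact_max and n2 <= exact_max:
        ranks2 = np.round(ranks * 2).astype(np.int64)
        return _exact_two_sided(ranks2, n1, int(round(w * 2)))
    return _asymptotic_p(w, ranks, n1, n2)


def _asymptotic_p(w: float, ranks: np.ndarray, n1: int, n2: int) -> float:
    n = n1 + n2
    mean = n1 * (n + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (w - mean) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def rank_sum_matrix(
    values: np.ndarray, in_group: np.ndarray, exact_max: int = _EXACT_MAX
) -> np.ndarray:
    """Row-wise two-sided rank-sum p-values, group vs rest.

    ``values`` is genes x cells; ``in_group`` a boolean cell mask. The
    asymptotic path is vectorised across genes; the exact path is taken
    per-gene when both groups are small.
    """
    values = np.asarray(values, dtype=float)
    in_group = np.asarray(in_group, dtype=bool)
    n1 = int(in_group.sum())
    n2 = int((~in_group).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("empty group")
    if n1 <= exact_max and n2 <= exact_max:
        return np.array(
            [rank_sum_test(row[in_group], row[~in_group], exact_max) for row in values]
        )
    n = n1 + n2
    ranks = rankdata(values, axis=1)
    w = ranks[:, in_group].sum(axis=1)
    mean = n1 * (n + 1) / 2.0
    # per-row tie correction
    tie_term = np.empty(len(values))
    for i, row in enumerate(ranks):
        _, counts = np.unique(row, return_counts=True)
        tie_term[i] = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    p = np.ones(len(values))
    ok = var > 0
    z = np.zeros(len(values))
    z[ok] = (w[ok] - mean) / np.sqrt(var[ok])
    p[ok] = np.minimum(1.0, 2.0 * norm.sf(np.abs(z[ok])))
    # constant rows have var 0 -> p 1 already
    return p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
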