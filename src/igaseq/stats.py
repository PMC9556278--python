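"""Shared nonparametric test machinery.

All group comparisons in the pipeline are nonparametric: two-sample
Wilcoxon rank-sum tests, one-sample Wilcoxon signed-rank tests against
zero, Kruskal-Wallis tests, Spearman rank correlation, and
Benjamini-Hochberg FDR adjustment.  Small cohorts sit exactly where
exact and asymptotic null distributions disagree, so the switch-over
rules are fixed here once and used everywhere:

* rank-sum: exact null when both groups have <= 10 observations and the
  pooled data are tie-free; otherwise the normal approximation with tie
  and continuity correction.
* signed-rank: exact null when n <= 25 with no zeros among the
  differences; otherwise the normal approximation.
* Spearman: exact permutation null when n <= 9; otherwise the
  t-approximation.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "rank_sum_test",
    "signed_rank_test",
    "kruskal_wallis_test",
    "spearman_test",
]

_EXACT_RANKSUM_MAX_N = 10
_EXACT_SIGNRANK_MAX_N = 25
_EXACT_SPEARMAN_MAX_N = 9


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries (untested hypotheses) are passed through as NaN and do
    not count toward the family size.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns (U statistic for x, two-sided p).  Exact when both samples
    are small (<= 10) and tie-free, else normal approximation with tie
    and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires non-empty groups")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and max(x.size, y.size) <= _EXACT_RANKSUM_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def signed_rank_test(values, mu: float = 0.0) -> tuple[float, float]:
    """Two-sided one-sample Wilcoxon signed-rank test against ``mu``.

    Zero differences are dropped (Wilcoxon's convention).  Returns
    (W statistic, two-sided p).  With every difference equal to zero the
    test carries no evidence and p = 1.
    """
    d = np.asarray(values, dtype=float) - mu
    d = d[d != 0.0]
    if d.size == 0:
        return 0.0, 1.0
    if d.size <= _EXACT_SIGNRANK_MAX_N:
        method = "exact"
    else:
        method = "approx"
    try:
        res = sps.wilcoxon(d, alternative="two-sided", method=method)
    except ValueError:
        res = sps.wilcoxon(d, alternative="two-sided", method="approx")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def kruskal_wallis_test(groups) -> tuple[float, float]:
    """Kruskal-Wallis H test across >= 2 groups (chi-square null)."""
    if len(groups) < 2:
        raise ValueError("kruskal_wallis_test requires >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size < 2:
            raise ValueError("every class needs >= 2 samples")
    if all(np.all(g == arrays[0][0]) for g in arrays):
        # all observations identical: no evidence at all
        return 0.0, 1.0
    res = sps.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx * rx).sum() * (ry * ry).sum())
    if denom == 0:
        return np.nan
    return float((rx * ry).sum() / denom)


def spearman_test(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ties are handled by midranks.  For n <= 9 the p-value is the exact
    permutation probability P(|rho_perm| >= |rho_obs|) over all n!
    orderings; for larger n the usual t-approximation is used.
    Returns (rho, p).  Raises ValueError if either variable is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman_test needs paired vectors of length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("spearman rho undefined for a constant variable")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _spearman_rho(rx, ry)
    n = x.size
    if n <= _EXACT_SPEARMAN_MAX_N:
        # enumerate all n! orderings of one rank vector, vectorized
        perms = np.array(list(permutations(range(n))))
        permuted = ry[perms]  # n! x n
        pc = permuted - permuted.mean(axis=1, keepdims=True)
        rc = rx - rx.mean()
        denom = np.sqrt((pc * pc).sum(axis=1) * (rc * rc).sum())
        rhos = (pc @ rc) / denom
        p = float((np.abs(rhos) >= abs(rho) - 1e-12).mean())
        return rho, p
    # t-approximation
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return rho, float(min(p, 1.0))
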