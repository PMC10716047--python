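"""Rank-sum machinery and BH correction shared across modules.

The Wilcoxon rank-sum test here supports both an exact permutation null
(enumerating all assignments of the pooled values to the first group, correct
in the presence of ties) and the tie-corrected normal approximation.  Count
and TPM data are tie-heavy, which is why the exact path enumerates observed
values rather than assuming a continuous distribution.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats

__all__ = ["rank_sum_test", "bh_adjust"]


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def _exact_pvals(ranks: np.ndarray, n_a: int, w_obs: float) -> tuple[float, float]:
    """(P(W >= w_obs), P(W <= w_obs)) by full enumeration of C(n, n_a) subsets."""
    idx = range(len(ranks))
    sums = np.array([ranks[list(c)].sum() for c in combinations(idx, n_a)])
    eps = 1e-9
    p_ge = np.mean(sums >= w_obs - eps)
    p_le = np.mean(sums <= w_obs + eps)
    return float(p_ge), float(p_le)


def _normal_pvals(
    ranks: np.ndarray, n_a: int, w_obs: float
) -> tuple[float, float]:
    """Tie-corrected normal approximation with continuity correction."""
    n = len(ranks)
    n_b = n - n_a
    mu = n_a * (n + 1) / 2.0
    # tie correction on the rank variance
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / 1.0)
    if var <= 0:
        return 1.0, 1.0
    sd = np.sqrt(var)
    p_ge = float(stats.norm.sf((w_obs - 0.5 - mu) / sd))
    p_le = float(stats.norm.cdf((w_obs + 0.5 - mu) / sd))
    return p_ge, p_le


def rank_sum_test(
    a,
    b,
    alternative: str = "two-sided",
    exact_max_n: int = 12,
) -> tuple[float, float]:
    """Wilcoxon rank-sum test of group ``a`` against group ``b``.

    Returns ``(W, p)`` where W is the midrank sum of group ``a``.  Exact
    enumeration of the permutation null is used when the pooled size is at
    most ``exact_max_n``; otherwise a tie-corrected normal approximation
    with continuity correction.  ``alternative`` is one of ``greater``
    (a shifted up), ``less`` or ``two-sided``.

    Degenerate input where every pooled value is identical yields p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    w_obs = float(ranks[: a.size].sum())
    if np.all(pooled == pooled[0]):
        return w_obs, 1.0
    if pooled.size <= exact_max_n:
        p_ge, p_le = _exact_pvals(ranks, a.size, w_obs)
    else:
        p_ge, p_le = _normal_pvals(ranks, a.size, w_obs)
    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_ge, p_le))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return w_obs, float(min(max(p, np.nextafter(0, 1)), 1.0))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR).

    Standard step-up with monotonicity enforcement; invariant to input
    order (the output is returned in the input order).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out
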