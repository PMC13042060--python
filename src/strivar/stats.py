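"""Shared statistical utilities.

Small, heavily-reused primitives: Benjamini-Hochberg adjustment with an
explicitly declared family size, the Blom rank-based inverse-normal
transform, and a Wilcoxon rank-sum wrapper that switches between the exact
and the tie-corrected normal method.
"""

from __future__ import annotations

import numpy as np
from scipy import special
from scipy import stats as sps

__all__ = ["bh_adjust", "inverse_normal_transform", "wilcoxon_rank_sum"]


def bh_adjust(pvalues, family_size: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Parameters
    ----------
    pvalues : array-like
        Nominal p-values, each in [0, 1].
    family_size : int, optional
        Declared number of tests in the family. Defaults to ``len(pvalues)``.
        Must be at least ``len(pvalues)``; using a larger family treats the
        unsupplied tests as non-significant, which is conservative and lets
        callers adjust a subset against the full declared family.

    Returns
    -------
    numpy.ndarray
        Monotone step-up q-values, in the input order, clipped to [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1] and non-missing")
    m = p.size if family_size is None else int(family_size)
    if m < p.size:
        raise ValueError(
            f"family_size ({m}) smaller than the number of p-values ({p.size})"
        )
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(q)
    out[order] = np.clip(q, 0.0, 1.0)
    return out


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset.

    Maps ranks through ``(rank - 3/8) / (n + 1/4)`` and the standard normal
    quantile function. Ties receive the average rank.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    if np.allclose(x, x[0]):
        raise ValueError("all values identical; transform undefined")
    ranks = sps.rankdata(x, method="average")
    return special.ndtri((ranks - 0.375) / (x.size + 0.25))


def wilcoxon_rank_sum(x, y, exact_max_n: int = 25):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when both groups have fewer than ``exact_max_n``
    observations and there are no ties; otherwise the tie-corrected normal
    approximation with continuity correction.

    Returns ``(statistic, pvalue)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if max(x.size, y.size) < exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
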