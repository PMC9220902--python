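"""Shared nonparametric statistics helpers.

Rank-based operations used across modules: Holm step-down adjustment,
Spearman rank correlation with an exact permutation p-value for very small
cohorts (the usual situation when correlating protein abundance with a
per-model sensitivity grade across a handful of PDM models).
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="holm")[1]


def spearman_r(x, y) -> float:
    """Spearman rank correlation with average-rank tie handling."""
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_exact_p(x, y) -> float:
    """Two-sided exact permutation p-value for Spearman's r.

    Enumerates all n! permutations of ``y`` and counts those whose |r| is at
    least the observed |r|.  Intended for n <= 8 (40,320 permutations at
    most); use the t-approximation beyond that.
    """
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    r_obs = spearman_r(x, y)
    if not np.isfinite(r_obs):
        return float("nan")
    rx_c = rx - rx.mean()
    denom_x = np.sqrt((rx_c**2).sum())
    count = 0
    total = 0
    for perm in permutations(ry):
        py = np.asarray(perm)
        py_c = py - py.mean()
        denom_y = np.sqrt((py_c**2).sum())
        r = float(rx_c @ py_c) / (denom_x * denom_y)
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_with_p(x, y, exact_max_n: int = 8) -> tuple[float, float, str]:
    """Spearman r with a two-sided p-value.

    Exact permutation enumeration for n <= ``exact_max_n``; the standard
    t-approximation otherwise.  Returns (r, p, method).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = spearman_r(x, y)
    if not np.isfinite(r):
        return r, float("nan"), "undefined"
    if len(x) <= exact_max_n:
        return r, spearman_exact_p(x, y), "exact-permutation"
    return r, float(stats.spearmanr(x, y).pvalue), "t-approximation"
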