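"""Shared statistical helpers (rank correlation, FDR adjustment)."""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

EXACT_SPEARMAN_MAX_N = 9


def spearman(x, y) -> tuple[float | None, float | None]:
    """Spearman rank correlation with midrank ties.

    P value by the large-sample t approximation, replaced by an exact
    permutation enumeration for n <= 9.  Degenerate inputs (constant
    ranks) yield ``(None, None)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return None, None
    rho = float(stats.spearmanr(x, y).statistic)
    n = x.size
    if n <= EXACT_SPEARMAN_MAX_N:
        p = _exact_spearman_p(x, y, abs(rho))
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, abs_rho: float) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    count = 0
    total = 0
    for perm in permutations(range(len(ry))):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(r) >= abs_rho - 1e-12:
            count += 1
        total += 1
    return count / total


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def ranksum_p(a, b) -> float | None:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) P, None on degenerate input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        return None
    if np.unique(np.concatenate([a, b])).size < 2:
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
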