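"""Paired hypothesis testing and multiplicity correction.

Thin, flagged wrappers: paired Wilcoxon signed-rank (exact distribution for
small tie-free samples, normal approximation with continuity correction
otherwise), Benjamini–Hochberg FDR, and Spearman rank correlation.  Degenerate
inputs (all-zero differences, constant vectors) yield an explicit
``undefined`` flag instead of an exception, so that figure-style sweeps over
many comparisons can proceed.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


class TestResult(NamedTuple):
    statistic: float
    pvalue: float
    n: int
    undefined: bool = False


def paired_wilcoxon(x, y, exact_max_n: int = 25) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped before ranking.  The exact null distribution
    is used for n <= ``exact_max_n`` without ties in |differences|; otherwise
    the normal approximation with continuity correction.  All differences zero
    -> undefined result (statistic/p NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if len(d) < 1:
        return TestResult(np.nan, np.nan, 0, undefined=True)
    absd = np.abs(d)
    has_ties = len(np.unique(absd)) < len(absd)
    method = "exact" if (len(d) <= exact_max_n and not has_ties) else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", method=method, correction=True)
    return TestResult(float(res.statistic), float(res.pvalue), len(d))


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with average-rank tie handling.

    Constant input -> undefined (rho NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("samples must have equal length")
    if len(x) < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult(np.nan, np.nan, len(x), undefined=True)
    rho, p = sps.spearmanr(x, y)
    return TestResult(float(rho), float(p), len(x))
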