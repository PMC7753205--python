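"""Shared statistical helpers: exact tests, FDR, presentation rounding."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def binom_test_balanced(k, n):
    """Two-sided exact binomial p-value against p = 0.5, vectorized.

    Uses the minimum-likelihood two-sided rule: the p-value sums P(j) over
    all outcomes j with P(j) <= P(k).  For a symmetric binomial this equals
    both tails beyond (and including) k and its mirror image n - k, i.e.
    min(1, 2 * CDF(min(k, n - k))).  Entries with n == 0 yield NaN.
    """
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("require 0 <= k <= n")
    lo = np.minimum(k, n - k)
    with np.errstate(invalid="ignore"):
        p = np.minimum(1.0, 2.0 * stats.binom.cdf(lo, np.maximum(n, 1), 0.5))
    p = np.where(n > 0, p, np.nan)
    if p.ndim == 0:
        return float(p)
    return p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone-capped)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero, matching how tables are printed."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
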