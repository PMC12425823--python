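"""Shared statistical primitives used across the pipeline.

All functions are vectorised over numpy arrays; scalar inputs work too.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "bh_fdr",
    "two_proportion_pvalue",
    "fisher_exact_doubled",
    "midp_signed_z",
    "stouffer",
]


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (q-values). NaNs propagate."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    n = pv.size
    if n == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def two_proportion_pvalue(k1, n1, k2, n2):
    """Two-sided pooled two-proportion z-test.

    Returns p-values; degenerate cells (zero pooled variance) give p = 1.
    """
    k1 = np.asarray(k1, float)
    n1 = np.asarray(n1, float)
    k2 = np.asarray(k2, float)
    n2 = np.asarray(n2, float)
    pooled = (k1 + k2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (k1 / n1 - k2 / n2) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.where(var > 0, p, 1.0)


def fisher_exact_doubled(k1, n1, k2, n2):
    """Two-sided Fisher exact p by tail doubling, vectorised.

    Conditions on the margins of the 2x2 table [[k1, n1-k1], [k2, n2-k2]]:
    p = min(1, 2*min(P(X<=k1), P(X>=k1))) with X ~ Hypergeom(n1+n2, k1+k2, n1).
    Slightly conservative relative to the minimum-likelihood rule but
    vectorisable; agreement with scipy.stats.fisher_exact is asserted in tests.
    """
    k1 = np.asarray(k1)
    n1 = np.asarray(n1)
    k2 = np.asarray(k2)
    n2 = np.asarray(n2)
    M = n1 + n2
    K = k1 + k2
    lo = stats.hypergeom.cdf(k1, M, K, n1)
    hi = stats.hypergeom.sf(k1 - 1, M, K, n1)
    return np.minimum(1.0, 2.0 * np.minimum(lo, hi))


def midp_signed_z(k1, n1, k2, n2):
    """Signed z-score from the mid-p of the conditional (hypergeometric) test.

    Positive values indicate the first proportion exceeds the second.  The
    mid-p correction (half the point probability) makes the statistic nearly
    unbiased for discrete counts, which matters when many such scores are
    combined.
    """
    k1 = np.asarray(k1)
    M = np.asarray(n1) + np.asarray(n2)
    K = k1 + np.asarray(k2)
    p_hi = stats.hypergeom.sf(k1, M, K, n1) + 0.5 * stats.hypergeom.pmf(k1, M, K, n1)
    p_hi = np.clip(p_hi, 1e-300, 1.0 - 1e-16)
    return stats.norm.isf(p_hi)


def stouffer(z, axis=-1, weights=None):
    """Stouffer combination of z-scores; returns (z_combined, two-sided p)."""
    z = np.asarray(z, float)
    if weights is None:
        zc = z.sum(axis=axis) / np.sqrt(z.shape[axis])
    else:
        w = np.asarray(weights, float)
        zc = np.tensordot(z, w, axes=([axis], [0])) / np.sqrt((w ** 2).sum())
    return zc, 2.0 * stats.norm.sf(np.abs(zc))
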