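"""Shared statistical primitives.

One hypergeometric tail implementation backs both the hub-gene neighborhood
test and gene-set over-representation, so the two stages are bit-identical
on the same contingency counts.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def hypergeom_tail(a, N, K, m) -> np.ndarray | float:
    """Upper hypergeometric tail P(X >= a), X ~ Hypergeom(N, K, m).

    The urn holds ``N`` items of which ``K`` are marked; ``m`` are drawn
    without replacement; ``a`` marked items are observed.  Equivalent to the
    one-sided (enrichment) Fisher exact p for the 2x2 table
    ``[[a, m-a], [K-a, N-m-K+a]]``.
    """
    a = np.asarray(a)
    p = stats.hypergeom.sf(a - 1, N, K, m)
    return float(p) if p.ndim == 0 else p


def fisher_two_sided(a: int, N: int, K: int, m: int) -> float:
    """Two-sided Fisher exact p for the same 2x2 table as :func:`hypergeom_tail`."""
    table = [[a, m - a], [K - a, N - m - K + a]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def paired_t(
    x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise two-sided paired t-test of x vs y (features x pairs).

    Returns ``(t, p, zero_variance)``.  Rows whose paired differences have
    zero variance get t=0, p=1 and the flag set — never NaN — because a
    constant difference carries no within-pair evidence for this test.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValueError("paired arrays must have identical shape")
    n = x.shape[1]
    if n < 2:
        raise ValueError("paired t-test needs at least 2 complete pairs")
    d = x - y
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    zero_var = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[zero_var] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p[zero_var] = 1.0
    return t, p, zero_var
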