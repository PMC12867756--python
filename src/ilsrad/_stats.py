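"""Small shared statistical helpers."""

from __future__ import annotations

import math

from scipy import stats


def two_proportion_z_test(n1, n2, n_total):
    """Two-sided z-test for equality of two category proportions of the same
    multinomial sample.

    Var(p1^ - p2^) = (p1 + p2 - (p1-p2)^2) / n for one multinomial of size
    ``n_total``.  Returns (z, p).
    """
    if n_total <= 0:
        raise ValueError("empty sample")
    p1, p2 = n1 / n_total, n2 / n_total
    var = (p1 + p2 - (p1 - p2) ** 2) / n_total
    if var == 0:
        return 0.0, 1.0
    z = (p1 - p2) / math.sqrt(var)
    return z, 2.0 * stats.norm.sf(abs(z))


def conditional_binomial_test(n1, n2, alternative="two-sided"):
    """Exact test of n1 = n2 for two categories of one multinomial,
    conditional on n1 + n2 (Binomial(n1+n2, 1/2) under H0)."""
    if n1 + n2 == 0:
        return 1.0
    return stats.binomtest(n1, n1 + n2, 0.5, alternative=alternative).pvalue
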