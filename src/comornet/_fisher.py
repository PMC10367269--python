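"""Two-sided Fisher exact test for 2x2 tables.

For small tables (total count up to ``EXACT_MAX``) the p-value is computed
by exact integer enumeration of the conditional hypergeometric
distribution: every table compatible with the margins contributes when its
probability numerator (an integer) is at most the observed one, and the
final division is performed with rational arithmetic so the returned double
is correctly rounded. Larger tables are delegated to
``scipy.stats.fisher_exact``.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
from scipy.stats import fisher_exact as _scipy_fisher

EXACT_MAX = 500

__all__ = ["fisher_exact_2x2", "EXACT_MAX"]


def _fisher_exact_int(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided p by integer enumeration over the margin support."""
    n = a + b + c + d
    r = a + b  # row-1 margin
    s = a + c  # col-1 margin
    k_lo = max(0, r + s - n)
    k_hi = min(r, s)
    # P(k) = C(r, k) C(n-r, s-k) / C(n, s); compare integer numerators.
    num_obs = comb(r, a) * comb(n - r, s - a)
    total = 0
    for k in range(k_lo, k_hi + 1):
        num = comb(r, k) * comb(n - r, s - k)
        if num <= num_obs:
            total += num
    return float(Fraction(total, comb(n, s)))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value of the table [[a, b], [c, d]].

    Tables with a zero margin carry no information; the p-value is 1.
    """
    a, b, c, d = int(a), int(b), int(c), int(d)
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    n = a + b + c + d
    if n == 0 or (a + b) in (0, n) or (a + c) in (0, n):
        return 1.0
    if n <= EXACT_MAX:
        return _fisher_exact_int(a, b, c, d)
    return float(_scipy_fisher(np.array([[a, b], [c, d]])).pvalue)
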