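"""Independent Clopper-Pearson oracle: bisection on exact binomial tails.

Uses only ``math.comb`` summation — no beta-distribution quantiles — so it
can cross-check the implementation's beta-quantile bounds.
"""

import math


def _binom_tail_ge(k, n, p):
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


def _binom_tail_le(k, n, p):
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(0, k + 1))


def cp_bruteforce(k, n, level=0.95, tol=1e-9):
    """Exact binomial CI bounds in percent, by bisection to ``tol``."""
    alpha = 1 - level
    if k == 0:
        lo = 0.0
    else:
        a, b = 0.0, 1.0
        while b - a > tol:
            m = (a + b) / 2
            a, b = (m, b) if _binom_tail_ge(k, n, m) < alpha / 2 else (a, m)
        lo = (a + b) / 2
    if k == n:
        hi = 1.0
    else:
        a, b = 0.0, 1.0
        while b - a > tol:
            m = (a + b) / 2
            a, b = (a, m) if _binom_tail_le(k, n, m) < alpha / 2 else (m, b)
        hi = (a + b) / 2
    return 100 * lo, 100 * hi
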