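"""Independent brute-force reference implementations used only by tests.

Everything here is exact rational arithmetic (stdlib Fraction / math.comb),
deliberately sharing no code with the package under test.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def frac_audic_pmf(x: int, y: int, n1: int, n2: int) -> Fraction:
    r = Fraction(n2, n1)
    return r**y * comb(x + y, y) / (1 + r) ** (x + y + 1)


def frac_audic_lower(x: int, y: int, n1: int, n2: int) -> Fraction:
    return sum(frac_audic_pmf(x, k, n1, n2) for k in range(y + 1))


def frac_audic_pvalue(x: int, y: int, n1: int, n2: int) -> Fraction:
    lower = frac_audic_lower(x, y, n1, n2)
    upper = 1 - (frac_audic_lower(x, y - 1, n1, n2) if y > 0 else Fraction(0))
    return min(Fraction(1), 2 * min(lower, upper))


def bh_brute(p_values) -> list[float]:
    """Textbook step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    m = len(p_values)
    indexed = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(indexed, start=1):
        candidates = []
        for other_pos, j in enumerate(indexed, start=1):
            if other_pos >= rank_pos:
                candidates.append(p_values[j] * m / other_pos)
        q[i] = min(1.0, min(candidates))
    return q


def frac_hypergeom_upper(m: int, n: int, M: int, N: int) -> Fraction:
    """P(X >= m) by exhaustive enumeration of the hypergeometric pmf."""
    total = comb(N, n)
    acc = Fraction(0)
    for i in range(m, min(n, M) + 1):
        if n - i > N - M:
            continue
        acc += Fraction(comb(M, i) * comb(N - M, n - i), total)
    return acc
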