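"""Independent reference implementations used only by the tests.

Everything here is exact (rational arithmetic) or textbook-direct, and
deliberately shares no code with the package internals it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction


def ac_pmf_exact(x: int, y: int, n2_over_n1: Fraction) -> Fraction:
    """P(y|x) = r^y (x+y)!/(x!y!) / (1+r)^(x+y+1), exact."""
    r = Fraction(n2_over_n1)
    return r**y * Fraction(math.comb(x + y, y)) / (1 + r) ** (x + y + 1)


def ac_lower_cumulative(x: int, ymax: int, n2_over_n1: Fraction) -> list[Fraction]:
    """Exact cumulative lower tails F[y] = P(Y <= y) for y = 0..ymax."""
    r = Fraction(n2_over_n1)
    q = r / (1 + r)
    pmf = (1 / (1 + r)) ** (x + 1)
    cum = [pmf]
    for y in range(1, ymax + 1):
        pmf = pmf * q * Fraction(x + y, y)
        cum.append(cum[-1] + pmf)
    return cum


def ac_two_sided_exact(y: int, cum: list[Fraction]) -> Fraction:
    """Two-sided p from an exact cumulative table (2*min(tails), capped)."""
    lower = cum[y]
    upper = 1 - (cum[y - 1] if y > 0 else Fraction(0))
    return min(Fraction(1), 2 * min(lower, upper))


def hypergeom_pmf_exact(N: int, M: int, n: int) -> dict[int, Fraction]:
    """Full exact hypergeometric mass over the feasible support."""
    denom = math.comb(N, n)
    lo = max(0, n + M - N)
    hi = min(M, n)
    return {
        i: Fraction(math.comb(M, i) * math.comb(N - M, n - i), denom)
        for i in range(lo, hi + 1)
    }


def hypergeom_upper_exact(N: int, n: int, M: int, m: int) -> Fraction:
    """P(X >= m) as one minus the enumerated lower mass (complement route)."""
    pmf = hypergeom_pmf_exact(N, M, n)
    return 1 - sum((p for i, p in pmf.items() if i < m), Fraction(0))


def welch_t_exact(a, b) -> tuple[float, float]:
    """Textbook Welch t statistic and degrees of freedom (no p-value)."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((v - ma) ** 2 for v in a) / (na - 1)
    vb = sum((v - mb) ** 2 for v in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df
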