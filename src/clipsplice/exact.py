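"""Exact small-table statistics.

Two-sided Fisher's exact test and the upper-tail hypergeometric overlap
probability, both computed by enumerating the hypergeometric support with
exact integer binomial coefficients and performing a single final division.
The enumeration is exact (no floating accumulation over probabilities), so
results agree with a brute-force rational-arithmetic oracle to the last bit
of the final float division.

Intended for the table sizes this pipeline produces (margins up to a few
thousand); complexity is linear in the smaller row margin.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    Sums P(T = t) over all tables t with the observed margins whose point
    probability does not exceed that of the observed table (ties included
    exactly, via integer comparison).
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("table entries must be non-negative")
    r1, r2 = a + b, c + d
    n1 = a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    lo = max(0, n1 - r2)
    hi = min(n1, r1)
    # weight(t) = C(r1, t) * C(r2, n1 - t); P(t) = weight(t) / C(n, n1)
    w_obs = comb(r1, a) * comb(r2, n1 - a)
    num = 0
    for t in range(lo, hi + 1):
        w = comb(r1, t) * comb(r2, n1 - t)
        if w <= w_obs:
            num += w
    return float(Fraction(num, comb(n, n1)))


def hypergeom_upper_tail(k: int, universe: int, n_a: int, n_b: int) -> float:
    """P(X >= k) for X ~ Hypergeom(universe, n_a, n_b).

    Probability that two sets of sizes ``n_a`` and ``n_b`` drawn from a
    universe of ``universe`` elements share at least ``k`` members.
    """
    if universe <= 0:
        raise ValueError("empty universe")
    if n_a > universe or n_b > universe:
        raise ValueError("set larger than universe")
    lo = max(0, n_a + n_b - universe)
    hi = min(n_a, n_b)
    if k <= lo:
        return 1.0
    if k > hi:
        return 0.0
    num = sum(comb(n_a, t) * comb(universe - n_a, n_b - t) for t in range(k, hi + 1))
    return float(Fraction(num, comb(universe, n_b)))
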