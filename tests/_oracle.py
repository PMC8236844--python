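"""Brute-force exact-integer oracle for conditional 2x2 tests.

Enumerates the full hypergeometric support with integer binomial-coefficient
weights, so tail sums and likelihood/acceptability comparisons are exact
(no floating-point ties). Independent of the package implementation, which
works in log space.
"""

from math import comb


def oracle_fisher(a: int, b: int, c: int, d: int, method: str) -> float:
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(c1, r1)
    if lo == hi:
        return 1.0
    w = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)}
    den = comb(n, c1)
    lower = sum(v for x, v in w.items() if x <= a)
    upper = sum(v for x, v in w.items() if x >= a)
    if method == "one_sided_greater":
        return upper / den
    if method == "central":
        return min(1.0, 2 * min(lower, upper) / den)
    if method == "minlike":
        return sum(v for v in w.values() if v <= w[a]) / den

    def acc(x: int) -> int:
        return min(
            sum(v for y, v in w.items() if y <= x),
            sum(v for y, v in w.items() if y >= x),
        )

    aa = acc(a)
    return min(1.0, sum(v for x, v in w.items() if acc(x) <= aa) / den)
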