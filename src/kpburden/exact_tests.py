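"""Exact conditional tests for 2x2 tables.

Conditioning on both margins, the count ``a`` in the upper-left cell follows
a (central) hypergeometric distribution. Several two-sided p-value
definitions are in common use and can disagree appreciably for rare-variant
tables:

``central``
    twice the smaller tail probability, capped at 1 (the default of the
    exact2x2 R package);
``minlike``
    the sum of probabilities of all outcomes no more likely than the
    observed one (the classical Fisher test of R's fisher.test and
    scipy.stats.fisher_exact);
``blaker``
    Blaker's acceptability method: the sum of probabilities of outcomes
    whose smaller-tail ("acceptability") value does not exceed that of the
    observed outcome;
``one_sided_greater``
    the upper-tail enrichment test P(X >= a).

Probabilities are accumulated from log-space hypergeometric masses;
likelihood/acceptability comparisons use a relative tolerance (default 1e-7,
matching R's convention) so exact ties across the two tails are honoured.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom

from ._util import DataError

TWO_SIDED_METHODS = ("central", "minlike", "blaker", "one_sided_greater")


def _validate(a: int, b: int, c: int, d: int) -> None:
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if int(v) != v or v < 0:
            raise DataError(f"2x2 cell {name} must be a non-negative integer, got {v!r}")


def fisher_exact_2x2(
    table: tuple[int, int, int, int],
    method: str = "central",
    eps: float = 1e-7,
) -> float:
    """Exact conditional p-value for a 2x2 table under the chosen method.

    ``table`` is (a, b, c, d) row-wise: cases with / without the feature,
    controls with / without. Degenerate tables (an empty margin) have a
    single attainable outcome and return 1.
    """
    a, b, c, d = (int(x) for x in table)
    _validate(a, b, c, d)
    if method not in TWO_SIDED_METHODS:
        raise DataError(f"unknown method {method!r}; expected one of {TWO_SIDED_METHODS}")

    row1, row2 = a + b, c + d
    col1 = a + c
    total = row1 + row2
    lo, hi = max(0, col1 - row2), min(col1, row1)
    if lo == hi:  # single attainable outcome
        return 1.0

    support = np.arange(lo, hi + 1)
    logpmf = hypergeom.logpmf(support, total, row1, col1)
    pmf = np.exp(logpmf)
    pmf /= pmf.sum()  # the conditional support carries all the mass
    idx = a - lo
    lower = float(pmf[: idx + 1].sum())
    upper = float(pmf[idx:].sum())

    if method == "one_sided_greater":
        p = upper
    elif method == "central":
        p = 2.0 * min(lower, upper)
    elif method == "minlike":
        p = float(pmf[logpmf <= logpmf[idx] + np.log1p(eps)].sum())
    else:  # blaker
        cum_lower = np.cumsum(pmf)
        cum_upper = np.cumsum(pmf[::-1])[::-1]
        accept = np.minimum(cum_lower, cum_upper)
        p = float(pmf[accept <= accept[idx] * (1.0 + eps)].sum())
    p = float(min(1.0, max(p, float(pmf[idx]))))
    return 1.0 if p > 1.0 - 1e-9 else p  # snap float residue on exact-1 tables
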