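"""2x2 contingency statistics: one-sided Fisher exact, chi-square, EASE.

All three return a :class:`ContingencyResult` carrying the table, the test
statistic (where one exists), the p-value and the sample odds ratio.  The
Fisher test is one-sided in the enrichment direction ("greater"): every use
in this pipeline is an enrichment claim.  The EASE score is the conservative
jackknifed variant of the Fisher test used by annotation-enrichment tools:
one gene is removed from the overlap cell before computing the tail, so a
single-gene overlap can never score as significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats as sps

Table = tuple[tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class ContingencyResult:
    table: Table
    statistic: float | None  # None where the test has no natural statistic
    p_value: float
    method: str  # fisher_one_sided_greater | chi_square | ease
    odds_ratio: float


def _cells(table: Table) -> tuple[int, int, int, int]:
    (a, b), (c, d) = table
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError(f"table cells must be nonnegative integers: {table}")
    return tuple(int(x) for x in cells)  # type: ignore[return-value]


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return math.inf if a * d > 0 else (0.0 if a * d == 0 and (b or c) else math.nan)
    return (a * d) / (b * c)


def fisher_exact_2x2(table: Table) -> ContingencyResult:
    """One-sided (greater) Fisher exact test on a 2x2 table.

    The p-value is the hypergeometric upper tail P(X >= a) with the table's
    margins fixed.  Degenerate margins (an empty row or column) leave the
    whole mass in the tail, so p = 1.
    """
    a, b, c, d = _cells(table)
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero table")
    # upper tail at the observed overlap: P(X >= a) for X ~ Hypergeom(n, a+c, a+b)
    p = float(sps.hypergeom.sf(a - 1, n, a + c, a + b))
    p = min(max(p, math.nextafter(0.0, 1.0)), 1.0)
    return ContingencyResult(
        table=((a, b), (c, d)),
        statistic=None,
        p_value=p,
        method="fisher_one_sided_greater",
        odds_ratio=_odds_ratio(a, b, c, d),
    )


def chi_square_2x2(table: Table, yates: bool = False) -> ContingencyResult:
    """Pearson chi-square test of independence on a 2x2 table (1 df).

    statistic = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), without continuity
    correction by default; ``yates=True`` applies the Yates correction.
    All four margins must be positive.
    """
    a, b, c, d = _cells(table)
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        raise ValueError(f"chi-square requires all margins > 0: {table}")
    dev = abs(a * d - b * c)
    if yates:
        dev = max(dev - n / 2.0, 0.0)
    stat = n * dev * dev / math.prod(margins)
    p = float(sps.chi2.sf(stat, df=1))
    p = min(max(p, math.nextafter(0.0, 1.0)), 1.0)
    return ContingencyResult(
        table=((a, b), (c, d)),
        statistic=stat,
        p_value=p,
        method="chi_square",
        odds_ratio=_odds_ratio(a, b, c, d),
    )


def ease_score(k: int, n: int, K: int, M: int) -> ContingencyResult:
    """EASE score: jackknifed one-sided Fisher exact enrichment p.

    Parameters are the usual enrichment counts — ``k`` list hits, ``n`` list
    size, ``K`` population hits, ``M`` population size.  One hit is removed
    from the overlap cell (margins adjusted consistently, population
    preserved) before the Fisher tail is computed, i.e. the test is run on

        ((k-1, n-k), (K-k+1, M-n-K+k))

    By convention k = 0 scores p = 1.
    """
    for name, v in (("k", k), ("n", n), ("K", K), ("M", M)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a nonnegative integer")
    k, n, K, M = int(k), int(n), int(K), int(M)
    if k > min(n, K) or n > M or K > M or M - n - K + k < 0:
        raise ValueError(f"inconsistent counts (k={k}, n={n}, K={K}, M={M})")
    if k == 0:
        table = ((0, n), (K, M - n - K))
        return ContingencyResult(
            table=table, statistic=None, p_value=1.0, method="ease",
            odds_ratio=_odds_ratio(*_cells(table)),
        )
    jack = ((k - 1, n - k), (K - k + 1, M - n - K + k))
    inner = fisher_exact_2x2(jack)
    return ContingencyResult(
        table=jack,
        statistic=None,
        p_value=inner.p_value,
        method="ease",
        odds_ratio=inner.odds_ratio,
    )
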