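"""Exact and asymptotic independence tests for 2x2 contingency tables.

Fisher's exact test conditions on both margins of the table: under the null
of independence the top-left cell follows a hypergeometric distribution, and
the two-sided p-value is the total probability of all tables (with the same
margins) that are no more probable than the observed one — the probability-
mass rule used by R's ``fisher.test``.  Probabilities are computed through
log-factorials so large tables cannot overflow.

The chi-square test (optional Yates continuity correction) is provided as the
usual large-sample companion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import chi2 as _chi2_dist

from .errors import DomainError

#: Relative tolerance absorbing floating-point ties in the two-sided rule.
PMF_TIE_TOLERANCE = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts (n11, n12 / n21, n22); rows = dependent factor,
    columns = classifier (hypothesis vs complement)."""

    n11: int
    n12: int
    n21: int
    n22: int

    def __post_init__(self) -> None:
        for cell in (self.n11, self.n12, self.n21, self.n22):
            if not isinstance(cell, int) or cell < 0:
                raise DomainError(f"cell counts must be non-negative integers, got {cell!r}")

    @property
    def total(self) -> int:
        return self.n11 + self.n12 + self.n21 + self.n22

    @property
    def row_totals(self) -> tuple[int, int]:
        return (self.n11 + self.n12, self.n21 + self.n22)

    @property
    def col_totals(self) -> tuple[int, int]:
        return (self.n11 + self.n21, self.n12 + self.n22)

    def cells(self) -> tuple[int, int, int, int]:
        return (self.n11, self.n12, self.n21, self.n22)

    def odds_ratio(self, haldane: bool = False) -> float:
        """Sample odds ratio; ``haldane`` adds 0.5 to every cell (finite with zeros)."""
        a, b, c, d = self.cells()
        if haldane:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        if b * c == 0:
            return math.inf if a * d > 0 else math.nan
        return (a * d) / (b * c)


@dataclass(frozen=True)
class TestResult:
    p_value: float
    method: str
    table: ContingencyTable2x2
    statistic: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise DomainError(f"p-value {self.p_value} outside [0, 1]")


def _log_factorials(n: int) -> list[float]:
    out = [0.0] * (n + 1)
    for i in range(2, n + 1):
        out[i] = out[i - 1] + math.log(i)
    return out


def hypergeometric_pmf(a: int, row1_total: int, col1_total: int, n: int) -> float:
    """P(A = a) for the hypergeometric cell distribution of a 2x2 table.

    ``a`` is the top-left cell, ``row1_total``/``col1_total`` the first-row and
    first-column margins, ``n`` the grand total:

        P(A=a) = C(c1, a) C(n-c1, r1-a) / C(n, r1)
    """
    if n < 0 or not (0 <= row1_total <= n) or not (0 <= col1_total <= n):
        raise DomainError(f"inconsistent margins r1={row1_total}, c1={col1_total}, n={n}")
    lo = max(0, row1_total + col1_total - n)
    hi = min(row1_total, col1_total)
    if not (lo <= a <= hi):
        raise DomainError(f"cell a={a} infeasible for margins ({row1_total}, {col1_total}, {n})")
    lf = _log_factorials(n)

    def log_comb(m: int, k: int) -> float:
        return lf[m] - lf[k] - lf[m - k]

    log_p = (
        log_comb(col1_total, a)
        + log_comb(n - col1_total, row1_total - a)
        - log_comb(n, row1_total)
    )
    return math.exp(log_p)


def fisher_exact(
    table: ContingencyTable2x2 | tuple[int, int, int, int],
    alternative: str = "two-sided",
) -> TestResult:
    """Fisher's exact test for a 2x2 table.

    ``two-sided`` (default) sums hypergeometric probabilities of all tables
    with the observed margins whose probability does not exceed the observed
    table's (within a small relative tolerance for floating-point ties);
    ``less``/``greater`` are the one-sided tail sums on the top-left cell.
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*table)
    n = table.total
    if n < 1:
        raise DomainError("Fisher's exact test is undefined for an all-zero table")
    r1, _ = table.row_totals
    c1, _ = table.col_totals
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    pmf = {k: hypergeometric_pmf(k, r1, c1, n) for k in range(lo, hi + 1)}
    observed = pmf[table.n11]

    if alternative == "two-sided":
        cutoff = observed * (1.0 + PMF_TIE_TOLERANCE)
        p = sum(v for v in pmf.values() if v <= cutoff)
    elif alternative == "less":
        p = sum(v for k, v in pmf.items() if k <= table.n11)
    elif alternative == "greater":
        p = sum(v for k, v in pmf.items() if k >= table.n11)
    else:
        raise DomainError(f"unknown alternative {alternative!r}")
    return TestResult(p_value=min(p, 1.0), method=f"fisher-exact ({alternative})", table=table)


def chi_square(
    table: ContingencyTable2x2 | tuple[int, int, int, int],
    yates_correction: bool = False,
) -> TestResult:
    """Pearson chi-square test of independence, 1 degree of freedom.

    With ``yates_correction`` the statistic uses ``(|O - E| - 0.5)^2 / E``
    (floored at zero), which never exceeds the uncorrected statistic.
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*table)
    r1, r2 = table.row_totals
    c1, c2 = table.col_totals
    if min(r1, r2, c1, c2) == 0:
        raise DomainError("chi-square is undefined when a margin is zero")
    n = table.total
    c = 0.5 if yates_correction else 0.0
    stat = 0.0
    for obs, rt, ct in (
        (table.n11, r1, c1), (table.n12, r1, c2),
        (table.n21, r2, c1), (table.n22, r2, c2),
    ):
        expected = rt * ct / n
        dev = max(abs(obs - expected) - c, 0.0)
        stat += dev * dev / expected
    p = float(_chi2_dist.sf(stat, df=1))
    name = "chi-square (Yates)" if yates_correction else "chi-square"
    return TestResult(p_value=p, method=name, table=table, statistic=stat)
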