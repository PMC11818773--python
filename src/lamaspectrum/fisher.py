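"""Two-sided Fisher exact test on 2x2 allele-count tables.

Implemented from first principles under the minimum-likelihood two-sided
convention: the p-value is the sum of hypergeometric probabilities of all
tables sharing the observed margins whose probability does not exceed the
observed table's (within a relative tie tolerance of 1e-7 — the
convention of mainstream statistics packages). Small tables use exact
integer arithmetic; large tables use log-gamma arithmetic with a stable
log-sum-exp accumulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "ContingencyTable2x2",
    "ExactTestResult",
    "fisher_two_sided",
    "compare_frequencies",
    "TIE_RTOL",
    "EXACT_N_MAX",
]

TIE_RTOL = 1e-7  # relative tolerance for probability ties
EXACT_N_MAX = 200  # grand totals up to this use exact integer arithmetic


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Allele counts for two populations: rows are populations, columns
    are allele present / absent."""

    a: int
    b: int
    c: int
    d: int
    labels: tuple[str, str] = ("group1", "group2")

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return math.inf if self.a * self.d > 0 else math.nan
        return (self.a * self.d) / (self.b * self.c)


@dataclass(frozen=True)
class ExactTestResult:
    p_two_sided: float
    odds_ratio: float
    method: str = "fisher-exact-two-sided-minlike"


def _fisher_exact_int(t: ContingencyTable2x2) -> float:
    """Exact integer-arithmetic path: compare unnormalised hypergeometric
    weights comb(r1, k) * comb(r2, c1 - k) as integers, so ties are exact."""
    r1, r2 = t.a + t.b, t.c + t.d
    c1 = t.a + t.c
    k_lo, k_hi = max(0, c1 - r2), min(r1, c1)
    w_obs = math.comb(r1, t.a) * math.comb(r2, c1 - t.a)
    num = 0
    denom = 0
    for k in range(k_lo, k_hi + 1):
        w = math.comb(r1, k) * math.comb(r2, c1 - k)
        denom += w
        if w <= w_obs:
            num += w
    return num / denom


def _fisher_exact_log(t: ContingencyTable2x2) -> float:
    """Log-gamma path for large counts (log-space hypergeometric sum)."""
    r1, r2 = t.a + t.b, t.c + t.d
    c1, n = t.a + t.c, t.n
    k = np.arange(max(0, c1 - r2), min(r1, c1) + 1)

    def _lchoose(n_, k_):
        return gammaln(n_ + 1) - gammaln(k_ + 1) - gammaln(n_ - k_ + 1)

    logp = _lchoose(r1, k) + _lchoose(r2, c1 - k) - _lchoose(n, c1)
    log_obs = float(logp[k == t.a][0])
    include = logp <= log_obs + math.log1p(TIE_RTOL)
    sel = logp[include]
    m = sel.max()
    return float(min(1.0, math.exp(m) * np.exp(sel - m).sum()))


def fisher_two_sided(t: ContingencyTable2x2) -> ExactTestResult:
    """Two-sided Fisher exact test (minimum-likelihood rule).

    Conditional on both margins, the table's first cell follows a
    hypergeometric distribution; the p-value sums the probabilities of
    all outcomes no more probable than the one observed. Deterministic;
    a zero margin leaves a single admissible table and p = 1.
    """
    p = _fisher_exact_int(t) if t.n <= EXACT_N_MAX else _fisher_exact_log(t)
    return ExactTestResult(p_two_sided=p, odds_ratio=t.odds_ratio())


def compare_frequencies(
    count1: tuple[int, int],
    count2: tuple[int, int],
    labels: tuple[str, str] = ("group1", "group2"),
) -> dict:
    """Build the 2x2 allele table from two (alt, total) count pairs and
    test it; returns the frequencies, the table and the test result."""
    (alt1, total1), (alt2, total2) = count1, count2
    for alt, total in (count1, count2):
        if total <= 0:
            raise ValueError("total allele count must be positive")
        if not 0 <= alt <= total:
            raise ValueError(f"alt count {alt} outside [0, {total}]")
    table = ContingencyTable2x2(alt1, total1 - alt1, alt2, total2 - alt2, labels)
    result = fisher_two_sided(table)
    return {
        "freq_1": alt1 / total1,
        "freq_2": alt2 / total2,
        "table": table,
        "result": result,
    }
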