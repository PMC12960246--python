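"""Contingency-table inference: Pearson chi-squared and exact Fisher tests.

The exact tests enumerate the margin-constrained lattice of tables with
integer (rational) arithmetic, so exact p-values are sums of exact
hypergeometric probabilities rather than floating-point approximations.
The two-sided rule is the probability-mass rule: sum the probabilities of
all tables whose probability does not exceed that of the observed table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _sps


@dataclass
class ContingencyTable:
    """An r x c table of non-negative integer counts."""

    counts: np.ndarray
    row_labels: Optional[Sequence[str]] = None
    col_labels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        a = np.asarray(self.counts)
        if a.ndim != 2 or a.shape[0] < 2 or a.shape[1] < 2:
            raise ValueError("table must be at least 2x2")
        if np.any(a < 0) or not np.allclose(a, np.round(a)):
            raise ValueError("table entries must be non-negative integers")
        if a.sum() <= 0:
            raise ValueError("table total must be positive")
        self.counts = a.astype(np.int64)


@dataclass
class TestResult:
    """Outcome of a hypothesis test.

    ``method`` distinguishes exact (enumeration-based) from asymptotic
    p-values; ``extra`` carries test-specific quantities such as group
    medians or expected counts.
    """

    statistic: float
    p_value: float
    method: str
    df: Optional[float] = None
    effect: Optional[float] = None
    alternative: str = "two-sided"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p-value out of range: {self.p_value}")
        self.p_value = min(float(self.p_value), 1.0)


def _as_table(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.counts
    return ContingencyTable(np.asarray(table)).counts


def pearson_chi2(table) -> TestResult:
    """Pearson chi-squared test of independence, no continuity correction.

    Expected counts come from the product of the margins; the p-value is
    the upper tail of the chi-squared distribution with (r-1)(c-1) df.
    """
    obs = _as_table(table)
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero row or column margin")
    n = obs.sum()
    expected = np.outer(row, col) / n
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(_sps.chi2.sf(chi2, df))
    return TestResult(
        statistic=chi2, p_value=p, method="asymptotic", df=df,
        extra={"expected": expected},
    )


def _table_prob_denominator(cells: Sequence[int]) -> int:
    """Product of cell factorials; the table probability is inversely
    proportional to it once margins are fixed."""
    out = 1
    for c in cells:
        out *= math.factorial(int(c))
    return out


def _enumerate_tables(row_margins, col_margins):
    """Yield all tables (flat tuples, row-major) with the given margins."""
    r, c = len(row_margins), len(col_margins)

    def rec(row_idx, col_rem, acc):
        if row_idx == r - 1:
            last = tuple(col_rem)
            if all(v >= 0 for v in last) and sum(last) == row_margins[-1]:
                yield acc + last
            return
        target = row_margins[row_idx]

        def fill(col_idx, remaining, row_acc):
            if col_idx == c - 1:
                if 0 <= remaining <= col_rem[col_idx]:
                    yield row_acc + (remaining,)
                return
            hi = min(remaining, col_rem[col_idx])
            for v in range(hi + 1):
                yield from fill(col_idx + 1, remaining - v, row_acc + (v,))

        for row_vals in fill(0, target, ()):
            new_rem = tuple(cr - v for cr, v in zip(col_rem, row_vals))
            yield from rec(row_idx + 1, new_rem, acc + row_vals)

    yield from rec(0, tuple(col_margins), ())


def _fisher_exact(obs: np.ndarray) -> Fraction:
    """Two-sided Fisher probability-mass p-value as an exact rational."""
    row = [int(v) for v in obs.sum(axis=1)]
    col = [int(v) for v in obs.sum(axis=0)]
    n = int(obs.sum())
    # P(table) = prod(row!) * prod(col!) / (n! * prod(cell!))
    const_num = 1
    for m in row + col:
        const_num *= math.factorial(m)
    const_den = math.factorial(n)
    obs_den = _table_prob_denominator(obs.ravel().tolist())
    total = Fraction(0)
    for cells in _enumerate_tables(row, col):
        den = _table_prob_denominator(cells)
        # prob <= obs prob  <=>  den >= obs_den (probs share the constant)
        if den >= obs_den:
            total += Fraction(const_num, const_den * den)
    return total


def fisher_exact_2x2(table) -> TestResult:
    """Exact two-sided Fisher test for a 2x2 table.

    Enumerates the hypergeometric distribution over the one free cell with
    rational arithmetic. The reported effect is the sample odds ratio
    (ad/bc), infinite when b*c = 0.
    """
    obs = _as_table(table)
    if obs.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 requires a 2x2 table")
    p = _fisher_exact(obs)
    a, b = obs[0]
    c, d = obs[1]
    if b * c == 0:
        orat = math.inf if a * d > 0 else math.nan
    else:
        orat = float(a * d) / float(b * c)
    return TestResult(
        statistic=float(obs[0, 0]), p_value=float(p), method="exact",
        effect=orat, extra={"p_exact": p},
    )


def fisher_exact_rxc(table, max_total: int = 200) -> TestResult:
    """Freeman-Halton exact test for an r x c table.

    Sums multivariate-hypergeometric probabilities (margins fixed) of every
    table at least as extreme (no more probable) than the observed one, by
    exhaustive enumeration of the margin-constrained lattice.
    """
    obs = _as_table(table)
    n = int(obs.sum())
    if n > max_total:
        raise ValueError(
            f"table total {n} exceeds enumeration guard {max_total}; "
            "use a Monte-Carlo variant for large tables"
        )
    p = _fisher_exact(obs)
    return TestResult(
        statistic=float("nan"), p_value=float(p), method="exact",
        extra={"p_exact": p},
    )
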