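"""Rank-based comparison and correlation.

The Mann-Whitney U test uses midranks for ties, an exact enumerated null
distribution for small untied samples, and a tie-corrected normal
approximation with continuity correction otherwise.
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache

import numpy as np
from scipy import stats as _sps

from ._contingency import TestResult

EXACT_MAX_N = 12


@lru_cache(maxsize=None)
def _u_counts(n1: int, n2: int) -> tuple:
    """Counts of arrangements giving each U value for sample sizes n1, n2.

    Classical recurrence: f(n1, n2, u) = f(n1-1, n2, u-n2) + f(n1, n2-1, u).
    Returns a tuple of length n1*n2 + 1 summing to C(n1+n2, n1).
    """
    if n1 == 0 or n2 == 0:
        return (1,)
    a = _u_counts(n1 - 1, n2)
    b = _u_counts(n1, n2 - 1)
    out = [0] * (n1 * n2 + 1)
    for u, cnt in enumerate(a):
        out[u + n2] += cnt
    for u, cnt in enumerate(b):
        out[u] += cnt
    return tuple(out)


def _exact_p(u: float, n1: int, n2: int, alternative: str) -> Fraction:
    counts = _u_counts(n1, n2)
    total = sum(counts)
    ui = int(round(u))
    lower = sum(counts[: ui + 1])          # P(U <= u)
    upper = sum(counts[ui:])               # P(U >= u)
    if alternative == "less":
        return Fraction(lower, total)
    if alternative == "greater":
        return Fraction(upper, total)
    p = 2 * min(Fraction(lower, total), Fraction(upper, total))
    return min(p, Fraction(1))


def mann_whitney(x, y, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon-Mann-Whitney U test.

    U counts, for each pair (x_i, y_j), 1 when x_i > y_j and 1/2 on ties
    (equivalently the midrank formulation). ``alternative='greater'`` tests
    the x distribution stochastically larger than y. Exact enumeration is
    used when both samples have at most 12 observations and no ties are
    present; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = _sps.rankdata(combined)  # midranks
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0     # number of (x > y) pairs, ties as 1/2

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = np.any(tie_counts > 1)

    if not has_ties and n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        p = float(_exact_p(u, n1, n2, alternative))
        method = "exact"
    else:
        n = n1 + n2
        mu = n1 * n2 / 2.0
        tie_term = (tie_counts ** 3 - tie_counts).sum()
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            sd = np.sqrt(var)
            if alternative == "two-sided":
                z = (abs(u - mu) - 0.5) / sd
                p = float(2 * _sps.norm.sf(max(z, 0.0)))
            elif alternative == "greater":
                z = (u - mu - 0.5) / sd
                p = float(_sps.norm.sf(z))
            else:
                z = (u - mu + 0.5) / sd
                p = float(_sps.norm.cdf(z))
        p = min(p, 1.0)
        method = "asymptotic"
    return TestResult(
        statistic=float(u), p_value=p, method=method,
        alternative=alternative,
        extra={"median_x": float(np.median(x)), "median_y": float(np.median(y)),
               "n_x": n1, "n_y": n2},
    )


def pearson_correlation(x, y) -> TestResult:
    """Pearson product-moment correlation with a t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input vector")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float((xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum()))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
        t = np.inf * np.sign(r)
    else:
        t = r * np.sqrt((n - 2) / (1 - r * r))
        p = float(2 * _sps.t.sf(abs(t), n - 2))
    return TestResult(
        statistic=float(t), p_value=p, method="asymptotic", df=n - 2,
        effect=r, extra={"r": r, "n": n},
    )
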