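"""Survival analysis: Kaplan-Meier, log-rank and Cox proportional hazards.

The Cox model maximizes the Efron-tie partial likelihood by Newton-Raphson
(Breslow available by flag) and supports delayed entry, where subjects join
the risk set only after their entry (recruitment) time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _sps

from ._contingency import TestResult


# ---------------------------------------------------------------- Kaplan-Meier

@dataclass
class KaplanMeierResult:
    """Product-limit estimate with Greenwood variance and log-log CI bands."""

    event_times: np.ndarray      # distinct event times
    survival: np.ndarray         # S(t) at each event time
    variance: np.ndarray         # Greenwood variance of S(t)
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events, alpha: float = 0.05) -> KaplanMeierResult:
    """Kaplan-Meier estimator.

    ``events`` is 1 for an observed event, 0 for right censoring. Confidence
    bands use the log(-log S) transformation, which keeps them inside [0,1].
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if not np.all(np.isin(d, [0, 1])):
        raise ValueError("events must be binary 0/1")
    order = np.argsort(t, kind="stable")
    t, d = t[order], d[order]
    uniq = np.unique(t[d == 1])
    n = t.size
    surv, var_cum, at_risk, n_ev = [], [], [], []
    s = 1.0
    gw = 0.0  # running Greenwood sum d/(n(n-d))
    for u in uniq:
        nr = int(np.sum(t >= u))
        de = int(np.sum((t == u) & (d == 1)))
        s *= (nr - de) / nr
        if nr - de > 0:
            gw += de / (nr * (nr - de))
        else:
            gw = np.inf
        surv.append(s)
        var_cum.append((s ** 2) * gw if np.isfinite(gw) else 0.0)
        at_risk.append(nr)
        n_ev.append(de)
    surv = np.asarray(surv)
    var = np.asarray(var_cum)
    z = _sps.norm.ppf(1 - alpha / 2)
    lo = np.empty_like(surv)
    hi = np.empty_like(surv)
    for i, (s_i, v_i) in enumerate(zip(surv, var)):
        if 0.0 < s_i < 1.0 and v_i > 0:
            se_loglog = np.sqrt(v_i) / (s_i * abs(np.log(s_i)))
            theta = np.log(-np.log(s_i))
            lo[i] = np.exp(-np.exp(theta + z * se_loglog))
            hi[i] = np.exp(-np.exp(theta - z * se_loglog))
        else:
            lo[i] = hi[i] = s_i
    return KaplanMeierResult(
        event_times=uniq, survival=surv, variance=var,
        ci_lower=lo, ci_upper=hi,
        n_at_risk=np.asarray(at_risk), n_events=np.asarray(n_ev),
    )


# -------------------------------------------------------------------- log-rank

@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray

    def as_test_result(self) -> TestResult:
        return TestResult(statistic=self.statistic, p_value=self.p_value,
                          method="asymptotic", df=self.df)


def logrank_test(times, events, groups) -> LogRankResult:
    """Multi-group log-rank test.

    Sums observed-minus-expected events over event times with the
    multivariate-hypergeometric variance; the statistic is a chi-squared
    with (g-1) df. Groups fully censored before the first event simply
    contribute risk-set counts.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    labels = np.unique(g)
    k = labels.size
    if k < 2:
        raise ValueError("need at least two groups")
    gidx = np.searchsorted(labels, g)
    event_times = np.unique(t[d == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for u in event_times:
        at_risk = t >= u
        n = at_risk.sum()
        dd = int(np.sum((t == u) & (d == 1)))
        ng = np.bincount(gidx[at_risk], minlength=k).astype(float)
        og = np.bincount(gidx[(t == u) & (d == 1)], minlength=k).astype(float)
        O += og
        E += dd * ng / n
        if n > 1:
            frac = ng / n
            vmat = (np.diag(frac) - np.outer(frac, frac)) * dd * (n - dd) / (n - 1)
            V += vmat
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        stat = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(Vsub) @ diff)
    df = k - 1
    p = float(_sps.chi2.sf(stat, df))
    return LogRankResult(statistic=stat, df=df, p_value=p, observed=O, expected=E)


# ------------------------------------------------------------------------- Cox

@dataclass
class CoxPHResults:
    params: np.ndarray
    bse: np.ndarray
    exog_names: list
    converged: bool
    flagged: bool           # monotone likelihood / no events
    n_iter: int
    llf: float
    nobs: int
    n_events: int
    ties: str

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = _sps.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - z * self.bse,
                                self.params + z * self.bse])

    def hr_conf_int(self, alpha: float = 0.05) -> np.ndarray:
        return np.exp(self.conf_int(alpha))

    @property
    def pvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.params / self.bse
        return 2 * _sps.norm.sf(np.abs(z))

    def summary(self) -> str:
        lines = [
            f"Cox proportional hazards ({self.ties} ties)",
            f"  n = {self.nobs}   events = {self.n_events}   "
            f"partial log-likelihood = {self.llf:.4f}",
        ]
        if self.flagged:
            lines.append("  WARNING: monotone likelihood or degenerate fit")
        ci = self.hr_conf_int()
        lines.append(f"  {'term':<20}{'coef':>10}{'se':>10}{'HR':>10}"
                     f"{'[0.025':>10}{'0.975]':>10}{'p':>10}")
        for i, name in enumerate(self.exog_names):
            lines.append(
                f"  {name:<20}{self.params[i]:>10.4f}{self.bse[i]:>10.4f}"
                f"{self.hazard_ratios[i]:>10.4f}{ci[i, 0]:>10.4f}"
                f"{ci[i, 1]:>10.4f}{self.pvalues[i]:>10.4g}"
            )
        return "\n".join(lines)


class CoxPHModel:
    """Cox proportional-hazards regression.

    Parameters
    ----------
    times, events : follow-up time and 0/1 event indicator.
    exog : covariate matrix (no intercept; the baseline hazard absorbs it).
    entry : optional delayed-entry times; subject i is at risk on
        (entry_i, time_i].
    """

    def __init__(self, times, events, exog,
                 exog_names: Optional[Sequence[str]] = None,
                 entry=None):
        t = np.asarray(times, dtype=float)
        d = np.asarray(events, dtype=int)
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        if X.shape[0] != t.size:
            X = X.T
        if X.shape[0] != t.size:
            raise ValueError("times and exog lengths differ")
        if np.any(t < 0):
            raise ValueError("times must be non-negative")
        if entry is not None:
            entry = np.asarray(entry, dtype=float)
            if np.any(entry >= t):
                raise ValueError("entry times must precede event/censor times")
        self.times, self.events, self.exog, self.entry = t, d, X, entry
        self.exog_names = (list(exog_names) if exog_names is not None
                           else [f"x{i}" for i in range(1, X.shape[1] + 1)])

    def _loglik_grad_hess(self, beta, ties="efron"):
        t, d, X = self.times, self.events, self.exog
        entry = self.entry
        p = X.shape[1]
        eta = X @ beta
        w = np.exp(eta - eta.max())  # rescaled; constants cancel in ratios
        logw_shift = eta.max()
        ll = 0.0
        grad = np.zeros(p)
        hess = np.zeros((p, p))
        for u in np.unique(t[d == 1]):
            at_risk = t >= u
            if entry is not None:
                at_risk &= entry < u
            D = (t == u) & (d == 1)
            dd = int(D.sum())
            wR = w[at_risk].sum()
            swR = X[at_risk].T @ w[at_risk]
            qR = (X[at_risk] * w[at_risk, None]).T @ X[at_risk]
            s_x = X[D].sum(axis=0)
            ll += float(eta[D].sum())
            if ties == "efron" and dd > 1:
                wD = w[D].sum()
                swD = X[D].T @ w[D]
                qD = (X[D] * w[D, None]).T @ X[D]
                for l in range(dd):
                    f = l / dd
                    phi = wR - f * wD
                    sphi = swR - f * swD
                    qphi = qR - f * qD
                    ll -= np.log(phi) + logw_shift
                    grad_term = sphi / phi
                    grad -= grad_term
                    hess -= qphi / phi - np.outer(grad_term, grad_term)
            else:  # breslow (or single event)
                ll -= dd * (np.log(wR) + logw_shift)
                grad_term = swR / wR
                grad -= dd * grad_term
                hess -= dd * (qR / wR - np.outer(grad_term, grad_term))
            grad += s_x
        return ll, grad, -hess  # return positive-definite information

    def fit(self, ties: str = "efron", tol: float = 1e-9,
            maxiter: int = 100) -> CoxPHResults:
        if ties not in ("efron", "breslow"):
            raise ValueError("ties must be 'efron' or 'breslow'")
        p = self.exog.shape[1]
        n_events = int(self.events.sum())
        beta = np.zeros(p)
        flagged = n_events == 0
        converged = False
        it = 0
        if not flagged:
            for it in range(1, maxiter + 1):
                ll, grad, info = self._loglik_grad_hess(beta, ties)
                if np.max(np.abs(grad)) < tol:
                    converged = True
                    break
                try:
                    step = np.linalg.solve(info, grad)
                except np.linalg.LinAlgError:
                    step = np.linalg.lstsq(info, grad, rcond=None)[0]
                lam = 1.0
                for _ in range(25):
                    cand = beta + lam * step
                    ll_new = self._loglik_grad_hess(cand, ties)[0]
                    if ll_new >= ll - 1e-12:
                        break
                    lam /= 2
                beta = beta + lam * step
            if np.max(np.abs(beta)) > 20:
                flagged = True
        ll, grad, info = self._loglik_grad_hess(beta, ties)
        try:
            cov = np.linalg.inv(info)
            bse = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        except np.linalg.LinAlgError:
            bse = np.full(p, np.nan)
            flagged = True
        return CoxPHResults(
            params=beta, bse=bse, exog_names=list(self.exog_names),
            converged=converged, flagged=flagged, n_iter=it, llf=ll,
            nobs=self.times.size, n_events=n_events, ties=ties,
        )


def coxph_fit(times, events, X, exog_names=None, entry=None,
              ties: str = "efron", **kw) -> CoxPHResults:
    """Functional wrapper around :class:`CoxPHModel`."""
    return CoxPHModel(times, events, X, exog_names=exog_names,
                      entry=entry).fit(ties=ties, **kw)
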