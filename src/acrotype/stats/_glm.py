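"""Binary logistic regression by iteratively reweighted least squares.

Model/results pair in the statsmodels idiom: ``LogisticModel(y, X).fit()``
returns :class:`LogisticResults` with Wald standard errors from the
observed information, odds ratios with 95% confidence intervals, and a
separation diagnostic (perfect separation is flagged, never silently
iterated to divergence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _sps

_Z975 = 1.959963984540054


@dataclass
class LogisticResults:
    params: np.ndarray
    bse: np.ndarray
    exog_names: list
    converged: bool
    separation: bool
    n_iter: int
    llf: float
    nobs: int

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = _sps.norm.ppf(1 - alpha / 2)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return np.column_stack([lo, hi])

    def or_conf_int(self, alpha: float = 0.05) -> np.ndarray:
        return np.exp(self.conf_int(alpha))

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2 * _sps.norm.sf(np.abs(self.zvalues))

    def summary(self) -> str:
        lines = [
            "Logistic regression (IRLS)",
            f"  n = {self.nobs}   log-likelihood = {self.llf:.4f}   "
            f"iterations = {self.n_iter}   converged = {self.converged}",
        ]
        if self.separation:
            lines.append("  WARNING: (quasi-)separation detected; "
                         "estimates/SEs are unreliable")
        lines.append(f"  {'term':<20}{'coef':>10}{'se':>10}{'OR':>10}"
                     f"{'[0.025':>10}{'0.975]':>10}{'p':>10}")
        ci = self.or_conf_int()
        for i, name in enumerate(self.exog_names):
            lines.append(
                f"  {name:<20}{self.params[i]:>10.4f}{self.bse[i]:>10.4f}"
                f"{self.odds_ratios[i]:>10.4f}{ci[i, 0]:>10.4f}"
                f"{ci[i, 1]:>10.4f}{self.pvalues[i]:>10.4g}"
            )
        return "\n".join(lines)


class LogisticModel:
    """Maximum-likelihood logistic regression for a binary outcome.

    Parameters
    ----------
    endog : array of 0/1 outcomes.
    exog : design matrix (an intercept column is prepended unless
        ``add_intercept=False``).
    """

    def __init__(self, endog, exog, exog_names: Optional[Sequence[str]] = None,
                 add_intercept: bool = True):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        if X.shape[0] != y.size:
            X = X.T
        if X.shape[0] != y.size:
            raise ValueError("endog and exog lengths differ")
        if not np.all(np.isin(y, [0.0, 1.0])):
            raise ValueError("endog must be binary 0/1")
        if add_intercept:
            X = np.column_stack([np.ones(y.size), X])
            names = ["intercept"] + (
                list(exog_names) if exog_names is not None
                else [f"x{i}" for i in range(1, X.shape[1])]
            )
        else:
            names = (list(exog_names) if exog_names is not None
                     else [f"x{i}" for i in range(X.shape[1])])
        # non-intercept columns must vary
        for j in range(1 if add_intercept else 0, X.shape[1]):
            if np.ptp(X[:, j]) == 0:
                raise ValueError(f"column {names[j]!r} is constant")
        if y.size <= X.shape[1]:
            raise ValueError("need more observations than parameters")
        self.endog = y
        self.exog = X
        self.exog_names = names

    @classmethod
    def from_dataframe(cls, data, formula_lhs: str, formula_rhs: Sequence[str]):
        y = data[formula_lhs].to_numpy()
        X = data[list(formula_rhs)].to_numpy()
        return cls(y, X, exog_names=list(formula_rhs))

    def loglike(self, beta: np.ndarray) -> float:
        eta = self.exog @ beta
        return float(np.sum(self.endog * eta - np.logaddexp(0.0, eta)))

    def fit(self, tol: float = 1e-8, maxiter: int = 50) -> LogisticResults:
        X, y = self.exog, self.endog
        beta = np.zeros(X.shape[1])
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            eta = np.clip(X @ beta, -30, 30)
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1 - mu)
            score = X.T @ (y - mu)
            if np.max(np.abs(score)) < tol:
                converged = True
                break
            info = (X * w[:, None]).T @ X
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(info, score, rcond=None)[0]
            # step-halving for stability
            ll0 = self.loglike(beta)
            lam = 1.0
            for _ in range(20):
                cand = beta + lam * step
                if self.loglike(cand) >= ll0 - 1e-12:
                    break
                lam /= 2
            beta = beta + lam * step
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        info = (X * w[:, None]).T @ X
        separation = bool(
            np.all((mu > 1 - 1e-6) == (y == 1)) and np.all(np.abs(eta) > 5)
        ) or bool(np.max(np.abs(beta)) > 25)
        try:
            cov = np.linalg.inv(info)
            bse = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        except np.linalg.LinAlgError:
            bse = np.full(beta.size, np.nan)
            separation = True
        return LogisticResults(
            params=beta, bse=bse, exog_names=list(self.exog_names),
            converged=converged, separation=separation, n_iter=it,
            llf=self.loglike(beta), nobs=y.size,
        )


def logistic_fit(X, y, exog_names=None, add_intercept: bool = True,
                 **fit_kw) -> LogisticResults:
    """Functional wrapper: fit ``y ~ X`` and return the results object."""
    return LogisticModel(y, X, exog_names=exog_names,
                         add_intercept=add_intercept).fit(**fit_kw)
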