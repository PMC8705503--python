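"""Right-censored Weibull proportional-hazards model for hitting times.

The hazard is a Weibull baseline scaled by a log-linear covariate term,

    h(t, theta) = (alpha / t) * (t / beta)**alpha * exp(gamma . theta),

with survival R(t, theta) = exp(-(t/beta)**alpha * exp(gamma . theta))
and density f = h * R.  The likelihood multiplies the density over
observed hitting times and the survival over right-censored ones.  The
MLE is computed by quasi-Newton optimization over the unconstrained
parameters (log alpha, log beta, gamma); Wald standard errors come from
the observed information with a delta-method transform back to the
(alpha, beta) scale.

Closed-form moments of the hitting time at covariate vector theta:

    E tau   = beta * exp(-gamma.theta / alpha) * Gamma(1 + 1/alpha)
    Var tau = beta**2 * exp(-2 gamma.theta / alpha)
              * (Gamma(1 + 2/alpha) - Gamma(1 + 1/alpha)**2)

so negative coefficients make both moments increase exponentially in
theta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats


def log_likelihood(times, events, X, alpha: float, beta: float,
                   gamma) -> float:
    """Weibull-Cox log likelihood: sum of log densities over events plus
    log survivals over censored rows."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != t.size:
        X = X.T
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    lin = X @ gamma
    log_h = np.log(alpha) - np.log(t) + alpha * (np.log(t) - np.log(beta)) + lin
    cum_h = (t / beta) ** alpha * np.exp(lin)
    return float(np.sum(log_h[e]) - np.sum(cum_h))


class WeibullCoxPH:
    """Weibull proportional-hazards model for right-censored data.

    Parameters
    ----------
    times : array-like
        Observed times (hitting times or censor times), strictly > 0.
    events : array-like of bool
        True where the time is an observed hit, False where censored.
    exog : array-like or DataFrame
        Covariate matrix theta (one row per observation).
    standardize : bool
        If True, z-score the covariates before fitting (coefficients are
        reported on the standardized scale).
    """

    def __init__(self, times, events, exog, exog_names=None,
                 standardize: bool = False):
        self.times = np.asarray(times, dtype=float)
        self.events = np.asarray(events, dtype=bool)
        if isinstance(exog, pd.DataFrame):
            exog_names = list(exog.columns)
            exog = exog.to_numpy()
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        if X.shape[0] != self.times.size:
            X = X.T
        if np.any(self.times <= 0):
            raise ValueError("times must be positive")
        if not self.events.any():
            raise ValueError("cannot fit with no observed events")
        self.exog_names = exog_names or [f"x{i}" for i in range(X.shape[1])]
        self._mu = X.mean(axis=0)
        self._sd = X.std(axis=0, ddof=0)
        self.standardize = standardize
        self.exog = (X - self._mu) / np.where(self._sd > 0, self._sd, 1.0) \
            if standardize else X

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, duration_col: str = "tau",
                       censor_col: str = "censored",
                       covariates: list[str] | None = None, **kw
                       ) -> "WeibullCoxPH":
        """Build from a sweep table: censored rows use their censor time
        as the observation time."""
        covariates = covariates or [c for c in df.columns
                                    if c not in (duration_col, censor_col)]
        cens = df[censor_col].astype(bool).to_numpy()
        t = np.where(cens, df.get("censor_time", df[duration_col]),
                     df[duration_col]).astype(float)
        return cls(t, ~cens, df[covariates], exog_names=covariates, **kw)

    def loglike(self, params: np.ndarray) -> float:
        """Log likelihood at transformed params (log a, log b, gamma)."""
        a, b = np.exp(params[0]), np.exp(params[1])
        return log_likelihood(self.times, self.events, self.exog, a, b,
                              params[2:])

    def fit(self, maxiter: int = 500) -> "WeibullCoxResults":
        p = self.exog.shape[1]
        # exponential-fit moment start for the scale
        start = np.r_[0.0, np.log(self.times.sum() / self.events.sum()),
                      np.zeros(p)]
        res = optimize.minimize(lambda th: -self.loglike(th), start,
                                method="BFGS",
                                options={"maxiter": maxiter, "gtol": 1e-8})
        # polish: finite-difference BFGS can stall on precision loss at
        # the optimum; a derivative-free refinement settles convergence
        polish = optimize.minimize(
            lambda th: -self.loglike(th), res.x, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        if polish.fun <= res.fun:
            res = polish
        hess = _numerical_hessian(lambda th: -self.loglike(th), res.x)
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov = np.full((2 + p, 2 + p), np.nan)
        return WeibullCoxResults(self, res.x, cov, -res.fun,
                                 converged=bool(res.success))


def _numerical_hessian(fun, x, eps: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian."""
    n = x.size
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej)
                - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * eps * eps)
    return H


@dataclass
class WeibullCoxResults:
    """MLE results: shape alpha, scale beta, coefficients gamma, Wald
    inference, and closed-form predictions."""

    model: WeibullCoxPH
    params_internal: np.ndarray      # (log alpha, log beta, gamma)
    cov_internal: np.ndarray
    llf: float
    converged: bool = True

    @property
    def alpha(self) -> float:
        return float(np.exp(self.params_internal[0]))

    @property
    def beta(self) -> float:
        return float(np.exp(self.params_internal[1]))

    @property
    def gamma(self) -> np.ndarray:
        return self.params_internal[2:]

    @property
    def bse(self) -> pd.Series:
        """Standard errors: delta method for alpha, beta; direct for
        gamma."""
        se_int = np.sqrt(np.diag(self.cov_internal))
        se = np.r_[self.alpha * se_int[0], self.beta * se_int[1], se_int[2:]]
        return pd.Series(se, index=self._names)

    @property
    def _names(self) -> list[str]:
        return ["alpha", "beta"] + [f"gamma_{n}" for n in
                                    self.model.exog_names]

    @property
    def params(self) -> pd.Series:
        return pd.Series(np.r_[self.alpha, self.beta, self.gamma],
                         index=self._names)

    @property
    def pvalues(self) -> pd.Series:
        """Wald p-values.  For alpha and beta the null is the
        exponential baseline (alpha=1) resp. beta=1; for gamma, zero."""
        se_int = np.sqrt(np.diag(self.cov_internal))
        z = np.r_[self.params_internal[0] / se_int[0],
                  self.params_internal[1] / se_int[1],
                  self.gamma / se_int[2:]]
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self._names)

    def linear_predictor(self, theta) -> float:
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        if self.model.standardize:
            theta = (theta - self.model._mu) / np.where(
                self.model._sd > 0, self.model._sd, 1.0)
        return float(self.gamma @ theta)

    def mean(self, theta=None) -> float:
        """E tau(theta) in closed form (theta=None: baseline, gamma.theta=0)."""
        lp = 0.0 if theta is None else self.linear_predictor(theta)
        a = self.alpha
        return self.beta * np.exp(-lp / a) * special.gamma(1 + 1 / a)

    def variance(self, theta=None) -> float:
        lp = 0.0 if theta is None else self.linear_predictor(theta)
        a = self.alpha
        g1 = special.gamma(1 + 1 / a)
        g2 = special.gamma(1 + 2 / a)
        return self.beta**2 * np.exp(-2 * lp / a) * (g2 - g1**2)

    def cumulative_hazard(self, t, theta=None) -> np.ndarray:
        lp = 0.0 if theta is None else self.linear_predictor(theta)
        return (np.asarray(t, dtype=float) / self.beta) ** self.alpha \
            * np.exp(lp)

    def survival_function(self, t, theta=None) -> np.ndarray:
        return np.exp(-self.cumulative_hazard(t, theta))

    def hazard(self, t, theta=None) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        lp = 0.0 if theta is None else self.linear_predictor(theta)
        return (self.alpha / t) * (t / self.beta) ** self.alpha * np.exp(lp)

    def survival_curves(self, t_grid, theta_grid) -> pd.DataFrame:
        """Tabulated R(t, theta) and H(t, theta) over a grid for plotting."""
        rows = []
        for i, th in enumerate(theta_grid):
            H = self.cumulative_hazard(t_grid, th)
            for t, h in zip(np.asarray(t_grid, dtype=float), H):
                rows.append({"theta_index": i, "t": t,
                             "survival": float(np.exp(-h)),
                             "cumulative_hazard": float(h)})
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame({"estimate": self.params, "se": self.bse,
                           "p": self.pvalues})
        df.attrs["llf"] = self.llf
        df.attrs["converged"] = self.converged
        df.attrs["n_obs"] = self.model.times.size
        df.attrs["n_events"] = int(self.model.events.sum())
        return df

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha, "beta": self.beta,
            "gamma": {n: float(g) for n, g in
                      zip(self.model.exog_names, self.gamma)},
            "se": {k: float(v) for k, v in self.bse.items()},
            "pvalues": {k: float(v) for k, v in self.pvalues.items()},
            "llf": self.llf, "converged": self.converged,
        }
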