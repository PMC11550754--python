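"""Two-sided censored (Tobit) regression for bounded efficiency scores.

DEA efficiency scores live in (0, 1] with a point mass at 1, so ordinary
least squares on them is misspecified.  The Tobit model posits a latent
normal outcome y* = X b + e, e ~ N(0, s^2), observed as

    y = lower   if y* <= lower
    y = y*      if lower < y* < upper
    y = upper   if y* >= upper

and is fit by maximum likelihood: interior points contribute the normal
density, boundary points the corresponding tail probability.  Standard
errors come from the observed information (numerical Hessian at the MLE)
and p-values from the normal approximation to the Wald statistic.
Coefficients may be displayed scaled by 10^3 since effects on a 0-1 score
are small numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools import numdiff

__all__ = ["TobitFit", "fit_tobit", "univariate_screen", "vif"]

_BOUND_TOL = 1e-10


@dataclass
class TobitFit:
    params: np.ndarray  # [beta..., sigma]
    names: list[str]
    se: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    n_lower: int
    n_interior: int
    n_upper: int
    lower: float
    upper: float
    converged: bool = True

    @property
    def beta(self) -> np.ndarray:
        return self.params[:-1]

    @property
    def sigma(self) -> float:
        return float(self.params[-1])

    def summary_frame(self, scale: float = 1.0) -> pd.DataFrame:
        """Coefficient table; pass scale=1e3 for the conventional x10^3 display."""
        return pd.DataFrame(
            {
                "coefficient": self.beta * scale,
                "se": self.se[:-1] * scale,
                "p_value": self.p_values[:-1],
            },
            index=self.names,
        )


def _neg_loglik(theta, y, X, lower, upper, at_lo, at_hi, interior):
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = np.exp(log_sigma)
    mu = X @ beta
    ll = 0.0
    if interior.any():
        z = (y[interior] - mu[interior]) / sigma
        ll += np.sum(stats.norm.logpdf(z)) - interior.sum() * log_sigma
    if at_lo.any():
        ll += np.sum(stats.norm.logcdf((lower - mu[at_lo]) / sigma))
    if at_hi.any():
        ll += np.sum(stats.norm.logsf((upper - mu[at_hi]) / sigma))
    return -ll


def fit_tobit(
    y,
    X,
    lower: float = 0.0,
    upper: float = 1.0,
    names: list[str] | None = None,
    add_intercept: bool = True,
    max_iter: int = 500,
) -> TobitFit:
    """Maximum-likelihood Tobit fit of y on X with censoring at [lower, upper].

    X is a (n, p) design without intercept (one is appended unless
    ``add_intercept=False``).  Optimization runs in (beta, log sigma) from
    an OLS start; the observed information matrix at the optimum gives the
    standard errors for (beta, sigma) via the delta method on log sigma.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("y and X must have the same number of rows")
    if np.any(y < lower - _BOUND_TOL) or np.any(y > upper + _BOUND_TOL):
        raise ValueError("y outside the censoring bounds")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["intercept"] + list(names)
    n, p = X.shape
    if n <= p + 2:
        raise ValueError("too few observations for the number of covariates")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")

    at_lo = y <= lower + _BOUND_TOL
    at_hi = y >= upper - _BOUND_TOL
    interior = ~(at_lo | at_hi)
    if not interior.any():
        raise ValueError(
            "all observations censored; the Tobit likelihood is degenerate"
        )

    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    sigma0 = max(float(resid.std(ddof=p)), 1e-6)
    theta0 = np.append(beta0, np.log(sigma0))
    args = (y, X, lower, upper, at_lo, at_hi, interior)

    res = optimize.minimize(
        _neg_loglik,
        theta0,
        args=args,
        method="BFGS",
        options={"maxiter": max_iter, "gtol": 1e-8},
    )
    if not res.success:
        # polish with Nelder-Mead before giving up; BFGS can stall on the
        # flat log-sigma direction when censoring is heavy
        res = optimize.minimize(
            _neg_loglik, res.x, args=args, method="Nelder-Mead",
            options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-10},
        )
        if not res.success:
            raise RuntimeError(f"Tobit MLE did not converge: {res.message}")

    theta = res.x
    hess = numdiff.approx_hess(theta, _neg_loglik, args=args)
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    sigma = float(np.exp(theta[-1]))
    params = np.append(theta[:-1], sigma)
    se = np.append(se[:-1], se[-1] * sigma)  # delta method for sigma
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = params / se
    p_values = 2 * stats.norm.sf(np.abs(zstat))
    return TobitFit(
        params=params,
        names=list(names),
        se=se,
        p_values=p_values,
        log_likelihood=-float(res.fun),
        n_lower=int(at_lo.sum()),
        n_interior=int(interior.sum()),
        n_upper=int(at_hi.sum()),
        lower=lower,
        upper=upper,
    )


def univariate_screen(
    y, covariates: pd.DataFrame, lower: float = 0.0, upper: float = 1.0
) -> dict[str, TobitFit]:
    """One single-covariate Tobit fit per column of ``covariates``."""
    fits = {}
    for name in covariates.columns:
        fits[name] = fit_tobit(
            y, covariates[[name]].to_numpy(), lower=lower, upper=upper, names=[name]
        )
    return fits


def univariate_table(fits: dict[str, TobitFit], scale: float = 1e3) -> pd.DataFrame:
    rows = {}
    for name, fit in fits.items():
        frame = fit.summary_frame(scale=scale)
        rows[name] = frame.loc[name]
    return pd.DataFrame(rows).T


def vif(X: pd.DataFrame | np.ndarray) -> pd.Series:
    """Variance inflation factor per covariate: 1 / (1 - R^2_k).

    R^2_k comes from OLS of covariate k (with intercept) on the others.
    Exactly collinear designs yield infinity.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        M = X.to_numpy(dtype=float)
    else:
        M = np.atleast_2d(np.asarray(X, dtype=float))
        names = [f"x{j}" for j in range(M.shape[1])]
    n, p = M.shape
    if p < 2:
        raise ValueError("VIF needs at least 2 covariates")
    out = {}
    for k in range(p):
        yk = M[:, k]
        Xk = np.column_stack([np.ones(n), np.delete(M, k, axis=1)])
        coef, *_ = np.linalg.lstsq(Xk, yk, rcond=None)
        resid = yk - Xk @ coef
        ss_tot = float(np.sum((yk - yk.mean()) ** 2))
        if ss_tot == 0:
            raise ValueError(f"covariate {names[k]!r} is constant")
        r2 = 1.0 - float(resid @ resid) / ss_tot
        out[names[k]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)
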