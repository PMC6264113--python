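"""Gaussian linear mixed model with a single scalar random intercept.

Profiled (RE)ML over the variance ratio lambda = tau^2 / sigma^2: for fixed
lambda the GLS fixed effects and the residual variance have closed forms via
the Woodbury identity (each group's marginal covariance is
sigma^2 (I + lambda 11')), so fitting reduces to a bounded one-dimensional
search. Satterthwaite denominator degrees of freedom for linear contrasts are
computed by the delta method over (sigma^2, tau^2) with a numeric Hessian of
the REML criterion — the approach popularized by lmerTest.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from ..errors import InvalidArgumentError
from .base import ModelFit, approx_hessian

__all__ = ["fit_lmm", "fit_gaussian_lmm_pct", "satterthwaite_df"]

_LAM_TINY = 1e-10


class _LMMData:
    """Precomputed sufficient statistics for the profiled likelihood."""

    def __init__(self, y, X, groups):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        codes, uniq = pd.factorize(np.asarray(groups))
        self.y, self.X, self.codes = y, X, codes
        self.n, self.p = X.shape
        self.g = len(uniq)
        self.n_g = np.bincount(codes, minlength=self.g).astype(float)
        self.sX = np.vstack([
            np.bincount(codes, weights=X[:, j], minlength=self.g)
            for j in range(self.p)
        ]).T                                             # (g, p) group sums
        self.sy = np.bincount(codes, weights=y, minlength=self.g)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def gls(self, lam: float):
        """GLS beta, the V-quadratic form of the residual and log|V~|."""
        c = lam / (1.0 + lam * self.n_g)                 # (g,)
        XtViX = self.XtX - (self.sX * c[:, None]).T @ self.sX
        XtViy = self.Xty - self.sX.T @ (c * self.sy)
        beta = np.linalg.solve(XtViX, XtViy)
        r = self.y - self.X @ beta
        sr = self.sy - self.sX @ beta
        quad = max(float(r @ r - np.sum(c * sr ** 2)), 0.0)
        logdetV = float(np.sum(np.log1p(lam * self.n_g)))
        return beta, XtViX, quad, logdetV

    def profiled_loglik(self, lam: float, reml: bool) -> float:
        beta, XtViX, quad, logdetV = self.gls(lam)
        n, p = self.n, self.p
        if reml:
            s2 = max(quad / (n - p), 1e-300)
            sign, logdetX = np.linalg.slogdet(XtViX)
            return -0.5 * ((n - p) * (np.log(2 * np.pi) + 1.0)
                           + (n - p) * np.log(s2) + logdetV + logdetX)
        s2 = max(quad / n, 1e-300)
        return -0.5 * (n * (np.log(2 * np.pi) + 1.0) + n * np.log(s2) + logdetV)

    def loglik_theta(self, sigma2: float, tau2: float, reml: bool = True) -> float:
        """(RE)ML log-likelihood at explicit variance components (unprofiled)."""
        lam = max(tau2, 0.0) / sigma2
        beta, XtViX, quad, logdetV = self.gls(lam)
        n, p = self.n, self.p
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdetV + quad / sigma2)
        if reml:
            sign, logdetX = np.linalg.slogdet(XtViX / sigma2)
            ll -= 0.5 * (logdetX - p * np.log(2 * np.pi))
        return ll


def fit_lmm(y, X: pd.DataFrame, groups, reml: bool = True) -> ModelFit:
    """Fit the random-intercept Gaussian mixed model.

    A variance ratio estimated at (or pushed to) zero is reported as a
    boundary (singular) fit with a warning, not an error: ``re_sd = 0`` and
    the model degenerates to OLS.
    """
    names = list(X.columns)
    data = _LMMData(y, X, groups)
    if data.n <= data.p:
        raise InvalidArgumentError("more parameters than observations")

    def neg(loglam: float) -> float:
        return -data.profiled_loglik(np.exp(loglam), reml)

    res = minimize_scalar(neg, bounds=(-12.0, 8.0), method="bounded",
                          options={"xatol": 1e-8})
    lam = float(np.exp(res.x))
    if -neg(np.log(_LAM_TINY)) >= -res.fun:          # boundary beats interior
        lam = _LAM_TINY
    beta, XtViX, quad, _ = data.gls(lam)
    dof = data.n - data.p if reml else data.n
    sigma2 = quad / dof
    tau2 = lam * sigma2
    boundary = lam <= _LAM_TINY * 10
    if boundary:
        tau2 = 0.0
        warnings.warn("random-intercept variance estimated at the boundary (0); "
                      "fit is singular", stacklevel=2)
    cov = sigma2 * np.linalg.inv(XtViX)
    cov_diag = np.maximum(np.diag(cov), 0.0)
    ll = data.profiled_loglik(lam, reml)
    fit = ModelFit(
        names=names, params=beta, se=np.sqrt(cov_diag), cov_params=cov,
        family="gaussian", link="identity",
        re_sd=float(np.sqrt(tau2)), dispersion=float(np.sqrt(sigma2)),
        loglik=float(ll), n=data.n, k=data.p + 2,
        method="REML" if reml else "ML",
    )
    fit.state.update({"data": data, "lam": lam, "sigma2": sigma2, "tau2": tau2,
                      "reml": reml, "columns": names, "boundary": boundary})
    return fit


def satterthwaite_df(fit: ModelFit, ell: np.ndarray) -> float:
    """Satterthwaite denominator df for the contrast ``ell' beta``.

    ``df = 2 f^2 / (g' A g)`` with ``f = ell' C(theta) ell``, ``g`` its
    numeric gradient over theta = (sigma^2, tau^2) and ``A`` the inverse
    observed information of the REML criterion. At a boundary (tau^2 = 0) fit
    the residual df ``n - p`` is returned.
    """
    data: _LMMData = fit.state["data"]
    sigma2, tau2 = fit.state["sigma2"], fit.state["tau2"]
    resid_df = float(data.n - data.p)
    if fit.state.get("boundary"):
        return resid_df
    ell = np.asarray(ell, dtype=float)

    def f(theta):
        s2, t2 = theta
        _, XtViX, _, _ = data.gls(max(t2, 0.0) / s2)
        C = s2 * np.linalg.inv(XtViX)
        return float(ell @ C @ ell)

    theta = np.array([sigma2, tau2])
    h = 1e-5 * np.maximum(np.abs(theta), 1e-8)
    grad = np.array([
        (f(theta + dh) - f(theta - dh)) / (2 * hi)
        for hi, dh in zip(h, np.diag(h))
    ])
    H = approx_hessian(lambda th: data.loglik_theta(th[0], th[1], fit.state["reml"]),
                       theta, rel_step=1e-4)
    try:
        A = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return resid_df
    denom = float(grad @ A @ grad)
    if not np.isfinite(denom) or denom <= 0:
        return resid_df
    df = 2.0 * f(theta) ** 2 / denom
    if not np.isfinite(df):
        return resid_df
    return float(np.clip(df, 1.0, resid_df))


def fit_gaussian_lmm_pct(table: pd.DataFrame,
                         covariates: tuple[str, ...] = ("mep_pre", "t_t")) -> ModelFit:
    """REML fit of the percent-change model:
    MEP% ~ Session x Time + covariates + (1 | Subject:Session)."""
    from .design import interaction_design, validate_trial_table

    validate_trial_table(table, outcome="mep_pct")
    X = interaction_design(table, covariates=covariates)
    groups = table["subject"].astype(str) + ":" + table["session"].astype(str)
    fit = fit_lmm(table["mep_pct"].to_numpy(dtype=float), X, groups.to_numpy(), reml=True)
    fit.state["cov_means"] = {c: float(table[c].mean()) for c in covariates}
    fit.state["cov_ranges"] = {
        c: (float(table[c].min()), float(table[c].max())) for c in covariates}
    fit.state["response"] = "mep_pct"
    return fit
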