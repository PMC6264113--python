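"""Marginal cell effects and Tukey-adjusted pairwise contrasts.

Effects are predicted (session, time) cell means on the response scale with
continuous covariates held at their sample means (delta-method standard
errors); for the log-link Gamma model contrasts are formed on the log scale
and reported as response-scale ratios.

The family-wise adjustment is the equicoordinate tail of the contrast
estimates' joint normal/t distribution — what modern marginal-means software
computes — rather than the classical equal-n studentized range, which does
not apply to mixed-model contrasts. Contrast families are usually rank
deficient (all pairwise differences of a few cells), so the tail probability
is evaluated by seeded scrambled-Sobol quasi-Monte Carlo over the underlying
full-rank Gaussian, with a chi-distributed denominator when a finite df is
requested.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import qmc

from ..errors import InvalidArgumentError
from ..types import SESSIONS, TIMES
from .base import ModelFit
from .design import cell_row
from .lmm import satterthwaite_df

__all__ = ["marginal_effects", "tukey_contrasts", "tukey_adjust", "max_abs_stat_samples"]


def _at_values(fit: ModelFit, at: dict | None) -> dict:
    means = dict(fit.state.get("cov_means", {}))
    if at:
        ranges = fit.state.get("cov_ranges", {})
        for k, v in at.items():
            lo, hi = ranges.get(k, (-np.inf, np.inf))
            if not lo <= v <= hi:
                import warnings
                warnings.warn(f"covariate {k}={v} outside the observed range "
                              f"[{lo}, {hi}]; extrapolating", stacklevel=3)
        means.update(at)
    return means


def marginal_effects(fit: ModelFit, at: dict | None = None) -> pd.DataFrame:
    """Predicted cell means on the response scale with delta-method SEs.

    For a log link the prediction is ``exp(eta)`` (the conditional mean at a
    zero random intercept); for identity it is ``eta`` itself.
    """
    atv = _at_values(fit, at)
    rows = []
    for s in SESSIONS:
        for t in TIMES:
            x = cell_row(fit.names, s, t, atv)
            eta = float(x @ fit.params)
            se_eta = float(np.sqrt(x @ fit.cov_params @ x))
            if fit.link == "log":
                est, se = np.exp(eta), np.exp(eta) * se_eta
            else:
                est, se = eta, se_eta
            rows.append({"session": s, "time": t, "estimate": est, "se": se,
                         "linear_predictor": eta})
    return pd.DataFrame(rows)


def max_abs_stat_samples(L: np.ndarray, C: np.ndarray, df: float,
                         n_pow: int = 17, seed: int = 202_6) -> np.ndarray:
    """QMC samples of ``max_j |T_j|`` for contrasts ``L beta_hat`` with
    covariance ``C``, standardized, with a shared chi denominator at ``df``."""
    w, V = np.linalg.eigh(C)
    keep = w > max(w.max(), 0) * 1e-12
    A = V[:, keep] * np.sqrt(w[keep])
    r = A.shape[1]
    sd = np.sqrt(np.einsum("ij,jk,ik->i", L, C, L))
    eng = qmc.Sobol(d=r + 1, scramble=True, seed=seed)
    U = np.clip(eng.random(2 ** n_pow), 1e-12, 1 - 1e-12)
    Z = sps.norm.ppf(U[:, :r])
    X = Z @ A.T @ L.T / sd
    M = np.abs(X).max(axis=1)
    if np.isfinite(df):
        M = M / np.sqrt(sps.chi2.ppf(U[:, r], df) / df)
    return M


def tukey_adjust(t_obs: np.ndarray, L: np.ndarray, C: np.ndarray,
                 df: float = np.inf, n_pow: int = 17, seed: int = 202_6) -> np.ndarray:
    """Family-wise adjusted p-values ``P(max_j |T_j| >= |t_i|)``.

    Never smaller than the raw two-sided p-value (enforced, which also
    absorbs the QMC integration error).
    """
    t_obs = np.atleast_1d(np.asarray(t_obs, dtype=float))
    M = max_abs_stat_samples(np.atleast_2d(L), np.asarray(C, float), df,
                             n_pow=n_pow, seed=seed)
    p_adj = np.array([(M >= abs(t)).mean() for t in t_obs])
    if np.isfinite(df):
        p_raw = 2.0 * sps.t.sf(np.abs(t_obs), df)
    else:
        p_raw = 2.0 * sps.norm.sf(np.abs(t_obs))
    return np.clip(np.maximum(p_adj, p_raw), 0.0, 1.0)


def _families(kind: str):
    if kind == "session_within_time":
        return [((t,), [((a, t), (b, t)) for a, b in combinations(SESSIONS, 2)])
                for t in TIMES]
    if kind == "time_within_session":
        return [((s,), [((s, a), (s, b)) for a, b in combinations(TIMES, 2)])
                for s in SESSIONS]
    raise InvalidArgumentError(f"unknown contrast family {kind!r}")


def tukey_contrasts(fit: ModelFit, family: str = "session_within_time",
                    at: dict | None = None) -> pd.DataFrame:
    """All pairwise cell contrasts, adjusted within each family.

    Log-link contrasts are exponentiated to response-scale ratios with
    delta-method SEs; Gaussian fits report differences with Satterthwaite df.
    The adjustment family is the set of pairwise contrasts sharing the same
    conditioning level (e.g. the three session contrasts at one time point).
    """
    atv = _at_values(fit, at)
    gaussian = fit.family == "gaussian"
    rows = []
    for level, pairs in _families(family):
        if len(pairs) < 1:
            continue
        L = []
        for (sa, ta), (sb, tb) in pairs:
            L.append(cell_row(fit.names, sa, ta, atv) - cell_row(fit.names, sb, tb, atv))
        L = np.asarray(L)
        est = L @ fit.params
        se = np.sqrt(np.einsum("ij,jk,ik->i", L, fit.cov_params, L))
        t_stat = est / se
        if gaussian:
            dfs = np.array([satterthwaite_df(fit, ell) for ell in L])
            fam_df = float(dfs.min())
        else:
            dfs = np.full(len(pairs), np.inf)
            fam_df = np.inf
        p_adj = tukey_adjust(t_stat, L, fit.cov_params, df=fam_df)
        for i, ((sa, ta), (sb, tb)) in enumerate(pairs):
            if fit.link == "log":
                scale = "ratio"
                estimate = float(np.exp(est[i]))
                se_out = float(estimate * se[i])
            else:
                scale = "difference"
                estimate = float(est[i])
                se_out = float(se[i])
            la = sa if family == "session_within_time" else ta
            lb = sb if family == "session_within_time" else tb
            sep = "/" if scale == "ratio" else " - "
            rows.append({
                "contrast": f"{la}{sep}{lb}",
                "by": level[0],
                "scale": scale,
                "estimate": estimate,
                "se": se_out,
                "statistic": float(t_stat[i]),
                "df": float(dfs[i]),
                "p_adjusted": float(p_adj[i]),
            })
    return pd.DataFrame(rows)
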