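"""Blinded covariate screen with semi-partial R-squared.

The screen fits MEPabs ~ MEPpre + Time + TPR + FPm + Tt + Mr + (1 | Subject)
— deliberately without Session, so covariate selection cannot be steered by
the treatment labels — and attributes to each performance covariate the
fraction of outcome variance it uniquely explains. The statistic is the Wald
R-squared-beta, ``R2 = F / (F + df)`` with ``F = (beta/se)^2`` and a
Satterthwaite denominator df; covariates at or above the 5% cutoff are
selected into the downstream treatment models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .base import ModelFit
from .design import additive_design, validate_trial_table
from .lmm import fit_lmm, satterthwaite_df

__all__ = ["ScreenResult", "screen_covariates", "SCREEN_COVARIATES"]

#: BCI performance metrics eligible for selection.
SCREEN_COVARIATES = ("tpr", "fp_m", "t_t", "m_r")


@dataclass
class ScreenResult:
    """Per-covariate semi-partial R^2 (percent) and the selected subset."""

    r2: dict[str, float]
    selected: list[str]
    threshold: float
    fit: ModelFit = field(repr=False, default=None)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "covariate": list(self.r2),
            "r2_percent": list(self.r2.values()),
            "selected": [c in self.selected for c in self.r2],
        })


def screen_covariates(table: pd.DataFrame, threshold: float = 5.0) -> ScreenResult:
    """Run the blinded screen and apply the >= ``threshold``% selection rule."""
    validate_trial_table(table)
    covs = ("mep_pre",) + SCREEN_COVARIATES
    X = additive_design(table, covariates=covs)
    y = table["mep_abs"].to_numpy(dtype=float)
    fit = fit_lmm(y, X, table["subject"].to_numpy(), reml=True)

    y_scale = max(float(np.std(y)), 1e-300)
    r2: dict[str, float] = {}
    for c in covs:
        j = fit.names.index(c)
        beta, se = fit.params[j], fit.se[j]
        x_scale = max(float(np.std(X[c])), 1e-300)
        # Degenerate exact fits: a coefficient that is numerically zero at
        # machine scale explains nothing even when the residual variance
        # underflows and the Wald ratio becomes 0/0.
        if abs(beta) * x_scale < 1e-10 * y_scale:
            r2[c] = 0.0
            continue
        if se == 0:
            r2[c] = 100.0
            continue
        F = (beta / se) ** 2
        if F > 1e12:  # numerically exact fit; df is moot
            r2[c] = 100.0
            continue
        ell = np.zeros(len(fit.names))
        ell[j] = 1.0
        df = satterthwaite_df(fit, ell)
        r2[c] = float(100.0 * F / (F + df))
    selected = [c for c in SCREEN_COVARIATES if r2[c] >= threshold]
    return ScreenResult(r2=r2, selected=selected, threshold=threshold, fit=fit)
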