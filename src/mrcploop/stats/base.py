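"""Shared model-fit container, AICc and numerical-differentiation helpers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import InvalidArgumentError

__all__ = ["ModelFit", "aicc", "approx_hessian"]


@dataclass
class ModelFit:
    """A fitted (mixed) regression model.

    ``params``/``se`` are aligned with ``names``; ``re_sd`` is the SD of the
    scalar random intercept, ``dispersion`` the Gamma shape (for the Gamma
    family) or the residual SD (Gaussian). ``loglik`` is the maximized
    marginal log-likelihood (ML for the Gamma family; REML for Gaussian fits
    unless stated otherwise) and ``k`` counts every estimated parameter.
    ``state`` carries family-specific internals used by downstream effect and
    contrast computations.
    """

    names: list[str]
    params: np.ndarray
    se: np.ndarray
    cov_params: np.ndarray
    family: str
    link: str
    re_sd: float
    dispersion: float
    loglik: float
    n: int
    k: int
    method: str = "ML"
    converged: bool = True
    state: dict = field(default_factory=dict, repr=False)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    def summary(self) -> pd.DataFrame:
        z = self.params / self.se
        return pd.DataFrame(
            {"estimate": self.params, "se": self.se, "statistic": z},
            index=self.names,
        )

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])


def aicc(fit: ModelFit) -> float:
    """Small-sample-corrected Akaike criterion.

    ``AICc = -2 loglik + 2k + 2k(k+1)/(n - k - 1)``; undefined when
    ``n <= k + 1``. The correction vanishes as n grows, so AICc >= AIC always.
    """
    n, k = fit.n, fit.k
    if n <= k + 1:
        raise InvalidArgumentError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return fit.aic + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def approx_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian with per-coordinate relative steps."""
    x = np.asarray(x, dtype=float)
    p = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4.0 * h[i] * h[j])
    return H
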