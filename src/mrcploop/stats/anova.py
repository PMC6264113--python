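"""One-way repeated-measures ANOVA for the per-session BCI performance metrics.

Subjects serve as blocks (each contributes one value per session), so the
error term is the subject-by-session interaction: for k sessions and n
subjects the F statistic carries (k - 1, (k - 1)(n - 1)) degrees of freedom —
(2, 22) in a 12-subject, 3-session design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ..errors import UnbalancedDesignError

__all__ = ["AnovaResult", "oneway_rm_anova"]


@dataclass
class AnovaResult:
    f: float
    df: tuple[int, int]
    p: float


def oneway_rm_anova(table: pd.DataFrame, value: str,
                    subject: str = "subject", factor: str = "session") -> AnovaResult:
    """Subject-blocked one-way ANOVA over ``factor`` on a long-format table."""
    wide = table.pivot(index=subject, columns=factor, values=value)
    if wide.isna().any().any():
        raise UnbalancedDesignError("every subject needs a value in every session")
    Y = wide.to_numpy(dtype=float)
    n, k = Y.shape
    grand = Y.mean()
    ss_factor = n * np.sum((Y.mean(axis=0) - grand) ** 2)
    ss_subject = k * np.sum((Y.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((Y - grand) ** 2)
    ss_error = ss_total - ss_factor - ss_subject
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_factor = ss_factor / df1
    ms_error = ss_error / df2
    # Constant (or numerically constant) data: no variance to partition.
    tiny = 1e-12 * max(abs(grand) ** 2 * n * k, 1.0)
    if ms_error <= tiny:
        return AnovaResult(f=0.0 if ms_factor <= tiny else np.inf, df=(df1, df2),
                           p=1.0 if ms_factor <= tiny else 0.0)
    f = ms_factor / ms_error
    return AnovaResult(f=float(f), df=(df1, df2), p=float(sps.f.sf(f, df1, df2)))
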