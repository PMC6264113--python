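"""Explicit treatment-coded design matrices for the trial-table models.

Reference cell is session ES at time post. Column naming:
``Intercept``, ``session[PM]``, ``session[Comb]``, ``time[post30]``,
``session[PM]:time[post30]``, ``session[Comb]:time[post30]`` plus raw
continuous covariate columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..errors import CollinearityError, InvalidArgumentError
from ..types import SESSIONS, TIMES

__all__ = [
    "TRIAL_TABLE_COLUMNS", "validate_trial_table",
    "interaction_design", "additive_design", "cell_row",
]

TRIAL_TABLE_COLUMNS = (
    "subject", "session", "time", "mep_abs", "mep_pre", "mep_pct",
    "tpr", "fp_m", "t_t", "m_r",
)


def validate_trial_table(table: pd.DataFrame, outcome: str = "mep_abs") -> pd.DataFrame:
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidArgumentError(f"trial table missing columns: {missing}")
    if table.duplicated(["subject", "session", "time"]).any():
        raise InvalidArgumentError("duplicate (subject, session, time) rows")
    if outcome in ("mep_abs",) and not (table[outcome] > 0).all():
        raise InvalidArgumentError(f"{outcome} must be strictly positive")
    return table


def _factor_columns(table: pd.DataFrame, interaction: bool) -> pd.DataFrame:
    cols = {"Intercept": np.ones(len(table))}
    for s in SESSIONS[1:]:
        cols[f"session[{s}]"] = (table["session"] == s).astype(float).to_numpy()
    for t in TIMES[1:]:
        cols[f"time[{t}]"] = (table["time"] == t).astype(float).to_numpy()
    if interaction:
        for s in SESSIONS[1:]:
            for t in TIMES[1:]:
                cols[f"session[{s}]:time[{t}]"] = (
                    ((table["session"] == s) & (table["time"] == t))
                    .astype(float).to_numpy())
    return pd.DataFrame(cols, index=table.index)


def _check_rank(X: pd.DataFrame) -> None:
    _, R = np.linalg.qr(X.to_numpy())
    diag = np.abs(np.diag(R))
    bad = diag < 1e-8 * max(diag.max(), 1.0)
    if bad.any():
        raise CollinearityError([X.columns[i] for i in np.flatnonzero(bad)])


def interaction_design(table: pd.DataFrame,
                       covariates: tuple[str, ...] = ("mep_pre", "t_t")) -> pd.DataFrame:
    """Session x Time full-factorial design plus continuous covariates."""
    X = _factor_columns(table, interaction=True)
    for c in covariates:
        X[c] = table[c].to_numpy(dtype=float)
    _check_rank(X)
    return X


def additive_design(table: pd.DataFrame,
                    covariates: tuple[str, ...]) -> pd.DataFrame:
    """Time main effect plus covariates, deliberately *without* session
    (the blinded covariate screen)."""
    X = _factor_columns(table, interaction=False)
    X = X.drop(columns=[c for c in X.columns if c.startswith("session")])
    for c in covariates:
        X[c] = table[c].to_numpy(dtype=float)
    _check_rank(X)
    return X


def cell_row(columns, session: str, time: str, at: dict) -> np.ndarray:
    """Design row for a (session, time) cell with covariates at ``at``."""
    row = np.zeros(len(columns))
    for j, name in enumerate(columns):
        if name == "Intercept":
            row[j] = 1.0
        elif name == f"session[{session}]":
            row[j] = 1.0
        elif name == f"time[{time}]":
            row[j] = 1.0
        elif name == f"session[{session}]:time[{time}]":
            row[j] = 1.0
        elif "[" not in name:
            if name not in at:
                raise InvalidArgumentError(f"no value supplied for covariate {name!r}")
            row[j] = float(at[name])
    return row
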