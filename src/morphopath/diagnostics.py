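"""Collinearity diagnostics for the model's predictor sets."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["vif", "vif_table"]


def vif(predictors: pd.DataFrame, target: str) -> float:
    """Variance inflation factor of one predictor against the others.

    ``1 / (1 - R^2)`` with R^2 from the ordinary least-squares regression of
    ``target`` on the remaining columns (plus an intercept). Always >= 1;
    perfect collinearity is reported as ``inf`` with a warning.
    """
    if target not in predictors.columns:
        raise KeyError(f"target {target!r} not among predictors")
    others = [c for c in predictors.columns if c != target]
    if not others:
        raise ValueError("VIF needs >= 2 predictors")
    n = len(predictors)
    if n <= len(predictors.columns):
        raise ValueError("need n > number of predictors")
    y = predictors[target].to_numpy(dtype=float)
    x = np.column_stack([np.ones(n),
                         predictors[others].to_numpy(dtype=float)])
    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError(f"target {target!r} is constant")
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    if r2 >= 1.0 - 1e-12:
        warnings.warn(f"perfect collinearity for {target!r}; VIF infinite",
                      stacklevel=2)
        return float("inf")
    return float(1.0 / (1.0 - r2))


def vif_table(predictors: pd.DataFrame) -> pd.Series:
    """VIF of every column against the rest."""
    return pd.Series({c: vif(predictors, c) for c in predictors.columns},
                     name="vif")
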