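"""Partial-dependence explainability for hazard models.

The marginal effect of covariate X_k on the predicted log-hazard is
estimated by clamping X_k to each grid value x in every observed row,
keeping all other covariates at their observed values, and averaging the
model's predicted log-hazard:

    pd_k(x) = (1/n) * sum_i f(x, x_other^(i))

For covariates that carry a mean-imputation missingness flag, the flag
column is held at 0 while the value is clamped: the curve describes the
counterfactual in which the value was actually observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .preprocess import FLAG_SUFFIX

__all__ = ["PDPCurve", "partial_dependence", "partial_dependence_all"]


@dataclass
class PDPCurve:
    covariate: str
    grid: np.ndarray
    mean_log_hazard: np.ndarray
    n: int

    def centered(self) -> np.ndarray:
        return self.mean_log_hazard - self.mean_log_hazard.mean()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "covariate": self.covariate,
            "grid_value": self.grid,
            "mean_log_hazard": self.mean_log_hazard,
        })


def _auto_grid(values: np.ndarray, n_grid: int) -> np.ndarray:
    uniq = np.unique(values)
    if np.isin(uniq, (0.0, 1.0)).all():
        return np.asarray([0.0, 1.0])
    lo, hi = np.quantile(values, [0.01, 0.99])
    return np.linspace(lo, hi, n_grid)


def partial_dependence(model, data: CohortTable, covariate: str,
                       grid: np.ndarray | None = None,
                       n_grid: int = 20) -> PDPCurve:
    """Average predicted log-hazard over the data with one covariate clamped
    to each grid value.

    ``model`` is anything exposing ``predict_log_hazard(covariates)``; the
    data must be complete (post-transform). The automatic grid is {0, 1} for
    binary covariates, otherwise ``n_grid`` equispaced points between the
    1st and 99th percentile of the observed values.
    """
    cov = data.covariates
    if covariate not in cov.columns:
        raise ValueError(f"covariate {covariate!r} not in the data")
    if cov.isna().any().any():
        raise ValueError("partial dependence needs complete covariates")
    values = cov[covariate].to_numpy(dtype=float)
    if grid is None:
        grid = _auto_grid(values, n_grid)
    grid = np.sort(np.asarray(grid, dtype=float))

    flag = covariate + FLAG_SUFFIX
    means = []
    work = cov.copy()
    if flag in work.columns:
        work[flag] = 0.0  # counterfactual: the value was observed
    for x in grid:
        work[covariate] = x
        means.append(float(model.predict_log_hazard(work).mean()))
    return PDPCurve(covariate=covariate, grid=grid,
                    mean_log_hazard=np.asarray(means), n=len(cov))


def partial_dependence_all(model, data: CohortTable,
                           covariates: list[str] | None = None,
                           n_grid: int = 20) -> pd.DataFrame:
    """Long-format table of PDP curves for several covariates (flag columns
    skipped by default)."""
    if covariates is None:
        covariates = [c for c in data.covariate_names
                      if not c.endswith(FLAG_SUFFIX)]
    frames = [partial_dependence(model, data, c, n_grid=n_grid).to_frame()
              for c in covariates]
    return pd.concat(frames, ignore_index=True)
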