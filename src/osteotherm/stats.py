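"""Model-development statistics.

Three questions shaped the decision model, and this module reproduces the
machinery behind each:

* which colour parameters are redundant — pairwise Pearson correlations
  (RGB and L* track each other closely; L* vs b* correlate weakly, which is
  why the model lives in that plane);
* how strongly temperature, duration and medium drive L* and b* — ordinary
  least squares with standardized coefficients (β) and semi-partial (part)
  correlations per predictor;
* what temperature range each cluster actually spans in a dataset with
  known exposure temperatures — empirical per-cluster minima/maxima.

OLS is delegated to statsmodels; β is ``b·σ_x/σ_y`` and the part
correlation is recovered from the coefficient t statistic as
``t_j · sqrt((1 − R²) / df_resid)``, the standard identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .colour import DomainError
from .dataset import ColourDataset
from .decision import DecisionThresholds, assign_clusters, temperature_range

__all__ = [
    "RegressionResult",
    "CollinearityError",
    "pearson_r",
    "correlation_matrix",
    "standardized_mlr",
    "cluster_temperature_ranges",
    "encode_predictors",
]


class CollinearityError(ValueError):
    """Predictor matrix is rank-deficient."""


def pearson_r(x, y) -> tuple:
    """Product-moment correlation with a two-sided t-test p-value.

    The p-value comes from ``t = r·sqrt((n − 2)/(1 − r²))`` on n − 2 degrees
    of freedom.  Vectors must have equal length >= 3 and non-zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise DomainError(f"need at least 3 observations, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DomainError("correlation undefined: a vector has zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def correlation_matrix(ds: ColourDataset | pd.DataFrame, params) -> tuple:
    """Pairwise Pearson correlations between colour parameters.

    Returns ``(r, p)`` as two symmetric DataFrames with unit/zero diagonal.
    """
    frame = ds.frame if isinstance(ds, ColourDataset) else ds
    missing = [c for c in params if c not in frame.columns]
    if missing:
        raise DomainError(f"parameters not in dataset: {missing}")
    k = len(params)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            rij, pij = pearson_r(frame[params[i]], frame[params[j]])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    return (
        pd.DataFrame(r, index=params, columns=params),
        pd.DataFrame(p, index=params, columns=params),
    )


def encode_predictors(frame: pd.DataFrame, predictors) -> pd.DataFrame:
    """Numeric design matrix: medium -> 0/1 (air/adipose), age_group -> dummies."""
    cols = {}
    for name in predictors:
        if name == "medium":
            cols[name] = frame["medium"].map({"air": 0.0, "adipose": 1.0})
            if cols[name].isna().any():
                raise DomainError("medium column contains values other than air/adipose")
        elif name == "age_group":
            dummies = pd.get_dummies(frame["age_group"], prefix="age", drop_first=True)
            for c in dummies.columns:
                cols[c] = dummies[c].astype(float)
        else:
            cols[name] = pd.to_numeric(frame[name])
    return pd.DataFrame(cols, index=frame.index)


@dataclass
class RegressionResult:
    """Standardized OLS summary: one row per predictor."""

    response: str
    n: int
    r_squared: float
    table: pd.DataFrame  # index: predictor; columns: beta, part_correlation, p_value

    def __post_init__(self) -> None:
        if (self.table["part_correlation"].abs() > 1 + 1e-12).any():
            raise DomainError("part correlation outside [-1, 1]")
        if ((self.table["p_value"] < 0) | (self.table["p_value"] > 1)).any():
            raise DomainError("p-value outside [0, 1]")


def standardized_mlr(
    ds: ColourDataset | pd.DataFrame,
    response: str,
    predictors,
) -> RegressionResult:
    """OLS of ``response`` on ``predictors`` with standardized β and part r.

    ``medium`` is coded air=0/adipose=1 and ``age_group`` expands to dummy
    columns.  Raises :class:`CollinearityError` for a rank-deficient design.
    """
    frame = ds.frame if isinstance(ds, ColourDataset) else ds
    X = encode_predictors(frame, list(predictors))
    y = pd.to_numeric(frame[response])
    n, k = X.shape
    if n <= k + 1:
        raise DomainError(f"need n > {k + 1} observations for {k} predictors, got {n}")
    if np.linalg.matrix_rank(X.to_numpy()) < k:
        raise CollinearityError("predictors are collinear; coefficients not identifiable")

    fit = sm.OLS(y.to_numpy(), sm.add_constant(X.to_numpy())).fit()
    b = fit.params[1:]
    t = fit.tvalues[1:]
    p = fit.pvalues[1:]
    beta = b * X.std(ddof=1).to_numpy() / y.std(ddof=1)
    part = t * np.sqrt((1.0 - fit.rsquared) / fit.df_resid)

    table = pd.DataFrame(
        {"beta": beta, "part_correlation": part, "p_value": p},
        index=list(X.columns),
    )
    return RegressionResult(response=response, n=n, r_squared=float(fit.rsquared), table=table)


def cluster_temperature_ranges(
    ds: ColourDataset | pd.DataFrame,
    thresholds: DecisionThresholds | None = None,
) -> pd.DataFrame:
    """Empirical exposure-temperature range per assigned cluster.

    Each record's (L*, b*) is pushed through the decision model and the true
    exposure temperatures are summarised per cluster.  Clusters with no
    members are retained with ``observed=False`` so gaps are visible.
    """
    frame = ds.frame if isinstance(ds, ColourDataset) else ds
    if "temperature_c" not in frame.columns:
        raise DomainError("dataset has no temperature_c column")
    cluster = assign_clusters(
        frame["L_star"].to_numpy(dtype=float),
        frame["B_star"].to_numpy(dtype=float),
        thresholds,
    )
    temps = frame["temperature_c"].to_numpy(dtype=float)
    rows = []
    for cid in range(1, 8):
        sel = temps[cluster == cid]
        model_range = temperature_range(cid)
        rows.append(
            {
                "cluster": cid,
                "observed": sel.size > 0,
                "n": int(sel.size),
                "t_min_c": float(sel.min()) if sel.size else np.nan,
                "t_max_c": float(sel.max()) if sel.size else np.nan,
                "model_t_min_c": model_range.t_min_c,
                "model_t_max_c": model_range.upper_bound,
            }
        )
    return pd.DataFrame(rows).set_index("cluster")
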