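"""Random-forest regression of isotope values on climate and population,
with cross-validation and residual diagnostics.

Predictors are the five Monte-Carlo mean covariates (four climate variables
plus one population KDE variant).  Collinearity between predictors is
screened with pairwise Pearson correlations at a 0.70 threshold; flagged
pairs are reported but retained, since tree ensembles tolerate correlated
predictors.  Diagnostics are out-of-fold residual autocorrelation over
20-year time bins and Moran's I on an inverse-great-circle-distance weight
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from statsmodels.tsa.stattools import acf as sm_acf

__all__ = [
    "FEATURES_UNCORRECTED",
    "FEATURES_CORRECTED",
    "ForestModel",
    "DiagnosticsReport",
    "collinearity_screen",
    "fit_forest",
    "cross_validate",
    "residual_diagnostics",
    "morans_i",
    "great_circle_km",
]

CLIMATE_FEATURES = ["temp", "temp_seasonality", "precip", "precip_seasonality"]
FEATURES_UNCORRECTED = CLIMATE_FEATURES + ["mean_kde_uncorrected"]
FEATURES_CORRECTED = CLIMATE_FEATURES + ["mean_kde_corrected"]

EARTH_RADIUS_KM = 6371.0
DISTANCE_FLOOR_KM = 1.0


@dataclass
class ForestModel:
    """Trained ensemble with its design metadata."""

    estimator: RandomForestRegressor
    features: list[str]
    n_trees: int
    min_node_size: int
    seed: int
    training_r2: float = np.nan
    oob_r2: float = np.nan

    def predict(self, design: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(design, pd.DataFrame):
            design = design[self.features].to_numpy()
        return self.estimator.predict(design)


@dataclass
class DiagnosticsReport:
    rmse_cv: float
    pct_variance_explained_cv: float
    acf_lags_yr: np.ndarray
    acf_values: np.ndarray
    morans_i: dict
    collinearity: pd.DataFrame


def collinearity_screen(
    design: pd.DataFrame, threshold: float = 0.70
) -> tuple[list[str], pd.DataFrame]:
    """Pairwise Pearson screen at |r| >= threshold.

    Returns all variables (flagged pairs are reported, not dropped) and the
    correlation matrix with a boolean ``flagged`` attribute per pair encoded
    in a long-form frame.
    """
    if design.shape[1] < 2:
        raise ValueError("need at least two variables to screen")
    stds = design.std(ddof=0)
    if (stds == 0).any():
        bad = list(stds.index[stds == 0])
        raise ValueError(f"constant column(s): correlation undefined for {bad}")
    corr = design.corr()
    rows = []
    cols = list(design.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = float(corr.loc[a, b])
            rows.append({"var_a": a, "var_b": b, "r": r,
                         "flagged": abs(r) >= threshold})
    return cols, pd.DataFrame(rows)


def fit_forest(
    design: pd.DataFrame,
    response: np.ndarray | pd.Series,
    features: Sequence[str] | None = None,
    n_trees: int = 500,
    min_node_size: int = 5,
    seed: int = 0,
) -> ForestModel:
    """Fit the regression forest.

    Defaults mirror standard regression-forest practice: 500 trees,
    ⌊p/3⌋ candidate variables per split (minimum 1), minimum node size 5.
    """
    if features is None:
        features = [c for c in design.columns]
    X = design[list(features)].to_numpy()
    y = np.asarray(response, dtype=float)
    if len(X) < 20:
        raise ValueError(f"need at least 20 rows to fit a forest, got {len(X)}")
    if np.any(~np.isfinite(X)) or np.any(~np.isfinite(y)):
        raise ValueError("design/response contain missing or non-finite values")
    mtry = max(1, len(features) // 3)
    est = RandomForestRegressor(
        n_estimators=n_trees, max_features=mtry,
        min_samples_leaf=min_node_size, random_state=seed, oob_score=True,
        n_jobs=1,
    )
    est.fit(X, y)
    return ForestModel(
        estimator=est, features=list(features), n_trees=n_trees,
        min_node_size=min_node_size, seed=seed,
        training_r2=float(est.score(X, y)), oob_r2=float(est.oob_score_),
    )


def cross_validate(
    design: pd.DataFrame,
    response: np.ndarray | pd.Series,
    features: Sequence[str] | None = None,
    k: int = 10,
    seed: int = 0,
    n_trees: int = 500,
    min_node_size: int = 5,
    return_predictions: bool = False,
):
    """k-fold cross-validation of the forest.

    Returns (rmse, pct_variance_explained) from the pooled out-of-fold
    predictions; pct is the VEcv measure 100·(1 − Σ(y−ŷ)²/Σ(y−ȳ)²).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if features is None:
        features = [c for c in design.columns]
    X = design[list(features)].to_numpy()
    y = np.asarray(response, dtype=float)
    if len(y) < k:
        raise ValueError("need at least k rows")
    mtry = max(1, len(features) // 3)
    oof = np.empty_like(y)
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (tr, te) in enumerate(kf.split(X)):
        est = RandomForestRegressor(
            n_estimators=n_trees, max_features=mtry,
            min_samples_leaf=min_node_size, random_state=seed + fold, n_jobs=1,
        )
        est.fit(X[tr], y[tr])
        oof[te] = est.predict(X[te])
    rmse = float(np.sqrt(np.mean((y - oof) ** 2)))
    sst = float(np.sum((y - y.mean()) ** 2))
    pct = 100.0 * (1.0 - float(np.sum((y - oof) ** 2)) / sst)
    if return_predictions:
        return rmse, pct, oof
    return rmse, pct


def great_circle_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Haversine distance in km (array-friendly)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def morans_i(residuals: np.ndarray, lats: np.ndarray, lons: np.ndarray,
             distance_floor_km: float = DISTANCE_FLOOR_KM) -> dict:
    """Moran's I with inverse great-circle-distance weights.

    I = (n/S0) · (ΣΣ w_ij r_i r_j) / (Σ r_i²) with w_ij = 1/d_ij, w_ii = 0,
    distances floored at ``distance_floor_km``.  The expected value under no
    autocorrelation, its normal-approximation standard deviation and a
    two-sided p-value are returned.
    """
    r = np.asarray(residuals, dtype=float)
    n = len(r)
    if n < 3:
        raise ValueError("Moran's I needs at least 3 observations")
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    d = great_circle_km(lats[:, None], lons[:, None], lats[None, :], lons[None, :])
    d = np.maximum(d, distance_floor_km)
    w = 1.0 / d
    np.fill_diagonal(w, 0.0)

    z = r - r.mean()
    s0 = w.sum()
    num = z @ w @ z
    den = float(np.sum(z * z))
    observed = (n / s0) * (num / den)

    expected = -1.0 / (n - 1)
    # normal approximation moments (Cliff & Ord)
    s1 = 0.5 * np.sum((w + w.T) ** 2)
    s2 = np.sum((w.sum(axis=1) + w.sum(axis=0)) ** 2)
    b2 = n * np.sum(z**4) / (np.sum(z**2) ** 2)
    var = (
        n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2)
        - b2 * ((n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2)
    ) / ((n - 1) * (n - 2) * (n - 3) * s0**2) - expected**2
    sd = float(np.sqrt(max(var, 0.0)))
    if sd > 0:
        zscore = (observed - expected) / sd
        p = 2.0 * stats.norm.sf(abs(zscore))
    else:
        p = np.nan
    return {"observed": float(observed), "expected": float(expected),
            "sd": sd, "p": float(p)}


def residual_diagnostics(
    design: pd.DataFrame,
    response: np.ndarray | pd.Series,
    lats: np.ndarray,
    lons: np.ndarray,
    mean_death_years: np.ndarray,
    features: Sequence[str] | None = None,
    k: int = 10,
    seed: int = 0,
    n_trees: int = 500,
    time_bin_yr: float = 20.0,
    acf_max_lag: int = 20,
) -> DiagnosticsReport:
    """Out-of-fold residual diagnostics for one model.

    Residuals are binned to ``time_bin_yr`` steps of mean death year for the
    temporal acf; Moran's I uses the raw per-individual residuals.
    """
    y = np.asarray(response, dtype=float)
    rmse, pct, oof = cross_validate(
        design, y, features=features, k=k, seed=seed, n_trees=n_trees,
        return_predictions=True,
    )
    resid = y - oof

    bins = np.round(np.asarray(mean_death_years, dtype=float) / time_bin_yr)
    series = (pd.DataFrame({"bin": bins, "r": resid})
              .groupby("bin")["r"].mean().sort_index())
    nlags = min(acf_max_lag, len(series) - 1)
    acf_vals = sm_acf(series.to_numpy(), nlags=nlags, fft=False)
    acf_lags = np.arange(nlags + 1) * time_bin_yr

    screen_design = design[features] if features is not None else design
    _, corr = collinearity_screen(screen_design)
    return DiagnosticsReport(
        rmse_cv=rmse, pct_variance_explained_cv=pct,
        acf_lags_yr=acf_lags, acf_values=acf_vals,
        morans_i=morans_i(resid, lats, lons), collinearity=corr,
    )
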