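"""Interaction-deducted effect sizes from centered partial dependence.

For a fitted ensemble model F and covariate j, the centered partial
dependence PD_j(v) is the mean prediction with every row's covariate j set
to v, centered over the evaluation grid.  Friedman's H statistic measures
the proportion of j's effect that is due to interactions:

    H_j = Σ_{i,k} (f_{i,k} − PD_j(v_k) − PD_−j(i))² / Σ_{i,k} f_{i,k}²

with f the centered prediction matrix, PD_−j the centered complement
partial dependence per row.  The explained sum of squares of j,
SS_j = Σ_k PD_j(v_k)², is deducted by the interaction share, SS_j·(1 − H_j),
averaged over Monte-Carlo re-draws of the evaluation grid from the observed
covariate values, and reported on the per-mil scale as √SS and as a percent
of the total prediction variability √SS_total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .forest import ForestModel

__all__ = [
    "PDProfile",
    "EffectDecomposition",
    "pd_profile",
    "friedman_h",
    "effect_size",
    "cumulative_comparison",
    "CLIMATE_SET",
]

CLIMATE_SET = ("temp", "temp_seasonality", "precip", "precip_seasonality")


@dataclass
class PDProfile:
    variable: str
    grid: np.ndarray          # (m,) evaluation values of x_j
    pd_centered: np.ndarray   # (m,) centered partial dependence over the grid
    pd_complement: np.ndarray  # (n,) centered complement PD per row
    predictions: np.ndarray   # (n, m) raw prediction matrix f-hat_{i,k}


@dataclass
class EffectDecomposition:
    zone: str
    variable: str
    h: float
    ss_raw: float
    ss_deducted: float
    ss_total: float
    effect_permil: float
    percent_of_total: float
    n_iterations: int


def _prediction_matrix(model: ForestModel, rows: pd.DataFrame,
                       variable: str, grid: np.ndarray) -> np.ndarray:
    """(n, m) matrix of predictions with rows[variable] swept over grid."""
    X = rows[model.features].to_numpy(dtype=float)
    n, m = len(X), len(grid)
    j = model.features.index(variable)
    rep = np.repeat(X, m, axis=0)
    rep[:, j] = np.tile(np.asarray(grid, dtype=float), n)
    return model.predict(rep).reshape(n, m)


def pd_profile(
    model: ForestModel,
    rows: pd.DataFrame,
    variable: str,
    grid: np.ndarray,
) -> PDProfile:
    """Centered partial-dependence profile of one covariate.

    ``grid`` is the set of values at which covariate ``variable`` is
    evaluated; predictions are averaged over the observed joint distribution
    of the remaining covariates (the rows).
    """
    if variable not in model.features:
        raise ValueError(f"{variable!r} is not a model feature {model.features}")
    grid = np.asarray(grid, dtype=float)
    if len(grid) == 0 or len(rows) == 0:
        raise ValueError("grid and rows must be non-empty")
    preds = _prediction_matrix(model, rows, variable, grid)
    pd_j = preds.mean(axis=0)
    pd_j = pd_j - pd_j.mean()
    pd_mj = preds.mean(axis=1)
    pd_mj = pd_mj - pd_mj.mean()
    return PDProfile(variable=variable, grid=grid, pd_centered=pd_j,
                     pd_complement=pd_mj, predictions=preds)


def friedman_h(profile: PDProfile) -> float:
    """Interaction proportion of one covariate's effect, in [0, 1].

    Zero for a model that is additive in the covariate; one when the entire
    joint effect is interaction.  Invariant to constant shifts of the
    predictions (everything is centered).
    """
    f = profile.predictions - profile.predictions.mean()
    denom = float(np.sum(f * f))
    if denom <= 0:
        warnings.warn("prediction matrix has zero variance; H reported as 0",
                      stacklevel=2)
        return 0.0
    resid = f - profile.pd_centered[None, :] - profile.pd_complement[:, None]
    h = float(np.sum(resid * resid)) / denom
    return float(np.clip(h, 0.0, 1.0))


def effect_size(
    model: ForestModel,
    rows: pd.DataFrame,
    variable: str,
    zone: str = "",
    n_iter: int = 100,
    m: int = 100,
    seed: int | np.random.Generator = 0,
    deduct: str = "one_minus_h",
) -> EffectDecomposition:
    """Monte-Carlo estimate of one covariate's interaction-deducted effect.

    Per iteration, ``m`` values of the covariate are resampled with
    replacement from its observed values in ``rows`` and used as the PD
    evaluation grid; the explained sum of squares, Friedman's H and the
    total prediction variability are computed and averaged over
    ``n_iter`` iterations.  ``deduct`` selects the interaction deduction:
    ``"one_minus_h"`` (default) or ``"one_minus_h2"``.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    if len(rows) < m / 2:
        raise ValueError(f"zone has too few rows ({len(rows)}) for m={m}")
    if deduct not in ("one_minus_h", "one_minus_h2"):
        raise ValueError("deduct must be 'one_minus_h' or 'one_minus_h2'")
    rng = np.random.default_rng(seed)
    observed = rows[variable].to_numpy(dtype=float)
    n = len(rows)

    ss_raw_acc = ss_ded_acc = ss_tot_acc = h_acc = 0.0
    for _ in range(n_iter):
        grid = rng.choice(observed, size=m, replace=True)
        prof = pd_profile(model, rows, variable, grid)
        h = friedman_h(prof)
        ss_raw = float(np.sum(prof.pd_centered**2))
        factor = (1.0 - h) if deduct == "one_minus_h" else (1.0 - h**2)
        ss_ded = ss_raw * factor
        f = prof.predictions - prof.predictions.mean()
        ss_tot = float(np.sum(f * f)) / n
        ss_raw_acc += ss_raw
        ss_ded_acc += ss_ded
        ss_tot_acc += ss_tot
        h_acc += h

    ss_raw = ss_raw_acc / n_iter
    ss_ded = ss_ded_acc / n_iter
    ss_tot = ss_tot_acc / n_iter
    h_mean = h_acc / n_iter
    effect = float(np.sqrt(ss_ded))
    percent = 100.0 * effect / float(np.sqrt(ss_tot)) if ss_tot > 0 else 0.0
    return EffectDecomposition(
        zone=zone, variable=variable, h=h_mean, ss_raw=ss_raw,
        ss_deducted=ss_ded, ss_total=ss_tot, effect_permil=effect,
        percent_of_total=percent, n_iterations=n_iter,
    )


def cumulative_comparison(
    decompositions: Sequence[EffectDecomposition],
    population_variable: str,
) -> pd.DataFrame:
    """Cumulative climate vs. demography effect table, one row per zone.

    Cumulative climate is the sum of the four climate variables'
    interaction-deducted per-mil effects (and of their percents), paired
    against the population covariate's effect.
    """
    rows = []
    zones = sorted({d.zone for d in decompositions})
    for zone in zones:
        dz = {d.variable: d for d in decompositions if d.zone == zone}
        missing = [v for v in (*CLIMATE_SET, population_variable)
                   if v not in dz]
        if missing:
            raise ValueError(f"zone {zone!r}: missing decompositions {missing}")
        clim_permil = sum(dz[v].effect_permil for v in CLIMATE_SET)
        clim_pct = sum(dz[v].percent_of_total for v in CLIMATE_SET)
        demo = dz[population_variable]
        rows.append({
            "zone": zone,
            "cumulative_climate_permil": clim_permil,
            "cumulative_climate_percent": clim_pct,
            "demography_permil": demo.effect_permil,
            "demography_percent": demo.percent_of_total,
            "climate_over_demography": (
                clim_permil / demo.effect_permil if demo.effect_permil > 0
                else np.inf
            ),
        })
    return pd.DataFrame(rows)
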