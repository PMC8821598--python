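"""Monte-Carlo assignment of climate and population covariates to individuals.

Each individual's death year is uncertain: a cultural-period window for most,
a calibrated radiocarbon density for directly dated individuals.  Covariates
are therefore assigned as Monte-Carlo means: the window is resampled with
replacement (weighted by calibrated probability where available), each draw
is mapped to the nearest climate cell/time step or to a random KDE fit, and
the draws are averaged.  Also provides the per-cell climate z-score series
used to visualize regional climate deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import CalendarDensity, calibrate, restrict, CalibrationCurve
from .climate import CLIMATE_VARIABLES, ClimateFieldSet
from .demography import PopulationEnsemble
from .qc import Individual

__all__ = [
    "ExposureRecord",
    "ANALYSIS_SPAN",
    "window_sampler",
    "assign_climate",
    "assign_population",
    "build_exposures",
    "climate_zscores",
    "exposures_frame",
]

#: analysis span in yBP (young, old); simulation output ends at 140 yBP
ANALYSIS_SPAN = (140.0, 7000.0)


@dataclass
class ExposureRecord:
    """Per-individual Monte-Carlo mean covariates — one design row."""

    individual_id: str
    zone: str
    temp: float
    temp_seasonality: float
    precip: float
    precip_seasonality: float
    mean_kde_uncorrected: float
    mean_kde_corrected: float
    n_draws: int
    lat: float = np.nan
    lon: float = np.nan
    mean_death_year: float = np.nan


def _clamped_window(ind: Individual,
                    span: tuple[float, float] = ANALYSIS_SPAN) -> tuple[float, float]:
    lo = max(ind.date_min, span[0])
    hi = min(ind.date_max, span[1])
    if lo > hi:
        raise ValueError(
            f"individual {ind.id}: window [{ind.date_min}, {ind.date_max}] "
            f"lies outside the analysis span {span}"
        )
    if (lo, hi) != (ind.date_min, ind.date_max):
        warnings.warn(
            f"individual {ind.id}: window truncated to analysis span {span}",
            stacklevel=2,
        )
    return lo, hi


def window_sampler(
    ind: Individual,
    n_draws: int = 10_000,
    seed: int | np.random.Generator = 0,
    curve: CalibrationCurve | None = None,
    density: CalendarDensity | None = None,
) -> np.ndarray:
    """Draw possible death years for an individual, with replacement.

    Directly dated individuals are sampled from their calibrated density
    restricted to the date window; all others are sampled uniformly over
    whole years in [date_min, date_max].  The window is clamped to the
    analysis span.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = _clamped_window(ind)
    if ind.c14 is not None:
        if density is None:
            if curve is None:
                raise ValueError(
                    f"individual {ind.id} is directly dated; pass a curve or "
                    "a precomputed density"
                )
            density = calibrate(ind.c14, curve)
        d = restrict(density, lo, hi)
        idx = rng.choice(len(d.years), size=n_draws, replace=True, p=d.p)
        return d.years[idx]
    if lo == hi:
        return np.full(n_draws, lo)
    return rng.integers(int(np.ceil(lo)), int(np.floor(hi)) + 1,
                        size=n_draws).astype(float)


def assign_climate(
    ind: Individual, fields: ClimateFieldSet, years: np.ndarray
) -> dict[str, float]:
    """Mean of each climate variable over sampled years at the individual's
    location (nearest cell center, nearest time step per draw)."""
    ci = fields.nearest_cell(ind.lat, ind.lon)
    steps = np.array([fields.nearest_step(y) for y in np.asarray(years)])
    return {
        var: float(fields.values[var][ci, steps].mean())
        for var in CLIMATE_VARIABLES
    }


def assign_population(
    ind: Individual,
    ens: PopulationEnsemble,
    n_draws: int = 10_000,
    seed: int | np.random.Generator = 0,
    years: np.ndarray | None = None,
) -> float:
    """Monte-Carlo mean KDE value over the individual's window.

    Per draw: pick one of the ensemble fits uniformly at random, pick one
    window year (calibration-weighted when directly dated), and take that
    fit's density at that year.  Returns the mean of the draws.
    """
    rng = np.random.default_rng(seed)
    if years is None:
        years = window_sampler(ind, n_draws=n_draws, seed=rng)
    years = np.asarray(years, dtype=float)
    lo, hi = ens.years.min(), ens.years.max()
    if years.min() < lo - 1e-9 or years.max() > hi + 1e-9:
        raise ValueError(
            f"individual {ind.id}: window years outside ensemble grid "
            f"[{lo}, {hi}]"
        )
    fit_idx = rng.integers(0, ens.n_fits, size=len(years))
    year_idx = np.argmin(np.abs(ens.years[None, :] - years[:, None]), axis=1)
    return float(ens.fits[fit_idx, year_idx].mean())


def build_exposures(
    individuals: Sequence[Individual],
    fields: ClimateFieldSet,
    ensembles_uncorrected: dict[str, PopulationEnsemble],
    ensembles_corrected: dict[str, PopulationEnsemble],
    n_draws: int = 10_000,
    seed: int | np.random.Generator = 0,
    curve: CalibrationCurve | None = None,
) -> list[ExposureRecord]:
    """Assign all covariates to every individual (one seeded pass)."""
    master = np.random.default_rng(seed)
    records = []
    for ind in individuals:
        rng = np.random.default_rng(master.integers(2**31))
        years = window_sampler(ind, n_draws=n_draws, seed=rng, curve=curve)
        clim = assign_climate(ind, fields, years)
        zone = ind.zone
        kde_u = assign_population(ind, ensembles_uncorrected[zone],
                                  seed=rng, years=years)
        kde_c = assign_population(ind, ensembles_corrected[zone],
                                  seed=rng, years=years)
        records.append(ExposureRecord(
            individual_id=ind.id, zone=zone, n_draws=n_draws,
            mean_kde_uncorrected=kde_u, mean_kde_corrected=kde_c,
            lat=ind.lat, lon=ind.lon, mean_death_year=float(years.mean()),
            **clim,
        ))
    return records


def exposures_frame(records: Sequence[ExposureRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def climate_zscores(
    fields: ClimateFieldSet, smooth_window: int = 5
) -> dict[str, dict[str, np.ndarray]]:
    """Per-cell z-score series of climate deviation from the cell mean.

    Returns, per variable: ``z`` (n_cells × n_steps) and ``central`` — the
    moving average (window ``smooth_window`` steps) of the cross-cell mean
    z-score.  Zero-variance cells yield z = 0 with a warning.
    """
    if len(fields.steps) < 2:
        raise ValueError("need at least two time steps for z-scores")
    out: dict[str, dict[str, np.ndarray]] = {}
    for var in CLIMATE_VARIABLES:
        vals = fields.values[var]
        mean = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, ddof=0, keepdims=True)
        zero = (sd == 0).ravel()
        if zero.any():
            warnings.warn(
                f"{var}: {zero.sum()} zero-variance cell(s); z set to 0",
                stacklevel=2,
            )
        safe_sd = np.where(sd == 0, 1.0, sd)
        z = (vals - mean) / safe_sd
        z[zero, :] = 0.0
        mean_z = z.mean(axis=0)
        central = (pd.Series(mean_z)
                   .rolling(smooth_window, center=True, min_periods=1)
                   .mean().to_numpy())
        out[var] = {"z": z, "central": central, "years": fields.steps.copy()}
    return out
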