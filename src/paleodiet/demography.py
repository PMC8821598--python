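"""Dates-as-data population proxies: composite KDE ensembles per zone.

The temporal frequency of archaeological radiocarbon dates is used as a
proxy for relative past population size.  Calibration uncertainty is carried
through by building an ensemble of kernel density estimates: each fit draws
one calendar year per date from its calibrated probability distribution.
Site-level overrepresentation is controlled by hierarchically clustering
each site's dates into bins and down-weighting dates from large bins.  An
optional taphonomic correction divides each fit by a power-law survival
curve for datable material.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .calibration import CalendarDensity, RadiocarbonMeasurement, sample_years

__all__ = [
    "DateBin",
    "DateQCReport",
    "PopulationEnsemble",
    "qc_dates",
    "bin_dates",
    "composite_kde",
    "taphonomic_correct",
    "default_grid",
    "write_ensemble",
    "read_ensemble",
    "SUROVELL_A",
    "SUROVELL_B",
    "SUROVELL_C",
]

# Global taphonomic-loss model for datable material:
# n(t) = A * (t + B) ** (-C), t in calendar years BP.
SUROVELL_A = 5_726_442.0
SUROVELL_B = 2176.4
SUROVELL_C = 1.3925309

MAX_AGE_BP = 15_000.0
MAX_ERROR = 200.0
DEFAULT_CUTOFF = 200.0


@dataclass
class DateBin:
    site_id: str
    members: list[str]

    @property
    def bin_size(self) -> int:
        return len(self.members)


@dataclass
class DateQCReport:
    input: int = 0
    dropped_old: int = 0
    dropped_error: int = 0
    dropped_no_coords: int = 0
    dropped_duplicate: int = 0
    retained: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class PopulationEnsemble:
    """Matrix of KDE fits (n_fits × n_years) for one elevation zone."""

    zone: str
    years: np.ndarray
    fits: np.ndarray
    corrected: bool = False
    bandwidth: float = 50.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=float)
        self.fits = np.atleast_2d(np.asarray(self.fits, dtype=float))
        if self.fits.shape[1] != len(self.years):
            raise ValueError("fits must be (n_fits, n_years)")
        if np.any(self.fits < 0):
            raise ValueError("densities must be non-negative")

    @property
    def n_fits(self) -> int:
        return self.fits.shape[0]

    def mean_fit(self) -> np.ndarray:
        return self.fits.mean(axis=0)

    def envelope(self, lo: float = 2.5, hi: float = 97.5) -> tuple[np.ndarray, np.ndarray]:
        return (np.percentile(self.fits, lo, axis=0),
                np.percentile(self.fits, hi, axis=0))

    def value_at(self, fit_index: int, year: float) -> float:
        """Density of one fit at the grid year nearest ``year``."""
        idx = int(np.argmin(np.abs(self.years - year)))
        return float(self.fits[fit_index, idx])


def qc_dates(
    dates: Sequence[RadiocarbonMeasurement],
    max_age: float = MAX_AGE_BP,
    max_error: float = MAX_ERROR,
    coord_exempt_sites: frozenset[str] | set[str] = frozenset(),
) -> tuple[list[RadiocarbonMeasurement], DateQCReport]:
    """Quality-control a radiocarbon date list.

    Drops, in order: duplicated lab ids (first kept), ages older than
    ``max_age``, errors above ``max_error``, and dates with missing
    coordinates — except dates from ``coord_exempt_sites``, kept because
    their source compilation is exclusively coastal and zone assignment does
    not need coordinates for them.
    """
    report = DateQCReport(input=len(dates))
    seen: set[str] = set()
    retained: list[RadiocarbonMeasurement] = []
    for d in dates:
        if d.lab_id in seen:
            report.dropped_duplicate += 1
            continue
        seen.add(d.lab_id)
        if d.age > max_age:
            report.dropped_old += 1
            continue
        if d.error > max_error:
            report.dropped_error += 1
            continue
        missing = np.isnan(d.lat) or np.isnan(d.lon)
        if missing and d.site_id not in coord_exempt_sites:
            report.dropped_no_coords += 1
            continue
        retained.append(d)
    report.retained = len(retained)
    return retained, report


def bin_dates(
    dates: Sequence[RadiocarbonMeasurement],
    median_years: Sequence[float],
    cutoff: float = DEFAULT_CUTOFF,
    method: str = "complete",
) -> list[DateBin]:
    """Cluster each site's dates into temporal bins.

    Agglomerative clustering (complete linkage by default) on the median
    calibrated year of each date, cutting the tree at ``cutoff`` years.
    Dates at different sites never share a bin.
    """
    if len(dates) != len(median_years):
        raise ValueError("dates and median_years must align")
    by_site: dict[str, list[int]] = {}
    for i, d in enumerate(dates):
        by_site.setdefault(d.site_id, []).append(i)

    bins: list[DateBin] = []
    med = np.asarray(median_years, dtype=float)
    for site, idxs in by_site.items():
        if len(idxs) == 1:
            bins.append(DateBin(site, [dates[idxs[0]].lab_id]))
            continue
        pts = med[idxs].reshape(-1, 1)
        labels = fcluster(linkage(pts, method=method), t=cutoff,
                          criterion="distance")
        for lab in np.unique(labels):
            members = [dates[idxs[j]].lab_id for j in np.where(labels == lab)[0]]
            bins.append(DateBin(site, members))
    return bins


def default_grid(year_max: float = 7000.0, year_min: float = 0.0,
                 step: float = 20.0) -> np.ndarray:
    """Calendar grid aligned with the climate time step (ascending yBP)."""
    return np.arange(year_min, year_max + 0.5 * step, step)


def composite_kde(
    dates: Sequence[RadiocarbonMeasurement],
    densities: Sequence[CalendarDensity],
    bins: Sequence[DateBin],
    zone: str = "",
    n_fits: int = 1000,
    bandwidth: float = 50.0,
    grid: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> PopulationEnsemble:
    """Build the composite KDE ensemble for one zone.

    Per fit: draw one calendar year per date from its calibrated density,
    weight each date by 1 / (size of its bin), and evaluate a Gaussian KDE
    with fixed ``bandwidth`` on the grid, renormalized to integrate to 1.
    """
    if len(dates) == 0:
        raise ValueError("composite_kde needs at least one date")
    if len(dates) != len(densities):
        raise ValueError("dates and densities must align")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)

    bin_size_of: dict[str, int] = {}
    for b in bins:
        for lab in b.members:
            bin_size_of[lab] = b.bin_size
    weights = np.array([1.0 / bin_size_of.get(d.lab_id, 1) for d in dates])
    weights = weights / weights.sum()

    # one vectorized draw matrix: (n_fits, n_dates)
    draws = np.empty((n_fits, len(dates)))
    for j, dens in enumerate(densities):
        draws[:, j] = sample_years(dens, n_fits, rng)

    fits = np.empty((n_fits, len(grid)))
    inv = 1.0 / (bandwidth * np.sqrt(2.0 * np.pi))
    for f in range(n_fits):
        z = (grid[:, None] - draws[f][None, :]) / bandwidth
        dens_vals = inv * np.exp(-0.5 * z * z) @ weights
        area = np.trapezoid(dens_vals, grid)
        fits[f] = dens_vals / area
    return PopulationEnsemble(
        zone=zone, years=grid, fits=fits, corrected=False, bandwidth=bandwidth,
        metadata={
            "n_fits": int(n_fits), "bandwidth": float(bandwidth),
            "linkage": "complete", "n_dates": len(dates),
        },
    )


def taphonomic_survival(t: np.ndarray | float) -> np.ndarray | float:
    """Expected surviving quantity of datable material of age ``t`` yBP."""
    return SUROVELL_A * np.power(np.asarray(t, dtype=float) + SUROVELL_B,
                                 -SUROVELL_C)


def taphonomic_correct(ens: PopulationEnsemble) -> PopulationEnsemble:
    """Divide each fit by the relative survival proportion and renormalize.

    The survival proportion is s(t) = n(t) / n(t_ref) with t_ref the
    youngest grid year, so the correction factor 1/s(t) grows with age.
    """
    if ens.corrected:
        raise ValueError("ensemble is already taphonomically corrected")
    t_ref = ens.years.min()
    s = taphonomic_survival(ens.years) / taphonomic_survival(t_ref)
    fits = ens.fits / s[None, :]
    areas = np.trapezoid(fits, ens.years, axis=1)
    fits = fits / areas[:, None]
    meta = dict(ens.metadata)
    meta["taphonomic_model"] = {"A": SUROVELL_A, "B": SUROVELL_B, "C": SUROVELL_C}
    return PopulationEnsemble(
        zone=ens.zone, years=ens.years, fits=fits, corrected=True,
        bandwidth=ens.bandwidth, metadata=meta,
    )


def write_ensemble(ens: PopulationEnsemble, csv_path, meta_path=None) -> None:
    df = pd.DataFrame(ens.fits, columns=[f"{y:.0f}" for y in ens.years])
    df.insert(0, "fit", np.arange(ens.n_fits))
    df.to_csv(csv_path, index=False)
    if meta_path is not None:
        meta = dict(ens.metadata)
        meta.update(zone=ens.zone, corrected=ens.corrected,
                    bandwidth=ens.bandwidth)
        with open(meta_path, "wt", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2)


def read_ensemble(csv_path, meta_path=None) -> PopulationEnsemble:
    df = pd.read_csv(csv_path)
    years = np.array([float(c) for c in df.columns if c != "fit"])
    fits = df.drop(columns=["fit"]).to_numpy()
    meta, zone, corrected, bandwidth = {}, "", False, 50.0
    if meta_path is not None:
        with open(meta_path, "rt", encoding="utf-8") as fh:
            meta = json.load(fh)
        zone = meta.pop("zone", "")
        corrected = meta.pop("corrected", False)
        bandwidth = meta.pop("bandwidth", 50.0)
    return PopulationEnsemble(zone=zone, years=years, fits=fits,
                              corrected=corrected, bandwidth=bandwidth,
                              metadata=meta)
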