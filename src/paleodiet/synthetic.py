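"""Synthetic inputs with known ground truth for the whole pipeline.

Generates every file the analysis consumes — a calibration curve, a gridded
climate time series, a radiocarbon date compilation, and an isotope table of
individuals — with a known data-generating process, so that downstream
stages (calibration, KDE demography, exposure assignment, trend and driver
models, effect decomposition) can be tested for parameter recovery without
any external data.

The individual response (isotope value) is additive in standardized climate
and population covariates plus one climate×climate interaction and Gaussian
noise; the variance share of each component is set directly, so the true
covariate ranking is known by construction.  No attempt is made to
reproduce real Andean climatology or real calibration curves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .calibration import CalibrationCurve, RadiocarbonMeasurement
from .climate import CLIMATE_VARIABLES, ClimateFieldSet
from .demography import PopulationEnsemble
from .qc import Individual, ZONES

__all__ = [
    "GroundTruth",
    "SyntheticBundle",
    "make_calibration_curve",
    "simulate_climate_fields",
    "simulate_dates",
    "simulate_individuals",
    "two_bump_curve",
    "make_bundle",
    "write_bundle",
]

#: default variance shares of the isotope response (must sum to 1):
#: climate carries 0.75 of the variance (0.70 additive + 0.05 temp×precip
#: interaction), population 0.10, unexplained noise 0.15; precipitation
#: seasonality is deliberately irrelevant so attribution methods can be
#: checked against a known null.
DEFAULT_SHARES = {
    "temp": 0.25,
    "temp_seasonality": 0.15,
    "precip": 0.30,
    "precip_seasonality": 0.0,
    "interaction": 0.05,
    "population": 0.10,
    "noise": 0.15,
}


@dataclass
class GroundTruth:
    """Known data-generating process for the isotope response.

    ``effect_shares`` maps each component (the four climate variables, one
    climate×climate ``interaction``, ``population``, ``noise``) to its
    intended fraction of the response variance; components are empirically
    standardized before weighting, so sample variance shares match the
    requested shares by construction.  ``intercept`` and ``total_sd`` set
    the per-mil location and scale of the response.
    """

    effect_shares: dict = field(default_factory=lambda: dict(DEFAULT_SHARES))
    interaction_pair: tuple[str, str] = ("temp", "precip")
    intercept: float = 10.0
    total_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for key, share in self.effect_shares.items():
            if share < 0:
                raise ValueError(f"effect share {key!r} is negative")
        total = sum(self.effect_shares.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"effect shares must sum to 1, got {total}")

    @property
    def noise_sd(self) -> float:
        return self.total_sd * float(np.sqrt(self.effect_shares.get("noise", 0.0)))

    @property
    def climate_share(self) -> float:
        return sum(self.effect_shares.get(v, 0.0) for v in CLIMATE_VARIABLES) \
            + self.effect_shares.get("interaction", 0.0)

    def response(self, covariates: dict[str, np.ndarray],
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """(noiseless signal, noisy response) from true covariate arrays."""

        def z(a: np.ndarray) -> np.ndarray:
            a = np.asarray(a, dtype=float)
            sd = a.std(ddof=0)
            return (a - a.mean()) / sd if sd > 0 else np.zeros_like(a)

        n = len(next(iter(covariates.values())))
        signal = np.zeros(n)
        for var in (*CLIMATE_VARIABLES, "population"):
            share = self.effect_shares.get(var, 0.0)
            if share > 0:
                signal = signal + np.sqrt(share) * z(covariates[var])
        s_int = self.effect_shares.get("interaction", 0.0)
        if s_int > 0:
            a, b = self.interaction_pair
            signal = signal + np.sqrt(s_int) * z(z(covariates[a]) * z(covariates[b]))
        signal = self.intercept + self.total_sd * signal
        s_noise = self.effect_shares.get("noise", 0.0)
        noise = (self.total_sd * np.sqrt(s_noise) * rng.standard_normal(n)
                 if s_noise > 0 else np.zeros(n))
        return signal, signal + noise


@dataclass
class SyntheticBundle:
    individuals: list[Individual]
    dates: list[RadiocarbonMeasurement]
    curve: CalibrationCurve
    climate: ClimateFieldSet
    truth: GroundTruth
    ensembles: dict[str, PopulationEnsemble] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# calibration curve

def make_calibration_curve(
    year_min: float,
    year_max: float,
    wiggle_amplitude: float = 30.0,
    seed: int = 0,
    step: float = 5.0,
    base_sigma: float = 10.0,
) -> CalibrationCurve:
    """Synthetic calibration curve: identity plus a smooth bounded wiggle.

    The curve mean is calBP plus a smooth zero-mean perturbation with
    standard deviation ``wiggle_amplitude``, clipped to ±3 amplitudes so the
    curve never strays far from the identity.  ``wiggle_amplitude = 0``
    yields the exact identity curve μ(t) = t.
    """
    if year_min >= year_max:
        raise ValueError("year_min must be < year_max")
    if wiggle_amplitude < 0:
        raise ValueError("wiggle_amplitude must be >= 0")
    cal = np.arange(year_min, year_max + 0.5 * step, step)
    mu = cal.astype(float).copy()
    if wiggle_amplitude > 0:
        rng = np.random.default_rng(seed)
        raw = gaussian_filter1d(rng.standard_normal(len(cal)), sigma=8.0,
                                mode="reflect")
        raw = raw - raw.mean()
        sd = raw.std(ddof=0)
        if sd > 0:
            wig = raw / sd * wiggle_amplitude
            wig = np.clip(wig, -3.0 * wiggle_amplitude, 3.0 * wiggle_amplitude)
            mu = mu + wig
    sigma = np.full(len(cal), float(base_sigma))
    return CalibrationCurve(cal, mu, sigma, name=f"synthetic-{seed}")


# ---------------------------------------------------------------------------
# climate fields

#: per variable: (cell mean, temporal sd, spatial sd, lat gradient, lon gradient)
#: gradients are deliberately different across variables (temperature falls
#: with latitude, seasonality varies mostly with longitude, ...) so the four
#: fields are distinguishable rather than collinear through a shared gradient
_CLIMATE_LEVELS = {
    "temp": (14.0, 0.8, 1.2, -0.3, 0.0),
    "temp_seasonality": (150.0, 30.0, 40.0, 0.0, 3.0),
    "precip": (2.0, 0.4, 0.6, 0.05, -0.04),
    "precip_seasonality": (80.0, 18.0, 25.0, 0.0, 0.0),
}


def simulate_climate_fields(
    lats: Sequence[float],
    lons: Sequence[float],
    year_range: tuple[float, float] = (140.0, 7000.0),
    step: float = 20.0,
    ar_coef: float = 0.7,
    seed: int = 0,
    sd_scale: float = 1.0,
) -> ClimateFieldSet:
    """AR(1) climate series per cell with smooth spatial gradients.

    ``lats``/``lons`` are the axes of a regular grid (cells are their outer
    product).  Each cell's series for each variable is a stationary AR(1)
    around a cell mean that varies with latitude plus a small random cell
    offset; precipitation variables are clipped at zero.  ``sd_scale = 0``
    gives constant-forcing (flat) series.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if len(lats) == 0 or len(lons) == 0:
        raise ValueError("climate grid must be non-empty")
    lo, hi = year_range
    steps = np.arange(lo, hi + 0.5 * step, step)
    lat_grid, lon_grid = np.meshgrid(lats, lons, indexing="ij")
    cell_lats = lat_grid.ravel()
    cell_lons = lon_grid.ravel()
    n_cells, n_steps = len(cell_lats), len(steps)
    rng = np.random.default_rng(seed)

    # random cell anomalies, made mutually orthogonal across variables so
    # that cross-variable correlation in a finite grid reflects only the
    # designed gradients, not chance alignment of the anomaly draws
    n_vars = len(_CLIMATE_LEVELS)
    anomalies = rng.standard_normal((n_cells, n_vars))
    if n_cells >= n_vars:
        anomalies, _ = np.linalg.qr(anomalies)
        anomalies *= np.sqrt(n_cells)  # back to unit variance per column

    values: dict[str, np.ndarray] = {}
    for vi, (var, (base, stat_sd, spat_sd, glat, glon)) in \
            enumerate(_CLIMATE_LEVELS.items()):
        stat_sd = stat_sd * sd_scale
        spat_sd = spat_sd * sd_scale
        cell_mean = (base
                     + glat * (cell_lats - cell_lats.mean())
                     + glon * (cell_lons - cell_lons.mean())
                     + spat_sd * anomalies[:, vi])
        innov_sd = stat_sd * np.sqrt(max(1.0 - ar_coef**2, 0.0))
        series = np.empty((n_cells, n_steps))
        series[:, 0] = stat_sd * rng.standard_normal(n_cells)
        eps = innov_sd * rng.standard_normal((n_cells, n_steps))
        for t in range(1, n_steps):
            series[:, t] = ar_coef * series[:, t - 1] + eps[:, t]
        vals = cell_mean[:, None] + series
        if var.startswith("precip"):
            vals = np.maximum(vals, 0.0)
        values[var] = vals

    return ClimateFieldSet(
        cell_ids=np.array([f"c{i:03d}" for i in range(n_cells)]),
        lats=cell_lats, lons=cell_lons, steps=steps, values=values,
    )


# ---------------------------------------------------------------------------
# radiocarbon dates

def two_bump_curve(
    years: np.ndarray, centers=(2000.0, 5000.0), widths=(400.0, 600.0),
    weights=(0.6, 0.4),
) -> np.ndarray:
    """A two-bump population density on a year grid (unnormalized)."""
    years = np.asarray(years, dtype=float)
    dens = np.zeros_like(years)
    for c, w, a in zip(centers, widths, weights):
        dens += a * np.exp(-0.5 * ((years - c) / w) ** 2)
    return dens


def simulate_dates(
    pop_curve: tuple[np.ndarray, np.ndarray],
    n: int,
    curve: CalibrationCurve,
    error_sd: float = 20.0,
    seed: int = 0,
    zone: str = "mid-elevation",
    site_concentration: float = 1.3,
    n_sites: int | None = None,
    lat_range: tuple[float, float] = (-16.0, -6.0),
    lon_range: tuple[float, float] = (-78.0, -69.0),
    duplicate_fraction: float = 0.02,
    big_error_fraction: float = 0.015,
    missing_coord_fraction: float = 0.01,
) -> list[RadiocarbonMeasurement]:
    """Draw a synthetic date compilation from a known population curve.

    Calendar death years are drawn proportional to ``pop_curve`` (a
    (years, density) pair), converted to ¹⁴C ages through the curve mean
    with Gaussian noise of sd ``error_sd``.  Site ids follow a heavy-tailed
    size distribution so some sites carry many dates (exercising the
    binning).  The reported lab error equals ``error_sd`` (floored at 1 yr
    so measurements stay valid when noiseless).  Small fractions of the
    compilation are flawed the way real ones are — duplicated lab ids,
    oversized errors, missing coordinates — so quality control has work to
    do; the flawed records are appended after the ``n`` clean ones.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    years_grid, dens = pop_curve
    years_grid = np.asarray(years_grid, dtype=float)
    dens = np.asarray(dens, dtype=float)
    if np.any(dens < 0) or dens.sum() <= 0:
        raise ValueError("pop_curve must be non-negative with positive mass")
    rng = np.random.default_rng(seed)
    p = dens / dens.sum()
    true_years = years_grid[rng.choice(len(years_grid), size=n, p=p)]

    mu, _ = curve.interpolate(true_years)
    ages = mu + (error_sd * rng.standard_normal(n) if error_sd > 0 else 0.0)

    if n_sites is None:
        n_sites = max(3, n // 8)
    # heavy-tailed site sizes via a power-law weight per site
    site_w = (np.arange(1, n_sites + 1, dtype=float)) ** (-site_concentration)
    site_w /= site_w.sum()
    site_idx = rng.choice(n_sites, size=n, p=site_w)
    site_lat = rng.uniform(*lat_range, size=n_sites)
    site_lon = rng.uniform(*lon_range, size=n_sites)

    elev = {"coastal": 100.0, "mid-elevation": 1800.0, "highland": 3900.0}[zone]
    out = []
    for i in range(n):
        s = site_idx[i]
        out.append(RadiocarbonMeasurement(
            lab_id=f"{zone[:4]}-{seed}-{i:05d}", age=float(ages[i]),
            error=max(float(error_sd), 1.0), marine=False,
            site_id=f"site-{zone[:4]}-{s:03d}",
            lat=float(site_lat[s]), lon=float(site_lon[s]), elevation=elev,
        ))

    def _flawed(count: int, **overrides) -> None:
        for _ in range(count):
            src = out[int(rng.integers(0, n))]
            fields = dict(
                lab_id=src.lab_id, age=src.age, error=src.error,
                marine=src.marine, site_id=src.site_id, lat=src.lat,
                lon=src.lon, elevation=src.elevation)
            fields.update(overrides)
            out.append(RadiocarbonMeasurement(**fields))

    _flawed(int(round(duplicate_fraction * n)))  # exact lab-id duplicates
    k = int(round(big_error_fraction * n))
    for j in range(k):
        src = out[int(rng.integers(0, n))]
        out.append(RadiocarbonMeasurement(
            lab_id=f"{zone[:4]}-{seed}-err{j:03d}", age=src.age,
            error=float(rng.uniform(210.0, 400.0)), site_id=src.site_id,
            lat=src.lat, lon=src.lon, elevation=src.elevation))
    k = int(round(missing_coord_fraction * n))
    for j in range(k):
        src = out[int(rng.integers(0, n))]
        out.append(RadiocarbonMeasurement(
            lab_id=f"{zone[:4]}-{seed}-nc{j:03d}", age=src.age,
            error=src.error, site_id=src.site_id,
            lat=float("nan"), lon=float("nan"), elevation=src.elevation))
    return out


# ---------------------------------------------------------------------------
# individuals

_ZONE_GEOMETRY = {
    # (elev_lo, elev_hi, dist_lo, dist_hi)
    "coastal": (5.0, 340.0, 0.5, 14.0),
    "mid-elevation": (400.0, 3400.0, 20.0, 250.0),
    "highland": (3550.0, 4600.0, 60.0, 400.0),
}


def simulate_individuals(
    n: int,
    climate: ClimateFieldSet,
    ensembles: dict[str, PopulationEnsemble],
    truth: GroundTruth,
    window_width: float = 200.0,
    seed: int = 0,
    dated_fraction: float = 0.09,
    curve: CalibrationCurve | None = None,
    c14_error: float = 25.0,
    zone_weights: dict[str, float] | None = None,
    span: tuple[float, float] = (140.0, 7000.0),
    underage_fraction: float = 0.03,
    bad_cn_fraction: float = 0.05,
    colonial_fraction: float = 0.012,
) -> list[Individual]:
    """Generate individuals whose isotope values follow the ground truth.

    Each individual receives a true death year (uniform over the analysis
    span), a location in one of the three elevation zones, a date window of
    width ``window_width`` containing the true year, and δ¹⁵N/δ¹³C values
    equal to the ground-truth response of the true local climate and zone
    population at that year plus noise.  A ``dated_fraction`` of individuals
    carry a direct ¹⁴C measurement consistent with their true year.  True
    covariates are recorded in each individual's ``truth`` dict.
    """
    if window_width < 0:
        raise ValueError("window_width must be >= 0")
    for zone in ZONES:
        if zone not in ensembles:
            raise ValueError(f"missing population ensemble for zone {zone!r}")
    rng = np.random.default_rng(seed)
    if zone_weights is None:
        zone_weights = {z: 1.0 for z in ZONES}
    zw = np.array([zone_weights[z] for z in ZONES], dtype=float)
    zw /= zw.sum()
    zones = np.array(ZONES)[rng.choice(3, size=n, p=zw)]

    lo, hi = span
    margin = min(window_width, (hi - lo) / 4)
    true_years = rng.uniform(lo + margin, hi - margin, size=n)

    lats = rng.uniform(climate.lats.min(), climate.lats.max(), size=n)
    lons = rng.uniform(climate.lons.min(), climate.lons.max(), size=n)

    covs = {v: np.empty(n) for v in CLIMATE_VARIABLES}
    pop = np.empty(n)
    for i in range(n):
        local = climate.at(lats[i], lons[i], true_years[i])
        for v in CLIMATE_VARIABLES:
            covs[v][i] = local[v]
        ens = ensembles[zones[i]]
        idx = int(np.argmin(np.abs(ens.years - true_years[i])))
        pop[i] = ens.mean_fit()[idx]
    covs["population"] = pop

    rng_n = np.random.default_rng(rng.integers(2**31))
    rng_c = np.random.default_rng(rng.integers(2**31))
    _, d15n = truth.response(covs, rng_n)
    signal_c, _ = truth.response(covs, rng_c)
    d13c = (signal_c - truth.intercept) - 12.0 \
        + truth.noise_sd * rng_c.standard_normal(n)

    n_dated = int(round(dated_fraction * n))
    dated = np.zeros(n, dtype=bool)
    if n_dated > 0:
        if curve is None:
            raise ValueError("dated_fraction > 0 requires a calibration curve")
        dated[rng.choice(n, size=n_dated, replace=False)] = True

    out: list[Individual] = []
    for i in range(n):
        elo, ehi, dlo, dhi = _ZONE_GEOMETRY[zones[i]]
        elevation = rng.uniform(elo, ehi)
        dist = rng.uniform(dlo, dhi)
        # place the window around the true year, clamped to the span
        off = rng.uniform(0.0, window_width)
        wlo = np.clip(true_years[i] - off, lo, hi - window_width) \
            if window_width > 0 else true_years[i]
        whi = wlo + window_width
        c14 = None
        if dated[i]:
            mu, _ = curve.interpolate(np.array([true_years[i]]))
            c14 = RadiocarbonMeasurement(
                lab_id=f"ind-{seed}-{i:05d}",
                age=float(mu[0] + c14_error * rng.standard_normal()),
                error=c14_error, site_id=f"isite-{i % 40:03d}",
                lat=float(lats[i]), lon=float(lons[i]), elevation=elevation,
            )
        # a small fraction of records fail the inclusion rules, mirroring the
        # ~10% loss real compilations see at quality control
        cn_ratio = float(np.clip(rng.normal(3.2, 0.12), 2.95, 3.55))
        age_years = float(rng.uniform(18, 60))
        period = "Prehispanic"
        author_accepted = False
        u = rng.uniform()
        if u < underage_fraction:
            age_years = float(rng.uniform(0.5, 4.5))
        elif u < underage_fraction + bad_cn_fraction:
            cn_ratio = float(rng.uniform(2.3, 2.85))
            author_accepted = bool(rng.uniform() < 0.3)  # some overridden
        elif u < underage_fraction + bad_cn_fraction + colonial_fraction:
            period = "Colonial"
        out.append(Individual(
            id=f"I{seed}-{i:05d}", site_id=f"isite-{i % 40:03d}",
            lat=float(lats[i]), lon=float(lons[i]),
            elevation=float(elevation), dist_coast=float(dist),
            d13C=float(d13c[i]), d15N=float(d15n[i]),
            cn_ratio=cn_ratio, author_accepted=author_accepted,
            age_years=age_years, period=period,
            date_min=float(wlo), date_max=float(whi), c14=c14,
            truth={
                "year": float(true_years[i]),
                **{v: float(covs[v][i]) for v in CLIMATE_VARIABLES},
                "population": float(pop[i]),
            },
        ))
    return out


# ---------------------------------------------------------------------------
# convenience bundle

def make_bundle(
    seed: int = 0,
    n_individuals: int = 500,
    n_dates_per_zone: int = 300,
    n_fits: int = 200,
    bandwidth: float = 50.0,
    window_width: float = 200.0,
    truth: GroundTruth | None = None,
    # 2.5-degree grid spanning a Central-Andes-sized study area (30 cells)
    lats: Sequence[float] = (-18.75, -16.25, -13.75, -11.25, -8.75, -6.25),
    lons: Sequence[float] = (-80.0, -77.5, -75.0, -72.5, -70.0),
    error_sd: float = 20.0,
    date_qc: bool = True,
) -> SyntheticBundle:
    """Build a complete, internally consistent synthetic study.

    Runs the real calibration and KDE machinery on the simulated date
    compilation (per zone), then generates individuals whose isotope values
    are a known function of the simulated climate and the KDE population
    proxy.
    """
    from . import demography as dm
    from .calibration import calibrate
    from .calibration import density_median as dm_median

    rng = np.random.default_rng(seed)
    truth = truth or GroundTruth(seed=seed)
    curve = make_calibration_curve(0.0, 7600.0, wiggle_amplitude=25.0,
                                   seed=int(rng.integers(2**31)))
    climate = simulate_climate_fields(lats, lons,
                                      seed=int(rng.integers(2**31)))

    grid = dm.default_grid(7400.0, 0.0, 20.0)
    dates: list[RadiocarbonMeasurement] = []
    ensembles: dict[str, PopulationEnsemble] = {}
    for zone in ZONES:
        zdates = simulate_dates(
            (grid, two_bump_curve(grid)), n_dates_per_zone, curve,
            error_sd=error_sd, seed=int(rng.integers(2**31)), zone=zone,
        )
        dates.extend(zdates)
        if date_qc:
            zdates, _ = dm.qc_dates(zdates)
        densities = [calibrate(d, curve) for d in zdates]
        medians = [dm_median(c) for c in densities]
        bins = dm.bin_dates(zdates, medians)
        ensembles[zone] = dm.composite_kde(
            zdates, densities, bins, zone=zone, n_fits=n_fits,
            bandwidth=bandwidth, grid=grid, seed=int(rng.integers(2**31)),
        )

    individuals = simulate_individuals(
        n_individuals, climate, ensembles, truth,
        window_width=window_width, seed=int(rng.integers(2**31)),
        curve=curve,
    )
    return SyntheticBundle(individuals=individuals, dates=dates, curve=curve,
                           climate=climate, truth=truth, ensembles=ensembles)


def write_bundle(bundle: SyntheticBundle, out_dir) -> dict[str, str]:
    """Write all bundle inputs as plain-text files; returns the path map."""
    import os

    from .calibration import write_curve, write_dates
    from .climate import write_climate
    from .qc import write_individuals

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "individuals": os.path.join(out_dir, "individuals.csv"),
        "dates": os.path.join(out_dir, "dates.csv"),
        "curve": os.path.join(out_dir, "curve.14c"),
        "climate": os.path.join(out_dir, "climate_long.csv"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    write_individuals(bundle.individuals, paths["individuals"])
    write_dates(bundle.dates, paths["dates"])
    write_curve(bundle.curve, paths["curve"])
    write_climate(bundle.climate, paths["climate"])
    truth = asdict(bundle.truth)
    truth["interaction_pair"] = list(truth["interaction_pair"])
    with open(paths["truth"], "wt", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2)
    return paths
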