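"""Radiocarbon calibration against a user-supplied curve.

A radiocarbon measurement (conventional ¹⁴C age ± 1σ) is converted into a
probability mass function over calendar years BP by evaluating, for every
year on a calendar grid, the Gaussian likelihood of the (reservoir-adjusted)
measurement against the curve mean, with the measurement error, the curve
error and the reservoir-offset error added in quadrature.  Marine samples
carry a local reservoir offset ΔR ± σ(ΔR) that is subtracted from the
measured age before comparison.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "RadiocarbonMeasurement",
    "CalibrationCurve",
    "CalendarDensity",
    "read_curve",
    "write_curve",
    "calibrate",
    "sample_years",
    "density_median",
]

#: masses below this fraction of the peak are trimmed from a density support
TRIM_FLOOR = 1e-5


@dataclass(frozen=True)
class RadiocarbonMeasurement:
    """One laboratory ¹⁴C determination.

    ``delta_r``/``delta_r_error`` are the local marine reservoir offset and
    its 1σ error; they are ignored unless ``marine`` is set.
    """

    lab_id: str
    age: float            # conventional 14C yr BP
    error: float          # 1 sigma, 14C yr
    marine: bool = False
    delta_r: float = 0.0
    delta_r_error: float = 0.0
    site_id: str = ""
    lat: float = np.nan
    lon: float = np.nan
    elevation: float = np.nan

    def __post_init__(self) -> None:
        if not self.error > 0:
            raise ValueError(f"measurement error must be positive, got {self.error}")


@dataclass
class CalibrationCurve:
    """Calibration curve on an ascending calendar grid (cal yr BP)."""

    cal_bp: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    name: str = "curve"

    def __post_init__(self) -> None:
        self.cal_bp = np.asarray(self.cal_bp, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.cal_bp) == len(self.mu) == len(self.sigma)):
            raise ValueError("cal_bp, mu and sigma must have equal length")
        if np.any(np.diff(self.cal_bp) <= 0):
            raise ValueError("cal_bp grid must be strictly increasing")
        if np.any(self.sigma <= 0):
            raise ValueError("curve sigma must be positive everywhere")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.cal_bp[0]), float(self.cal_bp[-1])

    def interpolate(self, years: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Linear interpolation of (mu, sigma) onto arbitrary calendar years."""
        years = np.asarray(years, dtype=float)
        return (
            np.interp(years, self.cal_bp, self.mu),
            np.interp(years, self.cal_bp, self.sigma),
        )


@dataclass
class CalendarDensity:
    """Normalized probability mass over calendar years BP."""

    years: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if len(self.years) != len(self.p):
            raise ValueError("years and p must have equal length")
        if np.any(self.p < 0):
            raise ValueError("probability masses must be non-negative")
        total = self.p.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"probability masses must sum to 1, got {total}")


def read_curve(path, name: str | None = None) -> CalibrationCurve:
    """Read a 3-column calibration curve file (calBP, ¹⁴C age, 1σ).

    Accepts both comma- and whitespace-separated rows; lines starting with
    ``#`` are comments.  Rows may be in either calendar order; the curve is
    sorted ascending in calBP.
    """
    rows = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 3:
                raise ValueError(f"curve row needs 3 columns: {line!r}")
            rows.append([float(parts[0]), float(parts[1]), float(parts[2])])
    if not rows:
        raise ValueError(f"no data rows in curve file {path}")
    arr = np.array(rows, dtype=float)
    arr = arr[np.argsort(arr[:, 0])]
    return CalibrationCurve(arr[:, 0], arr[:, 1], arr[:, 2],
                            name=name or str(path))


def write_curve(curve: CalibrationCurve, path) -> None:
    """Write a curve in the comma-separated 3-column dialect."""
    buf = io.StringIO()
    buf.write(f"# {curve.name}\n# cal BP, 14C age BP, 1-sigma error\n")
    for t, m, s in zip(curve.cal_bp, curve.mu, curve.sigma):
        buf.write(f"{t:.1f},{m:.2f},{s:.2f}\n")
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def calibrate(
    m: RadiocarbonMeasurement,
    curve: CalibrationCurve,
    grid_step: float = 1.0,
    trim_floor: float = TRIM_FLOOR,
) -> CalendarDensity:
    """Calibrate a measurement to a calendar-year probability mass function.

    For each year ``t`` on a ``grid_step``-spaced calendar grid across the
    curve span, the unnormalized weight is the normal density of the
    reservoir-adjusted age at mean ``mu(t)`` and standard deviation
    ``sqrt(error² + sigma(t)² + delta_r_error²)``.  Weights are normalized to
    sum to 1, masses below ``trim_floor`` times the peak are trimmed, and the
    result is renormalized.
    """
    lo, hi = curve.span
    years = np.arange(lo, hi + 0.5 * grid_step, grid_step)
    mu, sig = curve.interpolate(years)

    age = m.age
    var_extra = 0.0
    if m.marine:
        age = age - m.delta_r
        var_extra = m.delta_r_error**2
    sd = np.sqrt(m.error**2 + sig**2 + var_extra)

    reach = 6.0  # a measurement further than 6 combined sigmas from the
    # curve everywhere is unreachable within the span
    if np.all(np.abs(age - mu) > reach * sd):
        raise ValueError(
            f"age {m.age} (adjusted {age}) is unreachable within curve span "
            f"{lo}-{hi} calBP (curve 14C range {mu.min():.0f}-{mu.max():.0f})"
        )

    z = (age - mu) / sd
    w = np.exp(-0.5 * z * z) / sd
    total = w.sum()
    if total <= 0:
        raise ValueError("calibration produced zero total mass")
    p = w / total

    keep = p >= trim_floor * p.max()
    years, p = years[keep], p[keep]
    p = p / p.sum()
    return CalendarDensity(years, p)


def sample_years(
    d: CalendarDensity, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. calendar years (with replacement) from a density."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(d.years), size=n, replace=True, p=d.p)
    return d.years[idx]


def density_median(d: CalendarDensity) -> float:
    """Smallest grid year whose cumulative mass reaches 0.5."""
    cum = np.cumsum(d.p)
    return float(d.years[int(np.searchsorted(cum, 0.5))])


def write_dates(dates: Sequence[RadiocarbonMeasurement], path) -> None:
    """Write a radiocarbon date table (one row per lab determination)."""
    import pandas as pd

    pd.DataFrame([{
        "lab_id": d.lab_id, "site_id": d.site_id, "lat": d.lat, "lon": d.lon,
        "elevation": d.elevation, "age": d.age, "error": d.error,
        "marine": d.marine, "delta_r": d.delta_r,
        "delta_r_error": d.delta_r_error,
    } for d in dates]).to_csv(path, index=False)


def read_dates(path) -> list[RadiocarbonMeasurement]:
    import pandas as pd

    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        out.append(RadiocarbonMeasurement(
            lab_id=str(r["lab_id"]), site_id=str(r["site_id"]),
            lat=float(r["lat"]), lon=float(r["lon"]),
            elevation=float(r["elevation"]), age=float(r["age"]),
            error=float(r["error"]), marine=bool(r["marine"]),
            delta_r=float(r["delta_r"]),
            delta_r_error=float(r["delta_r_error"]),
        ))
    return out


def restrict(d: CalendarDensity, year_min: float, year_max: float) -> CalendarDensity:
    """Restrict a density to a calendar window [year_min, year_max] and
    renormalize.  Raises if the window carries no mass."""
    mask = (d.years >= year_min) & (d.years <= year_max)
    mass = d.p[mask].sum()
    if mass <= 0:
        raise ValueError(
            f"calibrated density has zero mass inside window "
            f"[{year_min}, {year_max}] yBP"
        )
    return CalendarDensity(d.years[mask], d.p[mask] / mass)
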