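"""Individual-level data model, inclusion filters, and elevation zoning.

Individuals are skeletal samples with bone-collagen δ¹³C/δ¹⁵N values.  The
inclusion rules are: drop known under-fives (weaning signal), drop samples
whose collagen C:N ratio falls outside the reliable range without an author
override, and drop Colonial-period individuals.  Elevation zones follow the
Andean natural-zone thresholds: coastal below 350 masl within 15 km of the
coast, highland above 3500 masl, mid-elevation otherwise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import RadiocarbonMeasurement

__all__ = [
    "Individual",
    "QCReport",
    "classify_zone",
    "parse_age",
    "distance_to_coast",
    "cn_acceptable",
    "qc_filter",
    "read_individuals",
    "write_individuals",
    "ZONES",
]

ZONES = ("coastal", "mid-elevation", "highland")

CN_LO, CN_HI = 2.9, 3.6
COASTAL_ELEV, COASTAL_DIST, HIGHLAND_ELEV = 350.0, 15.0, 3500.0
MIN_AGE_YEARS = 5.0


@dataclass
class Individual:
    """One skeletal individual with isotope values and chronological window.

    ``date_min``/``date_max`` are the younger/older bounds of the possible
    death window in calendar yBP (so ``date_min <= date_max``).  ``age_years``
    is the minimum estimated age at death; None means unknown (retained by
    the filters, since exclusion requires evidence of being under five).
    """

    id: str
    site_id: str
    lat: float
    lon: float
    elevation: float
    dist_coast: float
    d13C: Optional[float] = None
    d15N: Optional[float] = None
    cn_ratio: Optional[float] = None
    author_accepted: bool = False
    study_validated: bool = False
    age_years: Optional[float] = None
    period: str = ""
    date_min: float = 0.0
    date_max: float = 0.0
    c14: Optional[RadiocarbonMeasurement] = None
    # ground-truth fields populated by the synthetic generator only
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.d13C is None and self.d15N is None:
            raise ValueError(f"individual {self.id}: needs d13C or d15N")
        if self.elevation < 0:
            raise ValueError(f"individual {self.id}: negative elevation")
        if self.date_min > self.date_max:
            raise ValueError(f"individual {self.id}: empty date window")

    @property
    def zone(self) -> str:
        return classify_zone(self.elevation, self.dist_coast)


@dataclass
class QCReport:
    input: int = 0
    dropped_age: int = 0
    dropped_cn: int = 0
    dropped_colonial: int = 0
    retained: int = 0
    retained_d15N: int = 0
    retained_d13C: int = 0
    no_cn_included: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def check(self) -> None:
        assert self.input == (
            self.retained + self.dropped_age + self.dropped_cn + self.dropped_colonial
        )


#: minimum age in years implied by common categorical age classes
_AGE_CLASSES = {
    "infant": 0.0, "child": 3.0, "juvenile": 5.0, "subadult": 5.0,
    "adolescent": 12.0, "adult": 18.0, "middle adult": 35.0,
    "old adult": 50.0,
}


def parse_age(value) -> Optional[float]:
    """Minimum age in years from a numeric value or a categorical label.

    Categorical classes map to their minimum plausible age (so only classes
    that guarantee an age under five trigger the weaning filter); unknown
    labels and missing values return None (retained by the filters).
    """
    if value is None:
        return None
    try:
        if pd.isna(value):
            return None
    except (TypeError, ValueError):
        pass
    try:
        return float(value)
    except (TypeError, ValueError):
        return _AGE_CLASSES.get(str(value).strip().lower())


def distance_to_coast(lat: float, lon: float,
                      coastline: Sequence[tuple[float, float]],
                      n_interp: int = 20) -> float:
    """Great-circle distance (km) from a point to a coastline polyline.

    The polyline is a sequence of (lat, lon) vertices; each segment is
    densified with ``n_interp`` intermediate points before taking the
    minimum haversine distance.  A convenience for datasets that lack a
    precomputed distance column.
    """
    from .forest import great_circle_km

    pts = np.asarray(coastline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 1 or pts.shape[1] != 2:
        raise ValueError("coastline must be a sequence of (lat, lon) pairs")
    if len(pts) > 1:
        segs = []
        for a, b in zip(pts[:-1], pts[1:]):
            t = np.linspace(0.0, 1.0, n_interp + 2)[:, None]
            segs.append(a[None, :] * (1 - t) + b[None, :] * t)
        pts = np.vstack(segs)
    return float(np.min(great_circle_km(lat, lon, pts[:, 0], pts[:, 1])))


def classify_zone(elevation: float, dist_coast: float) -> str:
    """Elevation zone for a location.

    coastal iff elevation < 350 masl and distance-to-coast < 15 km;
    highland iff elevation > 3500 masl; mid-elevation otherwise.  Boundary
    values (exactly 350 or 3500 masl, exactly 15 km) are mid-elevation, the
    thresholds being strict.
    """
    if elevation < 0 or dist_coast < 0:
        raise ValueError("elevation and dist_coast must be non-negative")
    if elevation < COASTAL_ELEV and dist_coast < COASTAL_DIST:
        return "coastal"
    if elevation > HIGHLAND_ELEV:
        return "highland"
    return "mid-elevation"


def cn_acceptable(
    cn_ratio: Optional[float],
    author_accepted: bool = False,
    study_validated: bool = False,
) -> bool:
    """Collagen quality rule.

    True iff the C:N atomic ratio is within the reliable 2.9–3.6 range, or
    the reporting author explicitly accepted the sample (which in practice
    extends the range to about 2.6–3.6), or the ratio is unreported but the
    source study validated all its samples.
    """
    if cn_ratio is not None:
        if cn_ratio <= 0 or math.isnan(cn_ratio):
            raise ValueError(f"C:N ratio must be positive, got {cn_ratio}")
        if CN_LO <= cn_ratio <= CN_HI:
            return True
        return bool(author_accepted)
    if author_accepted or study_validated:
        return True
    return False


def qc_filter(individuals: Sequence[Individual]) -> tuple[list[Individual], QCReport]:
    """Apply the inclusion filters, in order: age, C:N, Colonial period.

    Each individual is dropped by the first rule it fails, so report counts
    are reproducible.  Idempotent: re-filtering the retained set is a no-op.
    """
    report = QCReport(input=len(individuals))
    retained: list[Individual] = []
    for ind in individuals:
        if ind.age_years is not None and ind.age_years < MIN_AGE_YEARS:
            report.dropped_age += 1
            continue
        if not cn_acceptable(ind.cn_ratio, ind.author_accepted, ind.study_validated):
            report.dropped_cn += 1
            continue
        if ind.period.strip().lower() == "colonial":
            report.dropped_colonial += 1
            continue
        retained.append(ind)
        if ind.cn_ratio is None:
            report.no_cn_included += 1
    report.retained = len(retained)
    report.retained_d15N = sum(1 for i in retained if i.d15N is not None)
    report.retained_d13C = sum(1 for i in retained if i.d13C is not None)
    report.check()
    return retained, report


# ---------------------------------------------------------------------------
# CSV round-trip

_COLUMNS = [
    "id", "site_id", "lat", "lon", "elevation", "dist_coast",
    "d13C", "d15N", "cn_ratio", "author_accepted", "study_validated",
    "age_years", "period", "date_min", "date_max",
    "c14_lab_id", "c14_age", "c14_error", "c14_marine",
    "c14_delta_r", "c14_delta_r_error",
]


def write_individuals(individuals: Iterable[Individual], path) -> None:
    rows = []
    for ind in individuals:
        row = {
            "id": ind.id, "site_id": ind.site_id, "lat": ind.lat, "lon": ind.lon,
            "elevation": ind.elevation, "dist_coast": ind.dist_coast,
            "d13C": ind.d13C, "d15N": ind.d15N, "cn_ratio": ind.cn_ratio,
            "author_accepted": ind.author_accepted,
            "study_validated": ind.study_validated,
            "age_years": ind.age_years, "period": ind.period,
            "date_min": ind.date_min, "date_max": ind.date_max,
        }
        if ind.c14 is not None:
            row.update(
                c14_lab_id=ind.c14.lab_id, c14_age=ind.c14.age,
                c14_error=ind.c14.error, c14_marine=ind.c14.marine,
                c14_delta_r=ind.c14.delta_r,
                c14_delta_r_error=ind.c14.delta_r_error,
            )
        else:
            row.update(c14_lab_id=None, c14_age=None, c14_error=None,
                       c14_marine=None, c14_delta_r=None, c14_delta_r_error=None)
        for key, val in ind.truth.items():
            row[f"truth_{key}"] = val
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _opt(val) -> Optional[float]:
    return None if pd.isna(val) else float(val)


def read_individuals(path) -> list[Individual]:
    df = pd.read_csv(path)
    out: list[Individual] = []
    truth_cols = [c for c in df.columns if c.startswith("truth_")]
    for _, r in df.iterrows():
        c14 = None
        if "c14_age" in df.columns and not pd.isna(r["c14_age"]):
            c14 = RadiocarbonMeasurement(
                lab_id=str(r["c14_lab_id"]), age=float(r["c14_age"]),
                error=float(r["c14_error"]), marine=bool(r["c14_marine"]),
                delta_r=float(r["c14_delta_r"]),
                delta_r_error=float(r["c14_delta_r_error"]),
                site_id=str(r["site_id"]), lat=float(r["lat"]),
                lon=float(r["lon"]), elevation=float(r["elevation"]),
            )
        truth = {c[len("truth_"):]: float(r[c]) for c in truth_cols
                 if not pd.isna(r[c])}
        out.append(Individual(
            id=str(r["id"]), site_id=str(r["site_id"]),
            lat=float(r["lat"]), lon=float(r["lon"]),
            elevation=float(r["elevation"]), dist_coast=float(r["dist_coast"]),
            d13C=_opt(r["d13C"]), d15N=_opt(r["d15N"]),
            cn_ratio=_opt(r["cn_ratio"]),
            author_accepted=bool(r["author_accepted"]),
            study_validated=bool(r["study_validated"]),
            age_years=_opt(r["age_years"]),
            period="" if pd.isna(r["period"]) else str(r["period"]),
            date_min=float(r["date_min"]), date_max=float(r["date_max"]),
            c14=c14, truth=truth,
        ))
    return out
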