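import numpy as np
import pytest

from paleodiet.calibration import CalibrationCurve, RadiocarbonMeasurement
from paleodiet.climate import CLIMATE_VARIABLES, ClimateFieldSet
from paleodiet.qc import Individual


@pytest.fixture(scope="session")
def identity_curve() -> CalibrationCurve:
    """Identity calibration curve: mu(t) = t, sigma = 10, 0-7600 calBP."""
    cal = np.arange(0.0, 7601.0, 5.0)
    return CalibrationCurve(cal, cal.copy(), np.full(len(cal), 10.0),
                            name="identity")


@pytest.fixture
def measurement() -> RadiocarbonMeasurement:
    return RadiocarbonMeasurement(lab_id="X-1", age=3000.0, error=20.0)


@pytest.fixture(scope="session")
def toy_climate() -> ClimateFieldSet:
    """Two-cell, six-step constant-in-space toy field (values set per test)."""
    steps = np.arange(100.0, 220.0, 20.0)
    vals = {v: np.tile(np.arange(len(steps), dtype=float), (2, 1))
            for v in CLIMATE_VARIABLES}
    return ClimateFieldSet(
        cell_ids=np.array(["a", "b"]), lats=np.array([-10.0, -12.5]),
        lons=np.array([-75.0, -75.0]), steps=steps, values=vals,
    )


def make_individual(**kw) -> Individual:
    base = dict(id="i1", site_id="s1", lat=-12.0, lon=-75.0, elevation=1000.0,
                dist_coast=50.0, d15N=10.0, d13C=-12.0, cn_ratio=3.2,
                age_years=30.0, period="Middle Horizon",
                date_min=2000.0, date_max=2200.0)
    base.update(kw)
    return Individual(**base)


@pytest.fixture
def individual_factory():
    return make_individual
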