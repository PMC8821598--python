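"""Monte-Carlo covariate assignment and climate z-scores."""

import numpy as np
import pytest
from scipy import stats

from paleodiet.calibration import CalendarDensity
from paleodiet.climate import CLIMATE_VARIABLES, ClimateFieldSet
from paleodiet.demography import PopulationEnsemble
from paleodiet.exposure import (assign_climate, assign_population,
                                climate_zscores, window_sampler)


def _fields(values_fn, steps=None, lats=(-10.0, -12.5), lons=(-75.0,)):
    steps = np.arange(140.0, 3001.0, 20.0) if steps is None else steps
    n_cells = len(lats) * len(lons)
    lat_g, lon_g = np.meshgrid(lats, lons, indexing="ij")
    vals = {}
    for v in CLIMATE_VARIABLES:
        vals[v] = np.array([[values_fn(v, c, t) for t in steps]
                            for c in range(n_cells)], dtype=float)
    return ClimateFieldSet(
        cell_ids=np.array([f"c{i}" for i in range(n_cells)]),
        lats=lat_g.ravel(), lons=lon_g.ravel(), steps=steps, values=vals)


class TestWindowSampler:
    def test_degenerate_window(self, individual_factory):
        ind = individual_factory(date_min=3000.0, date_max=3000.0)
        years = window_sampler(ind, n_draws=20, seed=1)
        assert np.all(years == 3000.0)

    def test_uniform_window_mean(self, individual_factory):
        ind = individual_factory(date_min=2000.0, date_max=2200.0)
        years = window_sampler(ind, n_draws=10_000, seed=2)
        assert abs(years.mean() - 2100.0) < 2.0
        assert years.min() >= 2000.0 and years.max() <= 2200.0

    def test_dated_individual_follows_density(self, individual_factory):
        # bimodal density restricted to the window; draw histogram must match
        years = np.arange(2000.0, 2201.0)
        p = (stats.norm.pdf(years, 2050, 15) + stats.norm.pdf(years, 2150, 15))
        dens = CalendarDensity(years, p / p.sum())
        from paleodiet.calibration import RadiocarbonMeasurement
        ind = individual_factory(
            date_min=2000.0, date_max=2200.0,
            c14=RadiocarbonMeasurement("L1", 2100.0, 30.0))
        draws = window_sampler(ind, n_draws=20_000, seed=3, density=dens)
        # chi-square GOF against the density on 20-yr bins
        bins = np.arange(2000.0, 2201.0, 20.0)
        obs, _ = np.histogram(draws, bins=bins)
        idx = np.digitize(years, bins) - 1
        exp = np.array([p[idx == k].sum() for k in range(len(bins) - 1)])
        exp = exp / exp.sum() * len(draws)
        _, pval = stats.chisquare(obs, exp)
        assert pval > 0.01

    def test_same_seed_identical(self, individual_factory):
        ind = individual_factory()
        a = window_sampler(ind, n_draws=100, seed=7)
        b = window_sampler(ind, n_draws=100, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_window_outside_span_raises(self, individual_factory):
        ind = individual_factory(date_min=20.0, date_max=100.0)
        with pytest.raises(ValueError, match="analysis span"):
            window_sampler(ind, n_draws=10, seed=0)

    def test_window_truncated_with_warning(self, individual_factory):
        ind = individual_factory(date_min=100.0, date_max=400.0)
        with pytest.warns(UserWarning, match="truncated"):
            years = window_sampler(ind, n_draws=500, seed=0)
        assert years.min() >= 140.0


class TestAssignClimate:
    def test_constant_field(self, individual_factory):
        fields = _fields(lambda v, c, t: 5.5)
        ind = individual_factory(lat=-10.0, lon=-75.0)
        means = assign_climate(ind, fields, np.array([2000.0, 2100.0]))
        assert all(means[v] == pytest.approx(5.5) for v in CLIMATE_VARIABLES)

    def test_linear_field_uniform_window(self, individual_factory):
        fields = _fields(lambda v, c, t: 0.01 * t)
        ind = individual_factory(lat=-10.0, lon=-75.0,
                                 date_min=1000.0, date_max=1400.0)
        years = window_sampler(ind, n_draws=20_000, seed=4)
        means = assign_climate(ind, fields, years)
        assert means["temp"] == pytest.approx(0.01 * 1200.0, abs=0.05)

    def test_degenerate_window_exact_step(self, individual_factory):
        fields = _fields(lambda v, c, t: t)
        ind = individual_factory(lat=-10.0, lon=-75.0)
        means = assign_climate(ind, fields, np.array([1407.0]))
        assert means["precip"] == 1400.0  # nearest 20-yr step

    def test_outside_grid_raises(self, individual_factory):
        fields = _fields(lambda v, c, t: 0.0)
        ind = individual_factory(lat=40.0, lon=-75.0)
        with pytest.raises(ValueError, match="grid"):
            assign_climate(ind, fields, np.array([2000.0]))


class TestAssignPopulation:
    def _ens(self, fits, years=None):
        years = np.arange(0.0, 7001.0, 20.0) if years is None else years
        return PopulationEnsemble(zone="z", years=years, fits=fits)

    def test_flat_identical_fits(self, individual_factory):
        years = np.arange(0.0, 7001.0, 20.0)
        ens = self._ens(np.full((5, len(years)), 0.25), years)
        ind = individual_factory()
        assert assign_population(ind, ens, n_draws=200, seed=1) == \
            pytest.approx(0.25)

    def test_single_fit_degenerate_window(self, individual_factory):
        years = np.arange(0.0, 7001.0, 20.0)
        fits = np.linspace(0, 1, len(years))[None, :]
        ens = self._ens(fits, years)
        ind = individual_factory(date_min=3000.0, date_max=3000.0)
        got = assign_population(ind, ens, n_draws=50, seed=2)
        idx = int(np.argmin(np.abs(years - 3000.0)))
        assert got == pytest.approx(fits[0, idx])

    def test_two_fits_exhaustive_expectation(self, individual_factory):
        # 2 fits x 2 window years -> expectation is the average of 4 values
        years = np.arange(2000.0, 2002.0)
        fits = np.array([[0.1, 0.3], [0.5, 0.7]])
        ens = self._ens(fits, years)
        ind = individual_factory(date_min=2000.0, date_max=2001.0)
        got = assign_population(ind, ens, n_draws=40_000, seed=3)
        assert got == pytest.approx(0.4, abs=0.005)

    def test_window_outside_grid_raises(self, individual_factory):
        years = np.arange(0.0, 1001.0, 20.0)
        ens = self._ens(np.full((2, len(years)), 1.0), years)
        ind = individual_factory(date_min=2000.0, date_max=2200.0)
        with pytest.raises(ValueError, match="ensemble grid"):
            assign_population(ind, ens, n_draws=10, seed=0)


class TestClimateZScores:
    def test_zscore_moments(self):
        rng = np.random.default_rng(0)
        steps = np.arange(140.0, 2001.0, 20.0)
        fields = _fields(lambda v, c, t: float(rng.normal()), steps=steps)
        z = climate_zscores(fields)
        for v in CLIMATE_VARIABLES:
            np.testing.assert_allclose(z[v]["z"].mean(axis=1), 0.0, atol=1e-9)
            np.testing.assert_allclose(z[v]["z"].std(axis=1, ddof=0), 1.0,
                                       atol=1e-9)

    def test_constant_series_zero_with_warning(self):
        fields = _fields(lambda v, c, t: 3.0)
        with pytest.warns(UserWarning, match="zero-variance"):
            z = climate_zscores(fields)
        assert np.all(z["temp"]["z"] == 0.0)

    def test_two_cell_central_line_hand_computed(self):
        steps = np.array([100.0, 120.0, 140.0])
        vals = {v: np.array([[0.0, 1.0, 2.0], [2.0, 1.0, 0.0]])
                for v in CLIMATE_VARIABLES}
        fields = ClimateFieldSet(cell_ids=np.array(["a", "b"]),
                                 lats=np.array([-10.0, -12.0]),
                                 lons=np.array([-75.0, -75.0]),
                                 steps=steps, values=vals)
        z = climate_zscores(fields, smooth_window=1)
        # cells are mirror images: cross-cell mean z is 0 everywhere
        np.testing.assert_allclose(z["temp"]["central"], 0.0, atol=1e-12)


def test_mc_means_converge_with_draws(individual_factory):
    # doubling the draw count moves each climate mean by well under 0.5% of
    # the value range across the window
    fields = _fields(lambda v, c, t: np.sin(t / 150.0),
                     steps=np.arange(140.0, 4001.0, 20.0))
    ind = individual_factory(lat=-10.0, lon=-75.0,
                             date_min=1000.0, date_max=2000.0)
    means = {}
    for n in (20_000, 40_000):
        years = window_sampler(ind, n_draws=n, seed=8)
        means[n] = assign_climate(ind, fields, years)["temp"]
    value_range = 2.0  # sin spans [-1, 1]
    assert abs(means[40_000] - means[20_000]) < 0.005 * value_range


def test_exposures_match_truth_with_degenerate_windows():
    # noiseless generator + zero-width windows + single-fit ensembles:
    # recovered covariates equal the generator's truth exactly
    from paleodiet.demography import PopulationEnsemble, default_grid
    from paleodiet.exposure import build_exposures
    from paleodiet.synthetic import (GroundTruth, simulate_climate_fields,
                                     simulate_individuals)

    clim = simulate_climate_fields([-14.0, -10.0], [-76.0, -73.0], seed=31)
    grid = default_grid(7400.0, 0.0, 20.0)
    fits = np.abs(np.sin(grid / 700.0)) + 0.1
    fits = (fits / np.trapezoid(fits, grid))[None, :]
    ens = {z: PopulationEnsemble(zone=z, years=grid, fits=fits.copy())
           for z in ("coastal", "mid-elevation", "highland")}
    shares = {k: 0.0 for k in GroundTruth().effect_shares}
    shares["precip"] = 1.0
    inds = simulate_individuals(
        30, clim, ens, GroundTruth(effect_shares=shares), window_width=0.0,
        seed=32, dated_fraction=0.0,
        underage_fraction=0.0, bad_cn_fraction=0.0, colonial_fraction=0.0)
    recs = build_exposures(inds, clim, ens, ens, n_draws=10, seed=33)
    for ind, rec in zip(inds, recs):
        # equality up to floating summation order in the draw mean
        assert rec.temp == pytest.approx(ind.truth["temp"], rel=1e-12)
        assert rec.precip == pytest.approx(ind.truth["precip"], rel=1e-12)
        assert rec.mean_kde_uncorrected == pytest.approx(
            ind.truth["population"], rel=1e-12)
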