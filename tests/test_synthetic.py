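"""Ground-truth structure and reproducibility of the synthetic generator."""

import numpy as np
import pytest
from scipy import stats

from paleodiet.climate import CLIMATE_VARIABLES
from paleodiet.demography import PopulationEnsemble, default_grid
from paleodiet.synthetic import (GroundTruth, make_bundle,
                                 make_calibration_curve,
                                 simulate_climate_fields, simulate_dates,
                                 simulate_individuals, write_bundle)


class TestCalibrationCurveGenerator:
    def test_zero_wiggle_is_identity(self):
        c = make_calibration_curve(0, 1000, wiggle_amplitude=0, seed=1)
        np.testing.assert_array_equal(c.mu, c.cal_bp)
        assert np.all(c.sigma == 10.0)

    def test_wiggle_bounded_across_seeds(self):
        amp = 30.0
        for seed in range(100):
            c = make_calibration_curve(0, 7000, wiggle_amplitude=amp, seed=seed)
            assert np.max(np.abs(c.mu - c.cal_bp)) <= 3 * amp + 1e-9

    def test_grid_monotone_and_sigma_positive(self):
        c = make_calibration_curve(100, 5000, wiggle_amplitude=50, seed=3)
        assert np.all(np.diff(c.cal_bp) > 0)
        assert np.all(c.sigma > 0)
        assert c.cal_bp[1] - c.cal_bp[0] == 5.0

    def test_inverted_range_raises(self):
        with pytest.raises(ValueError):
            make_calibration_curve(1000, 0)


class TestClimateSimulator:
    def test_ar_zero_uncorrelated(self):
        rs = []
        for seed in range(10):
            f = simulate_climate_fields([-10.0], [-75.0], year_range=(0, 6000),
                                        ar_coef=0.0, seed=seed)
            series = f.values["temp"][0]
            rs.append(np.corrcoef(series[:-1], series[1:])[0, 1])
        # per-seed sampling sd of lag-1 r at ~300 steps is ~0.06
        assert abs(np.mean(rs)) < 0.05
        assert max(abs(r) for r in rs) < 0.25

    def test_ar_high_strongly_autocorrelated(self):
        f = simulate_climate_fields([-10.0], [-75.0], year_range=(0, 6000),
                                    ar_coef=0.9, seed=2)
        series = f.values["temp"][0]
        r = np.corrcoef(series[:-1], series[1:])[0, 1]
        assert r > 0.8

    def test_constant_forcing_constant_series(self):
        f = simulate_climate_fields([-10.0, -12.5], [-75.0], sd_scale=0.0,
                                    seed=3)
        for v in CLIMATE_VARIABLES:
            assert np.all(f.values[v] == f.values[v][:, [0]])

    def test_precip_nonnegative_and_empty_grid_raises(self):
        f = simulate_climate_fields([-10.0], [-75.0], seed=4)
        assert np.all(f.values["precip"] >= 0)
        with pytest.raises(ValueError):
            simulate_climate_fields([], [-75.0])


class TestDateSimulator:
    def _identity(self):
        return make_calibration_curve(0, 7600, wiggle_amplitude=0, seed=0)

    def test_uniform_curve_flat_histogram(self):
        grid = np.arange(500.0, 6501.0, 20.0)
        dates = simulate_dates((grid, np.ones_like(grid)), 2000,
                               self._identity(), seed=5)
        # true calendar years equal 14C ages here up to noise; chi-square GOF
        ages = np.array([d.age for d in dates])
        obs, _ = np.histogram(ages, bins=10, range=(500, 6500))
        _, p = stats.chisquare(obs)
        assert p > 0.01

    def test_point_mass_mean(self):
        dates = simulate_dates((np.array([3000.0]), np.array([1.0])), 2000,
                               self._identity(), error_sd=20.0, seed=6)
        ages = np.array([d.age for d in dates])
        assert abs(ages.mean() - 3000.0) < 1.0

    def test_zero_error_exact(self):
        grid = np.array([1500.0, 2500.0])
        dates = simulate_dates((grid, np.array([0.5, 0.5])), 100,
                               self._identity(), error_sd=0.0, seed=7)
        assert all(d.age in (1500.0, 2500.0) for d in dates)

    def test_some_sites_carry_many_dates(self):
        grid = np.arange(1000.0, 6001.0, 20.0)
        dates = simulate_dates((grid, np.ones_like(grid)), 400,
                               self._identity(), seed=8)
        from collections import Counter
        sizes = Counter(d.site_id for d in dates)
        assert max(sizes.values()) >= 10 and len(sizes) > 5

    def test_invalid_n_raises(self):
        with pytest.raises(ValueError):
            simulate_dates((np.array([1.0]), np.array([1.0])), 0,
                           self._identity())


def _flat_ensembles():
    grid = default_grid(7400.0, 0.0, 20.0)
    flat = np.full((1, len(grid)), 1.0)
    flat /= np.trapezoid(flat, grid)
    return {z: PopulationEnsemble(zone=z, years=grid, fits=flat.copy())
            for z in ("coastal", "mid-elevation", "highland")}


class TestIndividualSimulator:
    def test_counts_and_zones(self):
        clim = simulate_climate_fields([-14.0, -10.0], [-76.0, -73.0], seed=9)
        truth = GroundTruth()
        inds = simulate_individuals(500, clim, _flat_ensembles(), truth,
                                    seed=10, dated_fraction=0.0)
        assert len(inds) == 500
        zones = {i.zone for i in inds}
        assert zones == {"coastal", "mid-elevation", "highland"}
        for i in inds:
            assert i.date_min <= i.truth["year"] <= i.date_max

    def test_noiseless_pure_precip_linear(self):
        clim = simulate_climate_fields([-14.0, -10.0], [-76.0, -73.0], seed=11)
        shares = {v: 0.0 for v in GroundTruth().effect_shares}
        shares["precip"] = 1.0
        truth = GroundTruth(effect_shares=shares)
        inds = simulate_individuals(300, clim, _flat_ensembles(), truth,
                                    seed=12, dated_fraction=0.0)
        precip = np.array([i.truth["precip"] for i in inds])
        d15n = np.array([i.d15N for i in inds])
        z = (precip - precip.mean()) / precip.std()
        np.testing.assert_allclose(d15n, truth.intercept + truth.total_sd * z,
                                   atol=1e-9)

    def test_dated_fraction(self):
        clim = simulate_climate_fields([-14.0, -10.0], [-76.0, -73.0], seed=13)
        curve = make_calibration_curve(0, 7600, 0, seed=0)
        inds = simulate_individuals(400, clim, _flat_ensembles(),
                                    GroundTruth(), seed=14,
                                    dated_fraction=0.09, curve=curve)
        n_dated = sum(1 for i in inds if i.c14 is not None)
        assert n_dated == round(0.09 * 400)

    def test_seed_reproducibility(self):
        clim = simulate_climate_fields([-14.0, -10.0], [-76.0, -73.0], seed=15)
        a = simulate_individuals(50, clim, _flat_ensembles(), GroundTruth(),
                                 seed=16, dated_fraction=0.0)
        b = simulate_individuals(50, clim, _flat_ensembles(), GroundTruth(),
                                 seed=16, dated_fraction=0.0)
        c = simulate_individuals(50, clim, _flat_ensembles(), GroundTruth(),
                                 seed=17, dated_fraction=0.0)
        assert all(x.d15N == y.d15N and x.truth == y.truth
                   for x, y in zip(a, b))
        assert any(x.d15N != y.d15N for x, y in zip(a, c))

    def test_negative_window_raises(self):
        clim = simulate_climate_fields([-14.0], [-76.0], seed=18)
        with pytest.raises(ValueError):
            simulate_individuals(10, clim, _flat_ensembles(), GroundTruth(),
                                 window_width=-1.0)


class TestGroundTruth:
    def test_share_validation(self):
        with pytest.raises(ValueError, match="negative"):
            GroundTruth(effect_shares={"temp": -0.1, "noise": 1.1})
        with pytest.raises(ValueError, match="sum to 1"):
            GroundTruth(effect_shares={"temp": 0.5, "noise": 0.3})

    def test_variance_shares_recovered_at_large_n(self):
        # empirical variance share of every response component matches the
        # requested share closely at n = 10,000
        rng = np.random.default_rng(20)
        n = 10_000
        covs = {v: rng.standard_normal(n)
                for v in (*CLIMATE_VARIABLES, "population")}
        truth = GroundTruth()
        signal, y = truth.response(covs, np.random.default_rng(21))
        total_var = truth.total_sd**2
        for var in (*CLIMATE_VARIABLES, "population"):
            share = truth.effect_shares[var]
            z = (covs[var] - covs[var].mean()) / covs[var].std()
            comp = truth.total_sd * np.sqrt(share) * z
            assert abs(comp.var() / total_var - share) < 0.05
        noise_share = np.var(y - signal) / total_var
        assert abs(noise_share - truth.effect_shares["noise"]) < 0.05


def test_bundle_roundtrip(tmp_path):
    from paleodiet.calibration import read_curve, read_dates
    from paleodiet.climate import read_climate
    from paleodiet.qc import read_individuals

    bundle = make_bundle(seed=3, n_individuals=40, n_dates_per_zone=30,
                         n_fits=10)
    paths = write_bundle(bundle, tmp_path / "b")
    inds = read_individuals(paths["individuals"])
    assert len(inds) == 40
    assert inds[0].d15N == pytest.approx(bundle.individuals[0].d15N)
    assert inds[0].truth["year"] == pytest.approx(
        bundle.individuals[0].truth["year"])
    dates = read_dates(paths["dates"])
    assert len(dates) == len(bundle.dates)
    curve = read_curve(paths["curve"])
    np.testing.assert_allclose(curve.cal_bp, bundle.curve.cal_bp)
    clim = read_climate(paths["climate"])
    np.testing.assert_allclose(clim.values["temp"],
                               bundle.climate.values["temp"])
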