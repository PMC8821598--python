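"""Centered partial dependence, Friedman's H, and effect decomposition."""

import numpy as np
import pandas as pd
import pytest

from paleodiet.effects import (EffectDecomposition, cumulative_comparison,
                               effect_size, friedman_h, pd_profile)


class Surrogate:
    """Deterministic stand-in model with a known prediction function."""

    def __init__(self, fn, features):
        self.fn = fn
        self.features = features

    def predict(self, design):
        if isinstance(design, pd.DataFrame):
            design = design[self.features].to_numpy()
        return np.apply_along_axis(self.fn, 1, np.asarray(design, dtype=float))


def _rows(n=30, seed=0, features=("x1", "x2")):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.standard_normal((n, len(features))),
                        columns=list(features))


class TestPDProfile:
    def test_model_ignoring_variable_has_zero_pd(self):
        model = Surrogate(lambda r: 3.0 * r[1], ["x1", "x2"])
        rows = _rows()
        prof = pd_profile(model, rows, "x1", np.linspace(-2, 2, 7))
        np.testing.assert_allclose(prof.pd_centered, 0.0, atol=1e-12)

    def test_linear_surrogate_closed_form(self):
        model = Surrogate(lambda r: 2.0 * r[0], ["x1", "x2"])
        rows = _rows()
        grid = np.array([-1.0, 0.0, 0.5, 2.0])
        prof = pd_profile(model, rows, "x1", grid)
        np.testing.assert_allclose(prof.pd_centered, 2.0 * (grid - grid.mean()),
                                   atol=1e-12)

    def test_three_by_three_bruteforce(self):
        model = Surrogate(lambda r: r[0] ** 2 + r[0] * r[1] - r[1], ["x1", "x2"])
        rows = pd.DataFrame({"x1": [0.0, 1.0, -1.0], "x2": [2.0, 0.0, 1.0]})
        grid = np.array([-1.0, 0.0, 1.0])
        prof = pd_profile(model, rows, "x1", grid)
        # independent 9-prediction enumeration
        f = np.empty((3, 3))
        for i in range(3):
            for k in range(3):
                f[i, k] = model.fn([grid[k], rows["x2"].iloc[i]])
        pd_j = f.mean(axis=0)
        pd_j -= pd_j.mean()
        pd_mj = f.mean(axis=1)
        pd_mj -= pd_mj.mean()
        np.testing.assert_allclose(prof.predictions, f, atol=1e-12)
        np.testing.assert_allclose(prof.pd_centered, pd_j, atol=1e-12)
        np.testing.assert_allclose(prof.pd_complement, pd_mj, atol=1e-12)

    def test_centering_invariants(self):
        model = Surrogate(lambda r: np.sin(r[0]) + r[1] ** 2, ["x1", "x2"])
        prof = pd_profile(model, _rows(50, 1), "x1", np.linspace(-2, 2, 11))
        assert abs(prof.pd_centered.mean()) < 1e-9
        assert abs(prof.pd_complement.mean()) < 1e-9

    def test_unknown_variable_raises(self):
        model = Surrogate(lambda r: r[0], ["x1", "x2"])
        with pytest.raises(ValueError, match="feature"):
            pd_profile(model, _rows(), "zz", np.array([0.0, 1.0]))


class TestFriedmanH:
    def test_additive_function_h_zero(self):
        model = Surrogate(lambda r: 2 * r[0] + np.sin(r[1]), ["x1", "x2"])
        prof = pd_profile(model, _rows(40, 2), "x1", np.linspace(-2, 2, 15))
        assert friedman_h(prof) == pytest.approx(0.0, abs=1e-9)

    def test_pure_product_h_near_one(self):
        model = Surrogate(lambda r: r[0] * r[1], ["x1", "x2"])
        rows = _rows(400, 3)
        rows -= rows.mean()  # centered inputs: no additive component survives
        prof = pd_profile(model, rows, "x1",
                          rows["x1"].to_numpy()[:100])
        assert friedman_h(prof) > 0.9

    def test_invariant_to_constant_shift(self):
        rows = _rows(40, 4)
        grid = np.linspace(-2, 2, 9)
        m0 = Surrogate(lambda r: r[0] * r[1] + r[0], ["x1", "x2"])
        m1 = Surrogate(lambda r: r[0] * r[1] + r[0] + 123.0, ["x1", "x2"])
        h0 = friedman_h(pd_profile(m0, rows, "x1", grid))
        h1 = friedman_h(pd_profile(m1, rows, "x1", grid))
        assert h0 == pytest.approx(h1, abs=1e-9)

    def test_zero_variance_warns(self):
        model = Surrogate(lambda r: 7.0, ["x1", "x2"])
        prof = pd_profile(model, _rows(10, 5), "x1", np.array([0.0, 1.0]))
        with pytest.warns(UserWarning, match="zero variance"):
            assert friedman_h(prof) == 0.0


class TestEffectSize:
    def test_irrelevant_variable_zero_effect(self):
        model = Surrogate(lambda r: 4.0 * r[1], ["x1", "x2"])
        dec = effect_size(model, _rows(60, 6), "x1", n_iter=5, m=20, seed=1)
        assert dec.effect_permil == pytest.approx(0.0, abs=1e-9)
        assert dec.percent_of_total == pytest.approx(0.0, abs=1e-9)

    def test_linear_surrogate_closed_form(self):
        # y = beta * x1 and nothing else: per iteration
        # ss_raw = beta^2 * sum_k (v_k - vbar)^2, h = 0, and
        # ss_total = sum_k (beta v_k - mean_{i,k} beta v)^2 ... equals ss_raw
        beta = 3.0
        model = Surrogate(lambda r: beta * r[0], ["x1", "x2"])
        rows = _rows(50, 7)
        m, n_iter, seed = 12, 4, 9
        dec = effect_size(model, rows, "x1", n_iter=n_iter, m=m, seed=seed)
        # independent re-derivation from the same seeded grid draws
        rng = np.random.default_rng(seed)
        obs = rows["x1"].to_numpy()
        ss = []
        for _ in range(n_iter):
            grid = rng.choice(obs, size=m, replace=True)
            ss.append(beta**2 * np.sum((grid - grid.mean()) ** 2))
        expect = float(np.sqrt(np.mean(ss)))
        assert dec.h == pytest.approx(0.0, abs=1e-9)
        assert dec.effect_permil == pytest.approx(expect, rel=1e-9)
        assert dec.percent_of_total == pytest.approx(100.0, rel=1e-6)

    def test_deduction_variants(self):
        model = Surrogate(lambda r: r[0] * r[1] + r[0], ["x1", "x2"])
        rows = _rows(80, 8)
        d1 = effect_size(model, rows, "x1", n_iter=3, m=15, seed=2,
                         deduct="one_minus_h")
        d2 = effect_size(model, rows, "x1", n_iter=3, m=15, seed=2,
                         deduct="one_minus_h2")
        assert 0.0 < d1.h < 1.0
        assert d1.ss_deducted < d2.ss_deducted <= d2.ss_raw

    def test_seed_stability(self):
        model = Surrogate(lambda r: np.tanh(r[0]) * 2 + r[1], ["x1", "x2"])
        rows = _rows(150, 10)
        a = effect_size(model, rows, "x1", n_iter=100, m=50, seed=1)
        b = effect_size(model, rows, "x1", n_iter=100, m=50, seed=2)
        assert abs(a.effect_permil - b.effect_permil) / a.effect_permil < 0.05

    def test_validation(self):
        model = Surrogate(lambda r: r[0], ["x1", "x2"])
        with pytest.raises(ValueError, match="m must"):
            effect_size(model, _rows(), "x1", m=1)


class TestCumulativeComparison:
    def _dec(self, zone, var, permil, pct):
        return EffectDecomposition(zone=zone, variable=var, h=0.0,
                                   ss_raw=permil**2, ss_deducted=permil**2,
                                   ss_total=1.0, effect_permil=permil,
                                   percent_of_total=pct, n_iterations=1)

    def test_cumulative_is_sum_of_components(self):
        # component per-mil effects mirroring a coastal-like row
        vals = {"temp": 1.4, "temp_seasonality": 6.5, "precip": 10.2,
                "precip_seasonality": 1.2, "kde": 1.6}
        decs = [self._dec("coastal", v, p, p) for v, p in vals.items()]
        table = cumulative_comparison(decs, "kde")
        assert table["cumulative_climate_permil"].iloc[0] == \
            pytest.approx(1.4 + 6.5 + 10.2 + 1.2)
        assert table["demography_permil"].iloc[0] == pytest.approx(1.6)

    def test_all_equal_effects_ratio_four_to_one(self):
        decs = [self._dec("z", v, 2.0, 10.0) for v in
                ("temp", "temp_seasonality", "precip", "precip_seasonality",
                 "kde")]
        table = cumulative_comparison(decs, "kde")
        assert table["climate_over_demography"].iloc[0] == pytest.approx(4.0)

    def test_missing_variable_raises(self):
        decs = [self._dec("z", "temp", 1.0, 1.0)]
        with pytest.raises(ValueError, match="missing"):
            cumulative_comparison(decs, "kde")


def test_additive_model_ss_raw_sums_to_ss_total():
    # for an additive prediction function, the per-variable explained sums of
    # squares add up to the total prediction variability (within MC error of
    # the resampled grids)
    rng = np.random.default_rng(30)
    rows = pd.DataFrame(rng.standard_normal((400, 2)), columns=["x1", "x2"])
    model = Surrogate(lambda r: 2.0 * r[0] + 1.0 * r[1], ["x1", "x2"])
    d1 = effect_size(model, rows, "x1", n_iter=20, m=60, seed=3)
    d2 = effect_size(model, rows, "x2", n_iter=20, m=60, seed=4)
    total = 0.5 * (d1.ss_total + d2.ss_total)
    assert abs((d1.ss_raw + d2.ss_raw) / total - 1.0) < 0.1
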