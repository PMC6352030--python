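"""Least-squares fitting, seeds, fit statistics and the report table."""

import numpy as np
import pandas as pd
import pytest

from odkinetics import (
    BurgersParams,
    KelvinVoigtParams,
    PelegParams,
    eval_burgers,
    eval_kelvin_voigt,
    eval_peleg,
    fit_model,
    fit_report,
    goodness_of_fit,
    initial_guess,
)
from odkinetics.fitting import InsufficientDataError, r2_ratio_form


@pytest.fixture(scope="module")
def grid():
    return np.arange(0.0, 181.0, 30.0)


class TestGoodnessOfFit:
    def test_perfect_fit(self):
        y = np.array([0.0, 0.5, 0.9, 1.2])
        g = goodness_of_fit(y, y, 2)
        assert g == {"r2": 1.0, "chi2": 0.0, "rmse": 0.0, "crv": 0.0}

    def test_crv_scale(self):
        # chi2 = 0.009 against a series with mean 3.295 -> CRV = 2.88%
        exp = np.full(7, 3.295)
        pred = exp + np.sqrt(0.009 * (7 - 2) / 7)
        g = goodness_of_fit(pred, exp, 2)
        assert g["chi2"] == pytest.approx(0.009)
        assert g["crv"] == pytest.approx(2.88, abs=0.02)

    def test_constant_prediction_gives_zero_r2(self):
        exp = np.array([1.0, 2.0, 3.0, 4.0])
        pred = np.full_like(exp, exp.mean())
        assert goodness_of_fit(pred, exp, 1)["r2"] == pytest.approx(0.0)

    def test_reduced_chi2_rmse_identity(self):
        rng = np.random.default_rng(5)
        exp = rng.uniform(1, 2, size=9)
        pred = exp + rng.normal(0, 0.1, size=9)
        g = goodness_of_fit(pred, exp, 3)
        assert g["chi2"] * (9 - 3) == pytest.approx(9 * g["rmse"] ** 2, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(InsufficientDataError):
            goodness_of_fit([1.0, 2.0], [1.0, 2.0], 2)
        with pytest.raises(ValueError, match="zero mean"):
            goodness_of_fit([1.0, -1.0, 0.0], [1.0, -1.0, 0.0], 1)

    def test_ratio_form_diagnostic_is_one_on_perfect_fit(self):
        y = np.array([0.1, 0.7, 1.1, 1.4])
        assert r2_ratio_form(y, y) == pytest.approx(1.0)


class TestInitialGuess:
    def test_peleg_linearization_exact(self, grid):
        p = PelegParams(k1=16.714, k2=0.534)
        seed = initial_guess(grid, eval_peleg(grid, p), "peleg")
        assert seed["k1"] == pytest.approx(p.k1, rel=1e-9)
        assert seed["k2"] == pytest.approx(p.k2, rel=1e-9)

    def test_kelvin_voigt_seed_close_on_exact_data(self, grid):
        p = KelvinVoigtParams(a=1.557, b=37.648)
        seed = initial_guess(grid, eval_kelvin_voigt(grid, p), "kelvin_voigt")
        assert seed["b"] == pytest.approx(p.b, rel=0.10)
        assert seed["a"] == pytest.approx(1.05 * eval_kelvin_voigt(180.0, p))

    def test_burgers_seed_nonnegative_c(self, grid):
        p = BurgersParams(a=0.957, b=19.818, c=3.304e-3)
        seed = initial_guess(grid, eval_burgers(grid, p), "burgers")
        assert seed["c"] >= 0

    def test_constant_series_rejected(self, grid):
        with pytest.raises(ValueError, match="constant"):
            initial_guess(grid, np.ones_like(grid), "peleg")


class TestFitModel:
    def test_peleg_self_consistency(self, grid):
        p = PelegParams(k1=28.202, k2=0.362)
        fr = fit_model(grid, eval_peleg(grid, p), "peleg", y0=0.0, direction=1)
        assert fr.params.k1 == pytest.approx(p.k1, rel=1e-6)
        assert fr.params.k2 == pytest.approx(p.k2, rel=1e-6)
        assert fr.r2 == pytest.approx(1.0)
        assert fr.crv == pytest.approx(0.0, abs=1e-8)

    def test_kelvin_voigt_self_consistency(self, grid):
        p = KelvinVoigtParams(a=2.113, b=63.358)
        fr = fit_model(grid, eval_kelvin_voigt(grid, p), "kelvin_voigt")
        assert fr.params.a == pytest.approx(p.a, rel=1e-6)
        assert fr.params.b == pytest.approx(p.b, rel=1e-6)

    def test_burgers_nesting_recovers_zero_c(self, grid):
        kv = KelvinVoigtParams(a=1.340, b=28.683)
        fr = fit_model(grid, eval_kelvin_voigt(grid, kv), "burgers")
        assert abs(fr.params.c) <= 1e-6
        assert fr.params.a == pytest.approx(kv.a, rel=1e-4)

    def test_fit_is_invariant_to_row_order(self, grid):
        rng = np.random.default_rng(3)
        p = PelegParams(k1=13.0, k2=0.66)
        y = eval_peleg(grid, p) + rng.normal(0, 0.02, grid.size)
        perm = rng.permutation(grid.size)
        a = fit_model(grid, y, "peleg", y0=0.0, direction=1)
        b = fit_model(grid[perm], y[perm], "peleg", y0=0.0, direction=1)
        assert a.params == b.params

    def test_fixed_y0_is_respected(self, grid):
        p = PelegParams(k1=10.892, k2=0.242, y0=5.69, direction=-1)
        y = eval_peleg(grid, p) + np.random.default_rng(1).normal(0, 0.05, grid.size)
        fr = fit_model(grid, y, "peleg", y0=5.69, direction=-1)
        assert fr.params.y0 == 5.69
        assert fr.n_free == 2
        fr_free = fit_model(grid, y, "peleg", direction=-1, fit_y0=True)
        assert fr_free.n_free == 3

    def test_chi2_identity_on_fits(self, grid):
        rng = np.random.default_rng(9)
        y = eval_kelvin_voigt(grid, KelvinVoigtParams(a=1.0, b=40.0))
        fr = fit_model(grid, y + rng.normal(0, 0.03, grid.size), "kelvin_voigt")
        assert fr.chi2 * (fr.n_points - fr.n_free) == pytest.approx(
            fr.n_points * fr.rmse ** 2, rel=1e-10)

    def test_insufficient_points(self):
        with pytest.raises(InsufficientDataError):
            fit_model([0.0, 30.0], [0.0, 0.5], "peleg", y0=0.0, direction=1)

    def test_fitted_ssr_beats_random_parameter_draws(self, grid):
        """Monte-Carlo lower bound: no random (k1, k2) in a broad box beats
        the optimizer's residual on a noisy instance."""
        rng = np.random.default_rng(17)
        y = eval_peleg(grid, PelegParams(k1=20.0, k2=0.6)) + rng.normal(0, 0.03, grid.size)
        fr = fit_model(grid, y, "peleg", y0=0.0, direction=1)
        ssr_fit = float(np.sum(fr.residuals ** 2))
        k1 = rng.uniform(1.0, 100.0, size=10_000)[:, None]
        k2 = rng.uniform(0.05, 5.0, size=10_000)[:, None]
        pred = grid[None, :] / (k1 + k2 * grid[None, :])
        ssr_draws = np.sum((pred - y[None, :]) ** 2, axis=1)
        assert ssr_fit <= ssr_draws.min() + 1e-12


class TestFitReport:
    @pytest.fixture()
    def averaged(self, noise_free_study):
        from odkinetics import kinetics_table
        _, measurements, initial, _ = noise_free_study
        _, avg = kinetics_table(measurements, initial)
        return avg

    def test_report_shape_and_defaults(self, averaged):
        report = fit_report(averaged)
        # 5 solutes x (WC:1 + WL:3 + SG:3 + WLT:3 + CR:1) families
        assert len(report) == 5 * 11
        assert report["fit_ok"].all()
        assert set(report["response"]) == {"WC", "SG", "WL", "WLT", "CR"}

    def test_usable_flag_tracks_crv_rule(self, averaged):
        report = fit_report(averaged)
        assert (report["usable"] == (report["CRV_pct"] < 20.0)).all()

    def test_empty_input_gives_empty_report(self, averaged):
        report = fit_report(averaged.iloc[0:0])
        assert report.empty

    def test_failed_fit_is_flagged_not_raised(self):
        # two solutes, one with a constant (unfittable) water-loss series
        kin = pd.DataFrame({
            "solute": ["ok"] * 7 + ["flat"] * 7,
            "tau_min": list(range(0, 181, 30)) * 2,
            "WL": list(eval_kelvin_voigt(np.arange(0, 181, 30.0),
                                         KelvinVoigtParams(a=1.5, b=40.0))) + [0.0] * 7,
        })
        report = fit_report(kin, responses=["WL"], families=["kelvin_voigt"])
        assert len(report) == 2
        flat = report[report["solute"] == "flat"].iloc[0]
        assert not flat["fit_ok"] and not flat["usable"]
        assert report[report["solute"] == "ok"].iloc[0]["fit_ok"]
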