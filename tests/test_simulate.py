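"""Synthetic study generation: true kinetics, mass-balance inversion, noise."""

import numpy as np
import pandas as pd
import pytest

from odkinetics import (
    SimConfig,
    fit_model,
    generate_study,
    invert_to_raw,
    kinetics_table,
    simulate_true_kinetics,
)
from odkinetics.simulate import DEFAULT_TRUE_MODELS, InfeasibleKineticsError
from odkinetics.transfer import solid_gain, water_loss


class TestTrueKinetics:
    def test_peleg_trajectory_value(self):
        cfg = SimConfig(solutes={
            "ery": {"wl": {"family": "peleg", "k1": 16.714, "k2": 0.534},
                    "sg": {"family": "kelvin_voigt", "a": 0.871, "b": 115.812}}})
        tau, wl, sg = simulate_true_kinetics(cfg, "ery")
        assert wl[-1] == pytest.approx(180.0 / (16.714 + 0.534 * 180.0), abs=1e-4)
        assert wl[-1] == pytest.approx(1.5953, abs=1e-3)
        assert sg[np.where(tau == 120)[0][0]] < sg[-1]

    def test_starts_at_zero(self, default_config):
        for solute in default_config.solutes:
            tau, wl, sg = simulate_true_kinetics(default_config, solute)
            assert tau[0] == 0 and wl[0] == 0 and sg[0] == 0

    def test_kelvin_voigt_at_time_constant(self):
        cfg = SimConfig(time_grid=(0.0, 115.812),
                        solutes={"x": {"wl": {"family": "kelvin_voigt",
                                              "a": 1.0, "b": 30.0},
                                       "sg": {"family": "kelvin_voigt",
                                              "a": 0.871, "b": 115.812}}})
        _, _, sg = simulate_true_kinetics(cfg, "x")
        assert sg[-1] == pytest.approx(0.5506, abs=1e-3)

    def test_unknown_solute(self, default_config):
        with pytest.raises(KeyError):
            simulate_true_kinetics(default_config, "glycerol")

    def test_sucrose_highest_maltitol_lowest_wl(self, default_config):
        finals = {}
        for solute in default_config.solutes:
            _, wl, _ = simulate_true_kinetics(default_config, solute)
            finals[solute] = wl[-1]
        assert max(finals, key=finals.get) == "sucrose"
        assert min(finals, key=finals.get) == "maltitol"


class TestInvertToRaw:
    def test_identity_at_zero(self):
        assert invert_to_raw(0.0, 0.0, 20.0, 0.2) == (20.0, 0.2)

    def test_worked_example(self):
        m, s = invert_to_raw(0.625, 0.125, 20.0, 0.2)
        assert (m, s) == pytest.approx((18.0, 0.25))

    def test_round_trip_is_algebraic_identity(self):
        rng = np.random.default_rng(13)
        n = 1000
        s0 = rng.uniform(0.1, 0.4, n)
        m0 = rng.uniform(15.0, 25.0, n)
        sg = rng.uniform(0.0, 1.0, n)
        wl = rng.uniform(0.0, 2.0, n)
        keep = np.ones(n, bool)
        m, s = np.empty(n), np.empty(n)
        for i in range(n):
            try:
                m[i], s[i] = invert_to_raw(wl[i], sg[i], m0[i], s0[i])
            except InfeasibleKineticsError:
                keep[i] = False
        assert keep.sum() > 500
        sg_back = solid_gain(s[keep], m[keep], m0[keep], s0[keep])
        wl_back = water_loss(s[keep], m[keep], m0[keep], s0[keep])
        assert np.max(np.abs(sg_back - sg[keep])) < 1e-12
        assert np.max(np.abs(wl_back - wl[keep])) < 1e-12

    def test_infeasible_states_raise(self):
        with pytest.raises(InfeasibleKineticsError):
            invert_to_raw(0.0, -1.0, 20.0, 0.2)
        with pytest.raises(InfeasibleKineticsError):
            invert_to_raw(100.0, 0.0, 20.0, 0.2)  # more water than the sample holds


class TestGenerateStudy:
    def test_default_design_shape(self, default_config):
        measurements, initial, truth = generate_study(default_config)
        assert len(measurements) == 5 * 7 * 2
        assert len(initial) == 5 * 2
        assert set(truth["solutes"]) == set(DEFAULT_TRUE_MODELS)

    def test_fixed_seed_reproduces_study(self, default_config):
        a = generate_study(default_config)
        b = generate_study(default_config)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_zero_noise_lies_on_model_curves(self, noise_free_study):
        cfg, measurements, initial, _ = noise_free_study
        by_rep, _ = kinetics_table(measurements, initial)
        for solute in cfg.solutes:
            tau, wl, sg = simulate_true_kinetics(cfg, solute)
            sub = by_rep[(by_rep["solute"] == solute) & (by_rep["replicate"] == 1)]
            np.testing.assert_allclose(sub["WL"].to_numpy(), wl, atol=1e-12)
            np.testing.assert_allclose(sub["SG"].to_numpy(), sg, atol=1e-12)

    def test_initial_water_content_is_config_value(self, default_config):
        measurements, initial, _ = generate_study(default_config)
        t0 = measurements[measurements["tau_min"] == 0]
        wc0 = (1 - t0["dry_fraction"]) / t0["dry_fraction"]
        expected = (1 - default_config.s0) / default_config.s0
        np.testing.assert_allclose(wc0, expected)
        assert expected == pytest.approx(5.69, abs=0.01)

    def test_infeasible_truth_errors_before_noise(self):
        cfg = SimConfig(solutes={
            "bad": {"wl": {"family": "kelvin_voigt", "a": 50.0, "b": 10.0},
                    "sg": {"family": "kelvin_voigt", "a": 0.5, "b": 50.0}}})
        with pytest.raises(InfeasibleKineticsError):
            generate_study(cfg)

    def test_water_activity_proxy_column(self):
        cfg = SimConfig(aw_proxy=(0.9386, 0.005, 0.0), seed=2)
        measurements, _, _ = generate_study(cfg)
        assert "a_w" in measurements.columns
        aw0 = measurements.loc[measurements["tau_min"] == 0, "a_w"]
        np.testing.assert_allclose(aw0, 0.9386 + 0.005 * 5.689, atol=1e-3)


class TestEndToEndRecovery:
    def test_zero_noise_recovers_every_true_parameter(self, noise_free_study):
        """generate -> kinetics table -> fit returns the generating models."""
        cfg, measurements, initial, truth = noise_free_study
        _, avg = kinetics_table(measurements, initial)
        for solute, spec in truth["solutes"].items():
            for response, col in (("wl", "WL"), ("sg", "SG")):
                true = dict(spec[response])
                family = true.pop("family")
                sub = avg[avg["solute"] == solute].sort_values("tau_min")
                kwargs = {"y0": 0.0, "direction": 1} if family == "peleg" else {}
                fr = fit_model(sub["tau_min"].to_numpy(), sub[col].to_numpy(),
                               family, **kwargs)
                from odkinetics.models import params_to_dict
                fitted = params_to_dict(fr.params)
                for key, val in true.items():
                    if val == 0.0:
                        assert abs(fitted[key]) < 1e-6
                    else:
                        assert fitted[key] == pytest.approx(val, rel=1e-4), (
                            solute, response, key)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(time_grid=(30.0, 0.0))
        with pytest.raises(ValueError):
            SimConfig(replicates=0)
        with pytest.raises(ValueError):
            SimConfig(noise_sd_s=-0.1)


def test_config_yaml_round_trip(tmp_path, default_config):
    path = tmp_path / "study.yaml"
    default_config.to_yaml(path)
    loaded = SimConfig.from_yaml(path)
    assert loaded == default_config
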