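"""Batch simulator: kinetics, conservation, oxygen cap, rendering."""

import dataclasses

import numpy as np
import pytest

from flaskkpi import (SCENARIOS, SimulationConfig, SimulationError,
                      render_signals, scenario, simulate_batch)


def _config(**kw):
    base = dict(mu_max=0.5, x0=0.05, s0=10.0, y_xs=0.5, q_o2=2e-2,
                kla=500.0, c_star=2.1e-4, ks=0.01, lag_h=0.0,
                duration_h=6.0, dt_h=0.05, seed=0)
    base.update(kw)
    return SimulationConfig(**base)


class TestKinetics:
    def test_pure_exponential_limit(self):
        # huge substrate and transfer capacity: closed-form X0*exp(mu*t)
        cfg = _config(s0=1e4, kla=1e5, ks=0.0)
        truth = simulate_batch(cfg)
        expected = cfg.x0 * np.exp(cfg.mu_max * truth.times)
        np.testing.assert_allclose(truth.biomass, expected, rtol=1e-6)

    def test_lag_holds_biomass_constant(self):
        truth = simulate_batch(_config(lag_h=1.0))
        on_lag = truth.times <= 1.0
        np.testing.assert_array_equal(truth.biomass[on_lag], 0.05)
        assert truth.biomass[-1] > 0.05

    def test_mass_conservation(self):
        for name in SCENARIOS:
            truth = simulate_batch(scenario(name))
            c = truth.config
            gap = np.abs(c.y_xs * (c.s0 - truth.substrate)
                         - (truth.biomass - c.x0))
            assert gap.max() <= 1e-6 * c.x0, name

    def test_oxygen_cap_and_analytic_onset(self):
        # X_lim = kLa*c*/qO2 = 1.05 g/L, reached at t* ~ 6.1 h
        cfg = _config(ks=0.0, s0=50.0, kla=100.0, duration_h=10.0)
        truth = simulate_batch(cfg)
        otr_max = cfg.kla * cfg.c_star
        assert np.all(truth.our <= otr_max * (1 + 1e-12))
        x_lim = otr_max / cfg.q_o2
        t_star = np.log(x_lim / cfg.x0) / cfg.mu_max
        assert truth.t_o2_onset == pytest.approx(t_star, abs=cfg.dt_h)
        after = truth.times > truth.t_o2_onset
        np.testing.assert_allclose(truth.our[after], otr_max, rtol=1e-9)
        assert np.all(truth.do_percent[after] < 1e-6)

    def test_integrator_convergence_under_dt_halving(self):
        cfg = scenario("ecoli_biener")
        coarse = simulate_batch(cfg)
        fine = simulate_batch(dataclasses.replace(cfg, dt_h=cfg.dt_h / 2))
        rel = np.abs(fine.biomass[::2] - coarse.biomass) / coarse.biomass
        assert rel.max() < 1e-3

    def test_invalid_config_rejected(self):
        with pytest.raises(SimulationError):
            _config(mu_max=-1.0)
        with pytest.raises(SimulationError):
            _config(bsl_mode="nope")


class TestRendering:
    def test_zero_noise_matches_clean_curves(self):
        cfg = _config(noise={"do": 0, "bsl": 0, "our": 0, "ph": 0})
        truth = simulate_batch(cfg)
        rec = render_signals(truth)
        np.testing.assert_array_equal(rec.traces["do"].values,
                                      truth.do_percent)
        np.testing.assert_array_equal(rec.traces["our"].values, truth.our)
        np.testing.assert_array_equal(
            rec.traces["bsl"].values,
            cfg.bsl_offset + cfg.bsl_gain * truth.biomass)

    def test_same_seed_bit_identical(self):
        truth = simulate_batch(_config(seed=7))
        a, b = render_signals(truth), render_signals(truth)
        for ch in a.traces:
            np.testing.assert_array_equal(a.traces[ch].values,
                                          b.traces[ch].values)

    def test_do_stays_within_physical_bounds(self):
        truth = simulate_batch(_config(kla=100.0, seed=3))
        rec = render_signals(truth)
        do = rec.traces["do"].values
        sigma = truth.config.noise["do"] * np.ptp(truth.do_percent)
        assert do.min() >= 0.0
        assert do.max() <= 100.0 + 3.0 * sigma

    def test_dead_cell_backscatter_flat_then_rising(self):
        cfg = dataclasses.replace(scenario("cho"),
                                  noise={"do": 0, "bsl": 0, "our": 0, "ph": 0})
        truth = simulate_batch(cfg)
        rec = render_signals(truth)
        bsl = rec.traces["bsl"].values
        growing = truth.times <= truth.true_phase[1]
        after = truth.times >= truth.t_depletion + 10
        assert np.ptp(bsl[growing]) < 1e-9  # no live-biomass signal
        assert bsl[after][-1] > bsl[growing][0] + 0.5 * np.ptp(bsl)

    def test_equilibration_artifact_shapes_early_do(self):
        cfg = _config(lag_h=2.0, do_equilibration_drop=0.05,
                      noise={"do": 0, "bsl": 0, "our": 0, "ph": 0})
        rec = render_signals(simulate_batch(cfg))
        do = rec.traces["do"].values
        assert do[0] < do[10]  # rises during equilibration


class TestScenarios:
    def test_preset_growth_rates(self):
        assert scenario("ecoli_biener").mu_max == pytest.approx(0.60)
        assert scenario("vitis").mu_max == pytest.approx(0.008)

    def test_unknown_scenario_lists_presets(self):
        with pytest.raises(KeyError, match="ecoli_biener"):
            scenario("unknown")

    def test_presets_are_fresh_copies(self):
        a, b = scenario("cho"), scenario("cho")
        a.noise["do"] = 99.0
        assert b.noise["do"] != 99.0
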