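"""Anchors, peak/plateau features, window optimization and the full detector."""

import dataclasses

import numpy as np
import pytest

from flaskkpi import (DetectionError, DetectionParams, PhaseWindow, Recipe,
                      SignalTrace, detect_exponential_phase,
                      detect_peak_or_plateau, find_initial_phase_end,
                      find_phase_start, fit_exponential, initial_phase_window,
                      optimize_phase_end, optimize_phase_start, run_scenario)
from flaskkpi.simulator import (render_signals, scenario, scenario_recipe,
                                simulate_batch)


def _do_trace(values, dt=0.5):
    t = np.arange(len(values), dtype=float) * dt
    return SignalTrace(t, np.asarray(values, float), "do")


FAST = Recipe(growth_speed="fast")
PARAMS = DetectionParams.for_recipe(FAST)


class TestAnchors:
    def test_end_anchor_monotone_crossing(self):
        # DO falls 100 -> 5, crossing 15% at t = 5 h: minimum on [0, cross]
        do = _do_trace(np.linspace(100, 5, 11))  # crosses 15 at t=4.5..5
        t_min = find_initial_phase_end(do, 15.0)
        below = do.values <= 15.0
        assert t_min == do.times[np.flatnonzero(below)[0]]

    def test_end_anchor_dip_without_crossing(self):
        do = _do_trace([100, 80, 50, 30, 60, 80, 90], dt=1.0)
        assert find_initial_phase_end(do, 15.0) == 3.0

    def test_end_anchor_constant_trace_returns_last(self):
        do = _do_trace([100.0] * 8)
        assert find_initial_phase_end(do, 15.0) == do.times[-1]

    def test_start_anchor_equilibration_bump(self):
        # DO rises during early equilibration, then falls with growth:
        # the in-window maximum sits at the end of the bump (~1 h)
        cfg = scenario("ecoli_complex")
        cfg = dataclasses.replace(
            cfg, lag_h=1.0, do_equilibration_drop=0.05,
            do_equilibration_tau_h=0.3,
            noise={"do": 0, "bsl": 0, "our": 0, "ph": 0})
        rec = render_signals(simulate_batch(cfg))
        t_start = find_phase_start(rec.traces["do"], FAST, PARAMS)
        assert t_start == pytest.approx(1.0, abs=0.3)

    def test_start_anchor_monotone_decrease_is_origin(self):
        do = _do_trace(np.linspace(100, 20, 20), dt=0.25)
        assert find_phase_start(do, FAST, PARAMS) == 0.0

    def test_start_anchor_tie_breaks_latest(self):
        do = _do_trace([98, 100, 99, 100, 97, 90, 80, 60], dt=0.5)
        assert find_phase_start(do, FAST, PARAMS) == 1.5

    def test_start_anchor_respects_recipe_window(self):
        # a deliberately short search window pins the anchor inside it
        recipe = Recipe(growth_speed="fast", search_window_h=2.0)
        rec = run_scenario("ecoli_biener", seed=2).record
        t_start = find_phase_start(rec.traces["do"], recipe,
                                   DetectionParams.for_recipe(recipe))
        assert 0.0 <= t_start <= 2.0


class TestPeakOrPlateau:
    def test_clean_exponential_has_neither(self):
        t = np.arange(0, 8, 0.1)
        tr = SignalTrace(t, np.exp(0.6 * t), "our")
        assert detect_peak_or_plateau(tr, (0.0, 8.0), PARAMS) is None

    def test_oxygen_limitation_plateau_located(self):
        t = np.arange(0, 10, 0.1)
        tr = SignalTrace(t, np.exp(0.6 * np.minimum(t, 5.0)), "our")
        found = detect_peak_or_plateau(tr, (0.0, 10.0), PARAMS)
        assert found is not None
        t_plateau, kind = found
        assert kind == "plateau"
        assert t_plateau == pytest.approx(5.0, abs=0.8)

    def test_isolated_spike_is_a_peak(self):
        t = np.arange(0, 8, 0.1)
        v = np.exp(0.3 * t)
        v[40] += 0.5 * np.ptp(v)  # 50%-of-range spike at t = 4 h
        found = detect_peak_or_plateau(SignalTrace(t, v, "our"),
                                       (0.0, 8.0), PARAMS)
        assert found == (4.0, "peak")


class TestInitialWindow:
    def test_noiseless_window_matches_truth(self, clean_ecoli_run):
        cfg = clean_ecoli_run.config
        window, _ = initial_phase_window(
            clean_ecoli_run.record, scenario_recipe(cfg), "our",
            DetectionParams.for_recipe(scenario_recipe(cfg)))
        assert window.phase_start == pytest.approx(cfg.lag_h, abs=cfg.dt_h)
        assert window.phase_end <= window.o2_min_time

    def test_no_growth_record_fails(self):
        do = _do_trace([100.0] * 30, dt=0.25)
        our = SignalTrace(do.times, np.full(30, 1e-4), "our")
        from flaskkpi import CultivationRecord
        rec = CultivationRecord(traces={"do": do, "our": our})
        with pytest.raises(DetectionError):
            initial_phase_window(rec, FAST, "our", PARAMS)


class TestOptimizeStart:
    def test_pure_exponential_start_unchanged(self):
        t = np.arange(0, 6, 0.05)
        tr = SignalTrace(t, 1e-3 * np.exp(0.5 * t), "our")
        win = PhaseWindow(0.0, t[-1], 0.0, t[-1], "o2_min")
        assert optimize_phase_start(tr, win, PARAMS).phase_start == 0.0

    def test_lag_plateau_is_cut_off(self):
        cfg = dataclasses.replace(scenario("ecoli_complex"), lag_h=2.0,
                                  noise={"do": 0, "bsl": 0, "our": 0,
                                         "ph": 0})
        truth = simulate_batch(cfg)
        rec = render_signals(truth)
        tr = rec.traces["our"]
        win = PhaseWindow(0.0, truth.t_o2_onset, 0.0, truth.t_o2_onset,
                          "o2_min")
        out = optimize_phase_start(tr, win, PARAMS)
        assert out.phase_start == pytest.approx(2.0, abs=2 * cfg.dt_h)

    def test_disturbed_leading_points_skipped(self):
        t = np.arange(0, 5, 0.05)
        v = np.exp(0.5 * t)
        v[:3] *= 1.5
        tr = SignalTrace(t, v, "our")
        win = PhaseWindow(0.0, t[-1], 0.0, t[-1], "o2_min")
        out = optimize_phase_start(tr, win, PARAMS)
        assert t[3] <= out.phase_start <= t[6]


class TestOptimizeEnd:
    def test_pure_exponential_end_unchanged_perfect_fit(self):
        t = np.arange(0, 6, 0.05)
        tr = SignalTrace(t, 1e-3 * np.exp(0.5 * t), "our")
        win = PhaseWindow(0.0, t[-1], 0.0, t[-1], "o2_min")
        out, fit = optimize_phase_end(tr, win, PARAMS)
        assert out.phase_end == t[-1]
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_transition_to_plateau_trimmed(self):
        t = np.arange(0, 7, 0.05)
        tr = SignalTrace(t, np.exp(0.5 * np.minimum(t, 5.0)), "our")
        win = PhaseWindow(0.0, 7.0 - 0.05, 0.0, 7.0 - 0.05, "o2_min")
        out, _ = optimize_phase_end(tr, win, PARAMS)
        assert out.phase_end == pytest.approx(5.0, abs=3 * 0.05)

    def test_single_worsening_does_not_abort(self):
        # one disturbed sample after the midpoint: RMSE upticks once,
        # recovers, and the consecutive-count rule keeps the full window
        t = np.arange(0, 6, 0.05)
        v = 1e-3 * np.exp(0.5 * t)
        v[80] *= 1.04
        tr = SignalTrace(t, v, "our")
        win = PhaseWindow(0.0, t[-1], 0.0, t[-1], "o2_min")
        out, _ = optimize_phase_end(tr, win, PARAMS)
        assert out.phase_end == t[-1]


class TestFitExponential:
    def test_exact_on_clean_exponential(self):
        t = np.arange(0, 4, 0.1)
        fit = fit_exponential(t, 0.2 * np.exp(0.8 * t), t0=0.0)
        assert fit.mu == pytest.approx(0.8, rel=1e-12)
        assert fit.y0 == pytest.approx(0.2, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.rmse == pytest.approx(0.0, abs=1e-12)

    def test_additive_offset_recovered_in_fit_space(self):
        t = np.arange(0, 4, 0.1)
        v = 5.0 + 0.2 * np.exp(0.8 * t)
        fit = fit_exponential(t, v, t0=0.0, offset=5.0)
        assert fit.mu == pytest.approx(0.8, rel=1e-12)
        np.testing.assert_allclose(fit.predicted, v, rtol=1e-12)

    def test_too_few_positive_samples(self):
        t = np.arange(0, 1, 0.1)
        with pytest.raises(DetectionError):
            fit_exponential(t, -np.ones_like(t), t0=0.0)


class TestFullDetector:
    @pytest.mark.parametrize("name,rel_tol", [
        ("ecoli_complex", 0.01),   # fast grower, OUR signal
        ("vitis", 0.01),           # very slow grower, BSL signal
    ])
    def test_noiseless_parameter_recovery(self, name, rel_tol):
        run = run_scenario(name, seed=0, noise_scale=0.0)
        err = abs(run.fit.mu - run.truth.true_mu) / run.truth.true_mu
        assert err < rel_tol

    def test_slow_grower_with_noise(self):
        # BSL-based detection at twice the default backscatter noise
        run = run_scenario("vitis", seed=3, noise_scale=2.0)
        err = abs(run.fit.mu - run.truth.true_mu) / run.truth.true_mu
        assert err < 0.05

    def test_window_nesting_invariant(self):
        for name in ("ecoli_biener", "yeast_ypd", "cho"):
            for seed in (0, 1):
                run = run_scenario(name, seed=seed)
                recipe = scenario_recipe(run.config)
                params = DetectionParams.for_recipe(recipe)
                init, _ = initial_phase_window(
                    run.record, recipe, run.config.detection_signal, params)
                assert run.window.phase_start >= init.phase_start
                assert run.window.phase_end <= init.phase_end

    def test_optimization_never_worsens_fit_on_final_window(self):
        for seed in (0, 1, 2):
            run = run_scenario("yeast_ypd", seed=seed)
            recipe = scenario_recipe(run.config)
            params = DetectionParams.for_recipe(recipe)
            init, growth = initial_phase_window(run.record, recipe, "our",
                                                params)
            i0, i1 = growth.window_indices(run.window.phase_start,
                                           run.window.phase_end)
            j0, _ = growth.window_indices(init.phase_start, init.phase_end)
            initial_fit = fit_exponential(
                growth.times[j0:i1 + 1], growth.values[j0:i1 + 1],
                growth.times[j0])
            pred = initial_fit.predicted[i0 - j0:]
            obs = growth.values[i0:i1 + 1]
            ss_res = np.sum((obs - pred) ** 2)
            ss_tot = np.sum((obs - obs.mean()) ** 2)
            assert run.fit.r2 >= 1 - ss_res / ss_tot - 1e-9

    def test_determinism_bitwise(self):
        a = run_scenario("ecoli_biener", seed=5)
        b = run_scenario("ecoli_biener", seed=5)
        assert a.window == b.window
        assert a.fit.mu == b.fit.mu and a.fit.y0 == b.fit.y0
        np.testing.assert_array_equal(a.fit.predicted, b.fit.predicted)

    def test_auto_signal_falls_back_to_bsl(self):
        run = run_scenario("vitis", seed=0, signal="auto")
        assert run.fit.flags["signal"] == "bsl"

    def test_flat_record_raises(self):
        from flaskkpi import CultivationRecord
        t = np.arange(0, 10, 0.25)
        rec = CultivationRecord(traces={
            "do": SignalTrace(t, np.full(t.size, 100.0), "do"),
            "our": SignalTrace(t, np.full(t.size, 1e-4), "our")})
        with pytest.raises(DetectionError):
            detect_exponential_phase(rec, FAST, "our")
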