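"""End-to-end helper: simulate a scenario, detect the phase, compute KPIs.

This is the programmatic equivalent of running ``flaskkpi simulate``,
``flaskkpi detect`` and ``flaskkpi kpi`` in sequence on one flask, and the
entry point the validation suite uses for parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .kpi import KPIResult, compute_kpis
from .phase_detection import (DetectionParams, FitResult, PhaseWindow,
                              detect_exponential_phase)
from .signals_io import CultivationRecord, Recipe
from .simulator import (GroundTruth, SimulationConfig, render_signals,
                        scenario, scenario_recipe, simulate_batch)


@dataclass
class ScenarioRun:
    """Everything produced by one simulated flask evaluation."""

    config: SimulationConfig
    truth: GroundTruth
    record: CultivationRecord
    recipe: Recipe
    window: PhaseWindow
    fit: FitResult
    kpis: KPIResult


def run_scenario(name: str | None = None,
                 config: SimulationConfig | None = None,
                 seed: int = 0,
                 noise_scale: float = 1.0,
                 signal: str | None = None,
                 params: DetectionParams | None = None,
                 **config_overrides) -> ScenarioRun:
    """Simulate one flask and push it through detection and KPIs.

    ``noise_scale`` multiplies every channel's noise sigma (0 gives clean
    sensor curves).  ``signal`` overrides the scenario's preferred growth
    signal; extra keyword arguments override configuration fields.
    """
    if config is None:
        if name is None:
            raise ValueError("either a scenario name or a config is required")
        config = scenario(name)
    overrides = dict(config_overrides)
    overrides["seed"] = seed
    if noise_scale != 1.0:
        overrides["noise"] = {k: v * noise_scale
                              for k, v in config.noise.items()}
    config = replace(config, **overrides)

    truth = simulate_batch(config)
    record = render_signals(truth)
    recipe = scenario_recipe(config)
    window, fit = detect_exponential_phase(
        record, recipe, signal or config.detection_signal, params)

    our = record.traces.get("our")
    kpis = compute_kpis(
        window, fit, our_trace=our, c_x0=config.x0, c_s0=config.s0,
        x_end=float(truth.biomass[-1]), s_end=float(truth.substrate[-1]),
        biomass_units=config.biomass_units)
    return ScenarioRun(config=config, truth=truth, record=record,
                       recipe=recipe, window=window, fit=fit, kpis=kpis)
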