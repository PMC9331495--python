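"""Synthetic shake-flask cultivations with known ground truth.

The simulator integrates a Monod batch model with oxygen-transfer-limited
growth:

    dX/dt = mu(S) * X * min(1, OTR_max / (qO2 * X)),   t >= lag
    dS/dt = -(1/Y_XS) * dX/dt
    mu(S) = mu_max * S / (Ks + S)

where OTR_max = kLa * c* is the maximum oxygen transfer the flask can
sustain.  Oxygen uptake is OUR = min(qO2 * X, OTR_max): once the culture's
demand reaches the transfer capacity the OUR plateaus at kLa * c* and the
dissolved oxygen is pinned near zero — the oxygen-limitation signature
seen in fast microbial runs.  Dissolved oxygen follows the quasi-steady
balance DO/100 = 1 - OUR / OTR_max, consistent with the equilibrium
assumption used to convert DO into OUR during analysis; this keeps the
model analytically checkable (closed-form exponentials before limitation,
exact conservation Y_XS * (S0 - S) = X - X0).

The lag is modeled as mu = 0 for t < lag_h (a hard switch gives crisp
ground truth for start-detection tests).  Integration is classical RK4 at
the fixed sampling step, so records are bit-reproducible.

Rendering adds the sensor layer: per-channel Gaussian noise (standard
deviation expressed as a fraction of each channel's clean range),
backscattered light as gain * biomass + offset (or gain * dead-cell
density for animal cultures, where scattering tracks dying cells), an
optional device-style OUR channel, an optional early DO equilibration
artifact, and a purely cosmetic two-segment pH drift.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from .errors import SimulationError
from .signals_io import CultivationRecord, Recipe, SignalTrace

#: default sensor noise, std as fraction of the clean channel range.
#: DO optodes and the derived OUR are precise (sub-percent short-term
#: repeatability); backscattered light is the optically noisy channel.
DEFAULT_NOISE = {"do": 0.002, "our": 0.002, "bsl": 0.01, "ph": 0.002}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cultivation.

    Rates are h^-1, concentrations g L^-1 (or 1e6 cells mL^-1 for animal
    cultures — ``biomass_units`` records which), qO2 in mol per biomass
    unit per hour, kLa in h^-1 and c* in mol L^-1.  ``noise`` maps channel
    keys to Gaussian sigma as a fraction of the channel's clean range.
    """

    mu_max: float
    x0: float
    s0: float
    y_xs: float
    q_o2: float
    kla: float
    c_star: float = 2.1e-4
    ks: float = 0.01
    lag_h: float = 0.0
    duration_h: float = 12.0
    dt_h: float = 0.1
    noise: dict = field(default_factory=lambda: dict(DEFAULT_NOISE))
    bsl_gain: float = 30.0
    bsl_offset: float = 40.0
    bsl_mode: str = "biomass"  # or "dead_cells"
    dead_rate_h: float = 0.05
    do_equilibration_drop: float = 0.0  # fraction of saturation at t=0
    do_equilibration_tau_h: float = 0.3
    seed: int = 0
    scenario_name: str = ""
    biomass_units: str = "g L^-1"
    growth_speed: str = "fast"
    detection_signal: str = "our"
    include_our_channel: bool = True
    include_kla_metadata: bool = True

    def __post_init__(self):
        for name in ("mu_max", "x0", "s0", "y_xs", "q_o2", "kla", "c_star",
                     "dt_h", "duration_h"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        if self.ks < 0 or self.lag_h < 0:
            raise SimulationError("ks and lag_h must be non-negative")
        if any(s < 0 for s in self.noise.values()):
            raise SimulationError("noise sigmas must be non-negative")
        if self.bsl_mode not in ("biomass", "dead_cells"):
            raise SimulationError(f"unknown bsl_mode {self.bsl_mode!r}")


@dataclass
class GroundTruth:
    """Clean curves and true parameters of a simulated batch."""

    config: SimulationConfig
    times: np.ndarray
    biomass: np.ndarray          # X(t)
    substrate: np.ndarray        # S(t)
    do_percent: np.ndarray       # quasi-steady DO, % air saturation
    our: np.ndarray              # min(qO2*X, kLa*c*), mol L^-1 h^-1
    dead_cells: np.ndarray       # D(t), same units as biomass
    true_mu: float
    true_qo2: float
    true_yxs: float
    true_phase: tuple[float, float]
    t_o2_onset: float            # oxygen-limitation onset (inf if never)
    t_depletion: float           # substrate exhaustion (inf if never)

    def to_json(self, path) -> None:
        def finite(x):
            return x if math.isfinite(x) else None  # inf -> null

        payload = {
            "config": asdict(self.config),
            "true_mu": self.true_mu,
            "true_qo2": self.true_qo2,
            "true_yxs": self.true_yxs,
            "true_phase": list(self.true_phase),
            "t_o2_onset": finite(self.t_o2_onset),
            "t_depletion": finite(self.t_depletion),
            "x_max": float(self.biomass.max()),
            "s_end": float(self.substrate[-1]),
            "x_end": float(self.biomass[-1]),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, allow_nan=False)
            fh.write("\n")


def simulate_batch(config: SimulationConfig) -> GroundTruth:
    """Integrate the batch model and return clean curves plus truth."""
    c = config
    otr_max = c.kla * c.c_star
    n = int(round(c.duration_h / c.dt_h)) + 1
    times = np.arange(n) * c.dt_h

    def deriv(t, x, s):
        s = max(s, 0.0)
        if c.ks > 0:
            mu = c.mu_max * s / (c.ks + s)
        else:
            mu = c.mu_max if s > 0 else 0.0
        demand = c.q_o2 * x
        cap = min(1.0, otr_max / demand) if demand > otr_max else 1.0
        dx = mu * x * cap
        return dx, -dx / c.y_xs

    X = np.empty(n)
    S = np.empty(n)
    # growth is switched off during the lag, so those samples sit exactly
    # on the initial state and integration starts at t = lag_h: no RK4
    # stage ever straddles the lag discontinuity
    on_lag = times <= c.lag_h
    k_lag = int(on_lag.sum())  # samples fully inside the lag
    X[:k_lag], S[:k_lag] = c.x0, c.s0
    # RK4 sub-stepping keeps the sharp substrate-exhaustion transition
    # resolved regardless of the sampling interval
    n_sub = 8
    x, s = c.x0, c.s0
    t_now = min(c.lag_h, c.duration_h)
    for k in range(max(k_lag, 1), n):
        h = (times[k] - t_now) / n_sub
        for j in range(n_sub):
            t = t_now + j * h
            k1x, k1s = deriv(t, x, s)
            k2x, k2s = deriv(t + h / 2, x + h / 2 * k1x, s + h / 2 * k1s)
            k3x, k3s = deriv(t + h / 2, x + h / 2 * k2x, s + h / 2 * k2s)
            k4x, k4s = deriv(t + h, x + h * k3x, s + h * k3s)
            x = x + h / 6 * (k1x + 2 * k2x + 2 * k3x + k4x)
            s = s + h / 6 * (k1s + 2 * k2s + 2 * k3s + k4s)
            if s < 0.0:
                if s < -0.05 * c.s0:
                    raise SimulationError(
                        f"substrate driven to {s:.3g} at t={t:.3g} h; "
                        "use a smaller dt_h"
                    )
                # project onto S = 0 along the conservation line
                # X + Y_XS * S = const, i.e. only the substrate that was
                # actually available is converted to biomass
                x = x + c.y_xs * s
                s = 0.0
        t_now = times[k]
        X[k], S[k] = x, s
    our = np.minimum(c.q_o2 * X, otr_max)
    do = 100.0 * (1.0 - our / otr_max)

    limited = np.flatnonzero(c.q_o2 * X >= otr_max * (1.0 - 1e-12))
    t_o2 = float(times[limited[0]]) if limited.size else float("inf")
    # the exponential regime ends, substrate-wise, once mu(S) has dropped
    # to 90% of mu_max
    starved = np.flatnonzero(S <= 9.0 * c.ks)
    t_dep = float(times[starved[0]]) if starved.size else float("inf")

    depleted = np.flatnonzero(S <= c.ks)
    dead = np.zeros(n)
    if depleted.size:
        t0 = times[depleted[0]]
        after = times >= t0
        dead[after] = X[after] * (1.0 - np.exp(-c.dead_rate_h
                                               * (times[after] - t0)))

    phase_end = min(t_o2, t_dep, c.duration_h)
    return GroundTruth(
        config=c, times=times, biomass=X, substrate=S, do_percent=do,
        our=our, dead_cells=dead, true_mu=c.mu_max, true_qo2=c.q_o2,
        true_yxs=c.y_xs, true_phase=(c.lag_h, phase_end),
        t_o2_onset=t_o2, t_depletion=t_dep,
    )


def render_signals(truth: GroundTruth,
                   config: SimulationConfig | None = None
                   ) -> CultivationRecord:
    """Turn clean curves into a noisy sensor record.

    Reproducible from ``config.seed``; with all noise sigmas at zero the
    channels equal the clean curves exactly.
    """
    c = config or truth.config
    rng = np.random.default_rng(c.seed)
    t = truth.times

    def noisy(clean, channel):
        sigma = c.noise.get(channel, 0.0) * float(np.ptp(clean))
        if sigma == 0.0:
            return clean.copy(), 0.0
        return clean + rng.normal(0.0, sigma, clean.size), sigma

    do_clean = truth.do_percent
    if c.do_equilibration_drop > 0:
        do_clean = do_clean * (1.0 - c.do_equilibration_drop
                               * np.exp(-t / c.do_equilibration_tau_h))
    do, do_sigma = noisy(do_clean, "do")
    do = np.clip(do, 0.0, 100.0 + 3.0 * do_sigma)

    if c.bsl_mode == "biomass":
        bsl_clean = c.bsl_offset + c.bsl_gain * truth.biomass
    else:
        bsl_clean = c.bsl_offset + c.bsl_gain * truth.dead_cells
    bsl, _ = noisy(bsl_clean, "bsl")

    # cosmetic pH drift: acidification while growing, drift up afterwards
    x_rel = (truth.biomass - truth.biomass[0]) / max(
        float(np.ptp(truth.biomass)), 1e-30)
    ph_clean = 7.0 - 0.5 * x_rel
    if np.isfinite(truth.t_depletion):
        after = t >= truth.t_depletion
        ph_clean = ph_clean + np.where(
            after, 0.4 * (1 - np.exp(-(t - truth.t_depletion) / 5.0)), 0.0)
    ph, _ = noisy(ph_clean, "ph")

    traces = {
        "do": SignalTrace(t.copy(), do, "do"),
        "bsl": SignalTrace(t.copy(), bsl, "bsl"),
        "ph": SignalTrace(t.copy(), ph, "ph"),
    }
    if c.include_our_channel:
        our, _ = noisy(truth.our, "our")
        traces["our"] = SignalTrace(t.copy(), our, "our")

    return CultivationRecord(
        traces=traces,
        kla=c.kla if c.include_kla_metadata else None,
        c_star=c.c_star if c.include_kla_metadata else None,
        c_x0=c.x0, c_s0=c.s0,
        flask_label=c.scenario_name or "synthetic",
    )


# ---------------------------------------------------------------------------
# preset scenarios
# ---------------------------------------------------------------------------

def _presets() -> dict[str, SimulationConfig]:
    return {
        # E. coli in chemically defined (Biener-style) glucose medium
        "ecoli_biener": SimulationConfig(
            mu_max=0.60, x0=0.05, s0=10.0, y_xs=0.434, q_o2=2.13e-2,
            kla=150.0, c_star=2.1e-4, lag_h=1.0, duration_h=12.0, dt_h=0.1,
            scenario_name="ecoli_biener", growth_speed="fast"),
        # E. coli in rich complex medium (TB-like): fast growth,
        # glycerin as the quantified carbon source
        "ecoli_complex": SimulationConfig(
            mu_max=1.3, x0=0.05, s0=5.0, y_xs=1.679, q_o2=1.82e-2,
            kla=180.0, c_star=2.1e-4, lag_h=0.5, duration_h=8.0, dt_h=0.1,
            scenario_name="ecoli_complex", growth_speed="fast"),
        # S. cerevisiae on YPD glucose
        "yeast_ypd": SimulationConfig(
            mu_max=0.47, x0=0.1, s0=20.0, y_xs=0.812, q_o2=2.59e-3,
            kla=100.0, c_star=2.1e-4, lag_h=1.5, duration_h=24.0, dt_h=0.15,
            scenario_name="yeast_ypd", growth_speed="fast"),
        # V. vinifera plant suspension: very slow growth, dense inoculum,
        # BSL is the usable signal and the device computes no OUR
        "vitis": SimulationConfig(
            mu_max=0.008, x0=3.2, s0=25.5, y_xs=0.474, q_o2=2.29e-4,
            kla=18.0, c_star=2.1e-4, lag_h=72.0, duration_h=336.0, dt_h=0.5,
            bsl_gain=25.0, bsl_offset=40.0,
            scenario_name="vitis", growth_speed="slow",
            detection_signal="bsl", include_our_channel=False,
            include_kla_metadata=False),
        # CHO culture: slow growth in a CO2 incubator, BSL tracks dead
        # cells, OUR is the informative signal
        "cho": SimulationConfig(
            mu_max=0.035, x0=0.3, s0=5.0, y_xs=1.99, q_o2=2.88e-4,
            kla=20.0, c_star=2.0e-4, lag_h=12.0, duration_h=160.0, dt_h=0.25,
            bsl_gain=15.0, bsl_offset=30.0, bsl_mode="dead_cells",
            scenario_name="cho", growth_speed="medium",
            biomass_units="1e6 cells mL^-1"),
        # baffled-flask yeast run: bubbles make the backscatter channel
        # noisy; OUR remains the signal of choice
        "noisy_baffled": SimulationConfig(
            mu_max=0.47, x0=0.1, s0=20.0, y_xs=0.812, q_o2=2.59e-3,
            kla=140.0, c_star=2.1e-4, lag_h=1.5, duration_h=24.0, dt_h=0.15,
            noise={**DEFAULT_NOISE, "bsl": 0.05},
            scenario_name="noisy_baffled", growth_speed="fast"),
    }


SCENARIOS = tuple(sorted(_presets()))


def scenario(name: str) -> SimulationConfig:
    """Return a fresh preset configuration by name."""
    presets = _presets()
    if name not in presets:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(SCENARIOS)}"
        )
    return presets[name]


def scenario_recipe(config: SimulationConfig) -> Recipe:
    """The recipe a user would pair with a scenario's organism."""
    return Recipe(growth_speed=config.growth_speed)
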