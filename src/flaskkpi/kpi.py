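"""Strain-characterization KPIs from a detected exponential phase.

Four quantities summarize a flask for strain/media comparison:

* mu_max — maximum specific growth rate (h^-1), the slope of the
  exponential fit over the detected phase;
* q_O2 — cell-specific oxygen consumption rate (mol per g, or per cell,
  per hour), from OUR = q_O2 * C_X with the biomass trajectory
  reconstructed from the OUR (q_O2 is assumed constant during the
  exponential phase, so C_X is proportional to the OUR once C_X,0 is
  known);
* Y_X/S and Y_P/S — biomass- and product-per-substrate yields from
  endpoint differences;
* C_X,max — maximum achieved biomass concentration.

Units are carried as labels and checked for consistency but never
auto-converted (microbial KPIs are g-based, animal-cell KPIs cell-based).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ComputationError
from .phase_detection import FitResult, PhaseWindow
from .signals_io import SignalTrace

log = logging.getLogger(__name__)


@dataclass
class KPIResult:
    """KPIs of one flask; unavailable entries are None with a reason."""

    mu_max: float | None = None
    q_o2: float | None = None
    y_xs: float | None = None
    y_ps: float | None = None
    c_x_max: float | None = None
    c_x_max_time: float | None = None
    provenance: str = ""          # signal that produced mu_max
    biomass_units: str = "g L^-1"
    flags: dict = field(default_factory=dict)
    reasons: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mu_max": self.mu_max, "q_o2": self.q_o2, "y_xs": self.y_xs,
            "y_ps": self.y_ps, "c_x_max": self.c_x_max,
            "c_x_max_time": self.c_x_max_time,
            "provenance": self.provenance,
            "biomass_units": self.biomass_units,
            "flags": self.flags, "reasons": self.reasons,
        }


def mu_from_fit(fit: FitResult) -> float:
    """Growth rate of a phase fit (h^-1); non-positive values are flagged
    in the fit, not fatal."""
    if fit.mu <= 0:
        log.warning("mu_max is non-positive (%.4g h^-1); flagging", fit.mu)
        fit.flags["nonpositive_mu"] = True
    return float(fit.mu)


def biomass_from_our(our_trace: SignalTrace, c_x0: float,
                     window: PhaseWindow,
                     our_at_start: float | None = None) -> SignalTrace:
    """Biomass trajectory C_X(t) = C_X,0 * OUR(t) / OUR(phase_start).

    Valid while q_O2 is constant, i.e. inside the exponential phase.  The
    denominator defaults to the raw OUR sample at phase_start; callers who
    have an exponential fit of the OUR should pass its fitted start value
    (``fit.y0``) instead, which estimates the same quantity from the whole
    window rather than from a single noisy sample.
    """
    if c_x0 is None or c_x0 <= 0:
        raise ComputationError(f"C_X,0 must be positive, got {c_x0}")
    i0, i1 = our_trace.window_indices(window.phase_start, window.phase_end)
    if i1 - i0 + 1 < 2:
        raise ComputationError("phase window holds fewer than 2 OUR samples")
    our = our_trace.values[i0:i1 + 1]
    denom = float(our[0]) if our_at_start is None else float(our_at_start)
    if denom <= 0:
        raise ComputationError(
            f"OUR at phase_start must be positive, got {denom:.4g}"
        )
    if np.any(our <= 0):
        raise ComputationError("OUR must be positive throughout the window")
    return SignalTrace(our_trace.times[i0:i1 + 1].copy(),
                       c_x0 * our / denom, "biomass")


def compute_qo2(our_trace: SignalTrace, biomass_trace: SignalTrace,
                window: PhaseWindow) -> tuple[float, np.ndarray]:
    """Specific oxygen consumption rate over the exponential window.

    Returns the median of the pointwise ratios OUR(t)/C_X(t) (robust to
    endpoint noise) together with the ratios themselves for diagnostics.
    """
    i0, i1 = our_trace.window_indices(window.phase_start, window.phase_end)
    j0, j1 = biomass_trace.window_indices(window.phase_start,
                                          window.phase_end)
    our = our_trace.values[i0:i1 + 1]
    cx = biomass_trace.values[j0:j1 + 1]
    if our.size == 0 or cx.size == 0:
        raise ComputationError("empty phase window")
    if our.size != cx.size or not np.allclose(
            our_trace.times[i0:i1 + 1], biomass_trace.times[j0:j1 + 1]):
        raise ComputationError("OUR and biomass traces do not share a grid "
                               "over the window")
    if np.any(cx <= 0):
        raise ComputationError("biomass must be positive throughout the "
                               "window")
    ratios = our / cx
    return float(np.median(ratios)), ratios


def compute_yield(delta_amount: float, delta_substrate: float) -> float:
    """Yield coefficient from endpoint differences.

    ``delta_amount`` is the biomass (or product) formed, X_end - X_0;
    ``delta_substrate`` the substrate consumed, S_0 - S_end (> 0).
    """
    if delta_substrate <= 0:
        raise ComputationError(
            f"substrate consumption must be positive, got {delta_substrate}"
        )
    return float(delta_amount) / float(delta_substrate)


def compute_cx_max(biomass_trace: SignalTrace) -> tuple[float, float]:
    """Maximum biomass concentration and the time it was reached."""
    i = int(np.argmax(biomass_trace.values))
    return float(biomass_trace.values[i]), float(biomass_trace.times[i])


def compute_kpis(window: PhaseWindow, fit: FitResult,
                 our_trace: SignalTrace | None = None,
                 c_x0: float | None = None,
                 c_s0: float | None = None,
                 x_end: float | None = None,
                 s_end: float | None = None,
                 p_end: float | None = None,
                 p0: float = 0.0,
                 biomass_units: str = "g L^-1") -> KPIResult:
    """Assemble a :class:`KPIResult` from whatever inputs are available.

    Missing metadata never fails the call: the affected KPI is left None
    with a reason recorded, the rest are computed.  ``x_end``/``s_end``/
    ``p_end`` are endpoint measurements (offline samples or simulator
    truth) used for yields and, when present, C_X,max.
    """
    result = KPIResult(provenance=fit.flags.get("signal", ""),
                       biomass_units=biomass_units)
    result.mu_max = mu_from_fit(fit)
    if fit.mu <= 0:
        result.flags["nonpositive_mu"] = True

    if our_trace is None:
        result.reasons["q_o2"] = "no OUR trace available"
    elif c_x0 is None:
        result.reasons["q_o2"] = "initial biomass C_X,0 unknown"
    else:
        # OUR at growth onset anchors the biomass reconstruction at C_X,0.
        # The OUR is flat at qO2 * C_X,0 throughout the lag (biomass does
        # not change before growth starts), so averaging the samples up to
        # phase_start estimates that level without the bias of a back-
        # extrapolated fit and with far less variance than a single
        # sample.
        i = int(np.searchsorted(our_trace.times, window.phase_start))
        if i >= 5:
            # median over the pre-start samples: robust if the detected
            # start overshot the lag by a few samples
            our_start = float(np.median(our_trace.values[max(0, i - 24):i]))
        else:
            our_start = float(np.median(
                our_trace.values[i:min(our_trace.n, i + 5)]))
        try:
            biomass = biomass_from_our(our_trace, c_x0, window, our_start)
            result.q_o2, _ = compute_qo2(our_trace, biomass, window)
            result.c_x_max, result.c_x_max_time = compute_cx_max(biomass)
        except ComputationError as exc:
            result.reasons["q_o2"] = str(exc)

    if x_end is not None:
        if result.c_x_max is None or x_end > result.c_x_max:
            result.c_x_max, result.c_x_max_time = float(x_end), None
    if result.c_x_max is None:
        result.reasons["c_x_max"] = "no biomass trajectory or endpoint"

    if c_s0 is None or s_end is None:
        result.reasons["y_xs"] = "substrate endpoints unknown"
        result.reasons["y_ps"] = "substrate endpoints unknown"
    else:
        try:
            if x_end is not None and c_x0 is not None:
                result.y_xs = compute_yield(x_end - c_x0, c_s0 - s_end)
            else:
                result.reasons["y_xs"] = "biomass endpoints unknown"
            if p_end is not None:
                result.y_ps = compute_yield(p_end - p0, c_s0 - s_end)
            else:
                result.reasons["y_ps"] = "no product measurement"
        except ComputationError as exc:
            result.reasons.setdefault("y_xs", str(exc))
            result.reasons.setdefault("y_ps", str(exc))
    return result
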