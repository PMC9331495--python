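"""Oxygen physics and shared signal conditioning.

The dissolved-oxygen optode reports % air saturation; 100 % corresponds to
the medium's saturation concentration c* = p * xO2 * H(T) (Henry's law),
with total pressure p (atm), oxygen mole fraction xO2 of the incubator
atmosphere and the temperature-dependent Henry solubility H
(mol L^-1 atm^-1).  Under quasi-steady conditions the oxygen transfer rate
equals the uptake rate of the cells:

    OUR = OTR = kLa * (c* - c_O2) = kLa * c* * (1 - DO/100)

so a calibrated kLa converts a DO trace into an OUR trace point by point.

This module also hosts the noise estimate and the Savitzky-Golay smoothing
shared by the phase detector.  H is supplied by the user at the cultivation
temperature; no Henry-law temperature correlation is shipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import ConfigurationError, ParameterError
from .signals_io import SignalTrace

log = logging.getLogger(__name__)


def o2_saturation(p: float, x_o2: float, henry: float) -> float:
    """Saturation concentration c* = p * xO2 * H in mol L^-1.

    Parameters are the total pressure (atm), the O2 mole fraction of the
    gas phase (0.2095 for air, lower in CO2 incubators) and the Henry
    solubility at cultivation temperature (mol L^-1 atm^-1).
    """
    if p < 0 or henry < 0 or not (0.0 <= x_o2 <= 1.0):
        raise ConfigurationError(
            f"invalid saturation inputs p={p}, xO2={x_o2}, H={henry}"
        )
    return p * x_o2 * henry


@dataclass
class OxygenContext:
    """Physical constants needed to convert DO into OUR.

    ``c_star`` may be given directly (e.g. from a blank measurement);
    otherwise it is derived from p, xO2 and H.
    """

    kla: float
    p: float = 1.0
    x_o2: float = 0.2095
    henry: float | None = None
    c_star: float | None = None

    def __post_init__(self):
        if self.kla is None or self.kla <= 0:
            raise ConfigurationError(f"kLa must be positive, got {self.kla}")
        if self.c_star is None:
            if self.henry is None:
                raise ConfigurationError(
                    "either c_star or the Henry solubility must be given"
                )
            self.c_star = o2_saturation(self.p, self.x_o2, self.henry)
        if self.c_star <= 0:
            raise ConfigurationError(f"c* must be positive, got {self.c_star}")


def our_from_do(do_trace: SignalTrace, ctx: OxygenContext) -> SignalTrace:
    """Convert a DO trace (% air saturation) to OUR (mol L^-1 h^-1).

    Uses the steady-state balance OUR = kLa * c* * (1 - DO/100) on the
    input grid.  Supersaturated samples (DO > 100 %) yield negative OUR
    values which are retained but flagged.
    """
    if do_trace.channel != "do":
        raise ConfigurationError(
            f"our_from_do expects a DO trace, got channel {do_trace.channel!r}"
        )
    our = ctx.kla * ctx.c_star * (1.0 - do_trace.values / 100.0)
    flags = {}
    if np.any(our < 0):
        flags["supersaturation"] = True
        log.warning("DO exceeds 100%% air saturation at %d samples; OUR is "
                    "negative there", int((our < 0).sum()))
    return SignalTrace(do_trace.times.copy(), our, "our",
                       "mol L^-1 h^-1", flags)


def _odd_window(target: int, n: int, minimum: int = 5) -> int:
    """Smallest odd integer >= max(target, minimum), capped at n (odd)."""
    w = max(int(target), minimum)
    if w % 2 == 0:
        w += 1
    if w > n:
        w = n if n % 2 == 1 else n - 1
    return w


def estimate_noise(trace: SignalTrace) -> float:
    """Noise-to-signal ratio of a trace.

    Residual standard deviation after a local quadratic (Savitzky-Golay)
    detrend, divided by the value range.  A short 9-point window keeps the
    detrend bias negligible even for strongly curved (exponential) signals,
    so the residuals reflect sensor noise.  Returns 0 for a constant trace.
    """
    if trace.n < 7:
        raise ParameterError("estimate_noise needs at least 7 samples")
    rng = float(np.ptp(trace.values))
    if rng == 0.0:
        return 0.0
    window = _odd_window(9, trace.n)
    trend = savgol_filter(trace.values, window, 2, mode="interp")
    return float(np.std(trace.values - trend) / rng)


def smooth_trace(trace: SignalTrace, window_points: int | None = None,
                 polyorder: int = 2) -> SignalTrace:
    """Savitzky-Golay smoothing on the trace's own time grid.

    The default window is the smallest odd integer covering 5 % of the
    trace length (minimum 5 points).  Endpoints are handled by polynomial
    extrapolation within the edge windows, so a polynomial of degree
    <= ``polyorder`` is reproduced exactly everywhere.  The filter assumes
    an equidistant grid; for irregular grids it is applied on an index
    basis with a logged warning.
    """
    if window_points is None:
        window_points = _odd_window(round(0.05 * trace.n), trace.n)
    window_points = int(window_points)
    if window_points % 2 == 0:
        raise ParameterError(f"window_points must be odd, got {window_points}")
    if window_points > trace.n:
        raise ParameterError(
            f"window ({window_points}) longer than trace ({trace.n})"
        )
    if window_points <= polyorder:
        raise ParameterError(
            f"window ({window_points}) must exceed polyorder ({polyorder})"
        )
    dt = np.diff(trace.times)
    if np.ptp(dt) > 1e-9 * np.median(dt):
        log.warning("channel %r: irregular time grid; Savitzky-Golay filter "
                    "applied on an index basis", trace.channel)
    smoothed = savgol_filter(trace.values, window_points, polyorder,
                             mode="interp")
    return trace.with_values(smoothed, smoothed=True)
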