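"""Automatic detection of the exponential growth phase.

The detector mirrors how an experienced operator reads a shake-flask run:

1. *Initial phase fitting.*  Anchors are taken from the dissolved-oxygen
   signal: the DO maximum inside a growth-speed-dependent search window
   marks the candidate phase start (growth onset ends the equilibration /
   lag plateau), and the DO minimum before the signal crosses the recipe's
   oxygen threshold marks the candidate phase end.  Between those anchors
   the growth signal (OUR or backscattered light) is scanned for a peak or
   a plateau — the signatures of a metabolic shift or oxygen limitation —
   which, when present, replaces the DO minimum as the candidate end.
   Noisy growth signals are smoothed first.

2. *Start optimization.*  An exponential reference curve is fitted over
   the upper half of the candidate window and extrapolated backward; a
   cumulative-residual (CUSUM) walk from the middle of the window toward
   the start finds where the data systematically leave that curve — the
   remnant of the lag — and the start is moved to just before the
   departure.  The pass is repeated until the start is stable, which lets
   a window contaminated by a long lag converge in a few passes.

3. *End optimization.*  A temporary fit over the first half of the window
   is extended one sample at a time; when the RMSE of the refit worsens
   several times in a row the growth phase is assumed to be over and the
   end is moved back to just before the degradation began.

The exponential model is C(t) = y0 * exp(mu * (t - t0)) (plus an additive
baseline for backscattered-light signals).  Fitting is ordinary least
squares on the log-transformed signal — deterministic and initialization
free — while R^2 and RMSE are always evaluated in the original signal
space.  The optimized window is always nested inside the initial one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.signal import find_peaks, medfilt, savgol_filter

from .errors import ConfigurationError, DetectionError, ParameterError
from .oxygen_transfer import (OxygenContext, _odd_window, estimate_noise,
                              our_from_do, smooth_trace)
from .signals_io import CultivationRecord, Recipe, SignalTrace

log = logging.getLogger(__name__)

#: start-search window (h) per growth-speed class; brackets the lag and
#: equilibration region for typical organisms of each class
SEARCH_WINDOW_H = {"fast": 6.0, "medium": 48.0, "slow": 240.0}

#: minimum plateau duration (h) per growth-speed class
PLATEAU_MIN_DURATION_H = {"fast": 0.5, "medium": 2.0, "slow": 10.0}


@dataclass
class PhaseWindow:
    """Detected boundaries of the exponential growth phase (hours)."""

    phase_start: float
    phase_end: float
    o2_max_time: float
    o2_min_time: float
    end_source: str  # "peak" | "plateau" | "o2_min"

    def __post_init__(self):
        if not self.phase_start < self.phase_end:
            raise DetectionError(
                f"phase_start ({self.phase_start}) must precede phase_end "
                f"({self.phase_end})",
                diagnostics={"o2_max_time": self.o2_max_time,
                             "o2_min_time": self.o2_min_time,
                             "end_source": self.end_source},
            )


@dataclass
class FitResult:
    """Exponential fit y = offset + y0 * exp(mu * (t - t0)).

    ``r2`` and ``rmse`` are computed in the original signal space against
    the window's observations; ``predicted`` is the fitted curve on the
    window's time grid.
    """

    y0: float
    mu: float
    t0: float
    r2: float
    rmse: float
    predicted: np.ndarray
    n_points: int
    offset: float = 0.0
    flags: dict = field(default_factory=dict)


@dataclass
class DetectionParams:
    """Tunable constants of the detector.

    The abort rules translate "the fit worsened substantially" into
    numbers: the start loop aborts when the cumulative standardized
    residual between the fitted curve and the data exceeds
    ``start_abort_z`` times its random-walk scale (see
    :func:`optimize_phase_start`); the end loop aborts after
    ``rmse_abort_count`` consecutive relative RMSE increases of more than
    ``rmse_increase_frac`` (requiring several consecutive worsenings
    keeps a single noisy point from ending the phase early, and the
    relative margin plus an absolute floor keeps float-level jitter on
    near-perfect fits from triggering at all).
    """

    start_abort_z: float = 8.0
    start_slack_frac: float = 0.02
    rmse_abort_count: int = 3
    rmse_increase_frac: float = 0.05
    search_window_h: dict = field(
        default_factory=lambda: dict(SEARCH_WINDOW_H))
    peak_prominence_frac: float = 0.3
    plateau_slope_frac: float = 0.05
    plateau_min_duration_h: float = 1.0
    noise_threshold: float = 0.02
    smoothing_window_points: int | None = None
    smoothing_polyorder: int = 2
    max_start_passes: int = 25

    def __post_init__(self):
        if self.start_abort_z <= 0:
            raise ParameterError("start_abort_z must be positive")
        if self.rmse_abort_count < 1:
            raise ParameterError("rmse_abort_count must be >= 1")
        if any(w <= 0 for w in self.search_window_h.values()):
            raise ParameterError("search windows must be positive")

    @classmethod
    def for_recipe(cls, recipe: Recipe, **overrides) -> "DetectionParams":
        """Defaults resolved for a recipe's growth-speed class."""
        kwargs = {
            "plateau_min_duration_h": PLATEAU_MIN_DURATION_H[
                recipe.growth_speed],
        }
        if recipe.search_window_h is not None:
            windows = dict(SEARCH_WINDOW_H)
            windows[recipe.growth_speed] = recipe.search_window_h
            kwargs["search_window_h"] = windows
        for name in ("start_abort_z", "rmse_abort_count", "noise_threshold",
                     "plateau_min_duration_h", "smoothing_window_points",
                     "smoothing_polyorder"):
            value = getattr(recipe, name, None)
            if value is not None:
                kwargs[name] = value
        kwargs.update(overrides)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# exponential fitting
# ---------------------------------------------------------------------------

def fit_exponential(times: np.ndarray, values: np.ndarray, t0: float,
                    offset: float = 0.0) -> FitResult:
    """Log-linear least-squares fit of an exponential.

    Samples that are non-positive after baseline subtraction are excluded
    from the regression; metrics are evaluated on all window samples.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    z = values - offset
    pos = z > 0
    if int(pos.sum()) < 2:
        raise DetectionError(
            "fewer than 2 positive samples in the fit window"
        )
    slope, intercept = np.polyfit(times[pos] - t0, np.log(z[pos]), 1)
    predicted = offset + np.exp(intercept + slope * (times - t0))
    resid = values - predicted
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((values - values.mean()) ** 2))
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        r2 = 1.0 if ss_res == 0.0 else -math.inf
    rmse = math.sqrt(ss_res / values.size)
    flags = {}
    if slope <= 0:
        flags["nonpositive_mu"] = True
    if not pos.all():
        flags["excluded_points"] = int((~pos).sum())
    return FitResult(y0=float(np.exp(intercept)), mu=float(slope), t0=t0,
                     r2=r2, rmse=rmse, predicted=predicted,
                     n_points=int(pos.sum()), offset=offset, flags=flags)


def estimate_baseline(times: np.ndarray, values: np.ndarray) -> float:
    """Additive baseline of a backscattered-light window.

    BSL is proportional to biomass plus an optical offset from the flask
    and medium.  The offset is estimated as the constant c in
    [0, min(values)) for which values - c is closest to a pure exponential
    (smallest linear-space SSE of the log-linear fit).  On a clean signal
    this recovers the optical offset exactly, so the log-fit then sees the
    biomass-proportional part alone.
    """
    vmin = float(np.min(values))
    if vmin <= 0:
        return 0.0

    def sse(c: float) -> float:
        z = values - c
        pos = z > 0
        if int(pos.sum()) < 3:
            return math.inf
        slope, intercept = np.polyfit(times[pos], np.log(z[pos]), 1)
        pred = c + np.exp(intercept + slope * times)
        return float(np.sum((values - pred) ** 2))

    res = minimize_scalar(sse, bounds=(0.0, vmin * (1.0 - 1e-9)),
                          method="bounded",
                          options={"xatol": vmin * 1e-8})
    c = float(res.x)
    # keep the trivial baseline if the optimizer did not improve on it
    return c if sse(c) <= sse(0.0) else 0.0


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

def find_initial_phase_end(do_trace: SignalTrace,
                           o2_threshold: float) -> float:
    """Time of the DO minimum before the threshold crossing.

    Only minima between the start of the experiment and the first time the
    DO signal reaches ``o2_threshold`` are of interest; later minima occur
    under oxygen limitation where exponential growth is impossible.  If DO
    never crosses the threshold the whole trace is searched.  Ties are
    broken toward the latest time, so a flat (no-growth) trace returns its
    last sample and is rejected downstream.
    """
    v = do_trace.values
    below = np.flatnonzero(v <= o2_threshold)
    i_cross = int(below[0]) if below.size else v.size - 1
    seg = v[: i_cross + 1]
    i_min = int(np.flatnonzero(seg == seg.min())[-1])
    return float(do_trace.times[i_min])


def find_phase_start(do_trace: SignalTrace, recipe: Recipe,
                     params: DetectionParams) -> float:
    """Time of the DO maximum inside the growth-speed search window.

    Oxygen rises during early equilibration and stays level through the
    lag; its maximum marks the onset of net oxygen consumption, i.e. the
    start of growth.  Restricting the search to a window keyed to the
    assumed growth speed avoids late artifacts.  Ties are broken toward
    the latest time (closest to growth onset).
    """
    window_h = (recipe.search_window_h
                if recipe.search_window_h is not None
                else params.search_window_h[recipe.growth_speed])
    t = do_trace.times
    n_in = int(np.searchsorted(t, t[0] + window_h, side="right"))
    if n_in < 3:
        raise ParameterError(
            f"start-search window of {window_h} h covers only {n_in} samples"
        )
    seg = do_trace.values[:n_in]
    i_max = int(np.flatnonzero(seg == seg.max())[-1])
    return float(t[i_max])


def detect_peak_or_plateau(growth_trace: SignalTrace,
                           window: tuple[float, float],
                           params: DetectionParams):
    """Earliest peak or plateau of the growth signal inside ``window``.

    A peak is a local maximum with prominence of at least
    ``peak_prominence_frac`` of the in-window signal range.  A plateau is
    the earliest time, after the signal's climb has peaked, from which the
    average slope over a ``plateau_min_duration_h`` stretch drops to
    within ``plateau_slope_frac`` of the steepest such slope in the
    window.  Slopes are taken as finite differences of a lightly smoothed
    signal over the full plateau duration, which makes the test robust to
    sample-level noise; the search starts at the steepest climb so that a
    flat stretch *before* growth (lag remnants) is never mistaken for the
    end of the phase.

    Returns ``(time, kind)`` with kind "peak" or "plateau", or ``None`` —
    absence is a valid outcome.
    """
    i0, i1 = growth_trace.window_indices(*window)
    if i1 - i0 + 1 < 5:
        return None
    t = growth_trace.times[i0:i1 + 1]
    v = growth_trace.values[i0:i1 + 1]

    t_peak = None
    rng = float(np.ptp(v))
    if rng > 0:
        peaks, _ = find_peaks(v, prominence=params.peak_prominence_frac * rng)
        if peaks.size:
            t_peak = float(t[int(peaks[0])])

    t_plateau = None
    dt = float(np.median(np.diff(t)))
    m = max(1, round(params.plateau_min_duration_h / dt))
    if v.size >= max(9, m + 2):
        # median filter first: isolated spikes belong to the peak branch
        # and must not set the slope reference (monotone stretches are
        # invariant under the median)
        smooth = savgol_filter(medfilt(v, 5), _odd_window(9, v.size), 2,
                               mode="interp")
        slopes = (smooth[m:] - smooth[:-m]) / (t[m:] - t[:-m])
        mag = np.abs(slopes)
        s_max = float(mag.max())
        if s_max > 0:
            i_fastest = int(mag.argmax())
            flat = np.flatnonzero(
                mag[i_fastest:] <= params.plateau_slope_frac * s_max)
            if flat.size:
                t_plateau = float(t[i_fastest + int(flat[0])])

    candidates = [(tp, kind) for tp, kind in
                  ((t_peak, "peak"), (t_plateau, "plateau")) if tp is not None]
    if not candidates:
        return None
    return min(candidates, key=lambda c: c[0])


# ---------------------------------------------------------------------------
# workflow part 1: initial window
# ---------------------------------------------------------------------------

def _growth_trace(record: CultivationRecord, signal: str) -> SignalTrace:
    """Resolve the requested growth signal, deriving OUR if needed."""
    if signal == "our":
        if record.has("our"):
            return record.traces["our"]
        if not record.has("do"):
            raise ConfigurationError("no OUR channel and no DO to derive it")
        if record.kla is None or record.c_star is None:
            raise ConfigurationError(
                "OUR can only be derived when both kLa and c* are known"
            )
        ctx = OxygenContext(kla=record.kla, c_star=record.c_star)
        return our_from_do(record.traces["do"], ctx)
    if signal == "bsl":
        if not record.has("bsl"):
            raise ConfigurationError("record has no BSL channel")
        return record.traces["bsl"]
    raise ConfigurationError(f"unknown growth signal {signal!r}")


def initial_phase_window(record: CultivationRecord, recipe: Recipe,
                         signal: str, params: DetectionParams
                         ) -> tuple[PhaseWindow, SignalTrace]:
    """Anchor-based initial window plus the prepared growth trace.

    The growth trace is smoothed when its noise ratio exceeds the
    threshold; the returned trace is the one the optimization loops should
    operate on.
    """
    if not record.has("do"):
        raise DetectionError("record has no dissolved-oxygen trace")
    do = record.traces["do"]
    growth = _growth_trace(record, signal)

    t_start = find_phase_start(do, recipe, params)
    t_min = find_initial_phase_end(do, recipe.o2_threshold)
    if t_start >= t_min:
        raise DetectionError(
            "no growth detected: DO maximum does not precede the DO minimum",
            diagnostics={"o2_max_time": t_start, "o2_min_time": t_min},
        )
    # growth must produce a measurable oxygen drawdown between the anchors
    do_max = float(do.values[np.searchsorted(do.times, t_start)])
    do_min = float(do.values[np.searchsorted(do.times, t_min)])
    do_noise = (estimate_noise(do) * float(np.ptp(do.values))
                if do.n >= 7 else 0.0)
    if do_max - do_min <= max(5.0 * do_noise, 1e-9):
        raise DetectionError(
            "no growth detected: dissolved oxygen shows no drawdown beyond "
            "sensor noise",
            diagnostics={"o2_max_time": t_start, "o2_min_time": t_min,
                         "drawdown": do_max - do_min},
        )

    noise = estimate_noise(growth)
    if noise > params.noise_threshold:
        log.info("growth signal noise ratio %.3f > %.3f; smoothing",
                 noise, params.noise_threshold)
        growth = smooth_trace(growth, params.smoothing_window_points,
                              params.smoothing_polyorder)

    feature = detect_peak_or_plateau(growth, (t_start, t_min), params)
    if feature is not None:
        t_end, end_source = feature
        t_end = min(t_end, t_min)
    else:
        t_end, end_source = t_min, "o2_min"

    i0, i1 = growth.window_indices(t_start, t_end)
    if i1 - i0 + 1 < 4:
        raise DetectionError(
            "initial phase window holds fewer than 4 samples",
            diagnostics={"o2_max_time": t_start, "o2_min_time": t_min,
                         "phase_end": t_end, "end_source": end_source},
        )
    window = PhaseWindow(phase_start=t_start, phase_end=t_end,
                         o2_max_time=t_start, o2_min_time=t_min,
                         end_source=end_source)
    return window, growth


# ---------------------------------------------------------------------------
# workflow part 2: start optimization
# ---------------------------------------------------------------------------

def optimize_phase_start(growth_trace: SignalTrace, window: PhaseWindow,
                         params: DetectionParams,
                         offset: float = 0.0,
                         estimate_offset: bool = False) -> PhaseWindow:
    """Move ``phase_start`` past lag or disturbed samples.

    Each pass fits the exponential over the *upper half* of the current
    window — which the anchors keep clear of the lag — extrapolates it
    backward, and walks from the temporal midpoint of the fit span toward
    the start,
    feeding the residuals between the fitted curve and the observations
    into a pair of one-sided Page (CUSUM) statistics.  Inside the true
    exponential phase the residuals stay within the per-sample allowance
    — half a noise standard deviation plus ``start_slack_frac`` of the
    local fitted amplitude, so both sensor noise and smooth model
    imperfections (which scale with the signal) are tolerated — and the
    statistics repeatedly reset to zero.  Where the data leave the
    exponential, e.g. on a flat lag plateau that sits systematically off
    the backward-extrapolated curve, the excess residuals accumulate; the
    pass aborts once a statistic exceeds ``start_abort_z`` noise units and
    the start moves to the statistic's last reset: the last sample before
    the systematic deviation began.  The noise scale is estimated from the
    data by a short local detrend, so a contaminated fit cannot inflate it
    and mask the boundary.

    Passes repeat until the start no longer moves, which lets an initial
    fit contaminated by a long lag converge in a few steps.  The start
    never moves earlier than its anchor.
    """
    t = growth_trace.times
    v = growth_trace.values
    i0, i1 = growth_trace.window_indices(window.phase_start, window.phase_end)

    for _ in range(params.max_start_passes):
        span = i1 - i0 + 1
        if span < 8:
            break
        if estimate_offset:
            # the baseline must be re-estimated as the window shrinks: an
            # estimate over a lag-contaminated window is biased upward
            offset = estimate_baseline(t[i0:i1 + 1], v[i0:i1 + 1])
        win = v[i0:i1 + 1]
        mid = span // 2
        # reference curve from the upper half only: a lag plateau at the
        # bottom of the window cannot contaminate it, so its backward
        # extrapolation tracks the clean exponential tightly
        fit = fit_exponential(t[i0 + mid:i1 + 1], win[mid:],
                              t[i0 + mid], offset)
        predicted = offset + fit.y0 * np.exp(
            fit.mu * (t[i0:i1 + 1] - t[i0 + mid]))
        resid = win - predicted
        scale = float(np.max(np.abs(win)))
        # noise level from a short local detrend of the data themselves —
        # independent of how well the current fit matches
        trend = savgol_filter(win, _odd_window(9, win.size), 2, mode="interp")
        sigma = max(float(np.std(win - trend)), 1e-12 * scale)
        amplitude = np.abs(predicted - offset)
        slack = 0.5 * sigma + params.start_slack_frac * amplitude

        # March the full half-span and note, for each one-sided statistic,
        # where it first tripped (backtracked to its last reset).  The
        # earliest such position wins: taking the deeper evidence keeps
        # the start from overshooting into the phase — the repeated
        # passes sort out the rest.
        s_up = s_dn = 0.0
        last_zero_up = last_zero_dn = mid
        cand_up = cand_dn = None
        for k in range(mid - 1, -1, -1):
            s_up = max(0.0, s_up + (resid[k] - slack[k]) / sigma)
            if s_up == 0.0:
                last_zero_up = k
            s_dn = max(0.0, s_dn + (-resid[k] - slack[k]) / sigma)
            if s_dn == 0.0:
                last_zero_dn = k
            if cand_up is None and s_up > params.start_abort_z:
                cand_up = last_zero_up
            if cand_dn is None and s_dn > params.start_abort_z:
                cand_dn = last_zero_dn
        cands = [c for c in (cand_up, cand_dn) if c is not None]
        new_i0 = i0 + min(cands) if cands else None
        if new_i0 is None or new_i0 <= i0:
            break
        i0 = new_i0

    return replace(window, phase_start=float(t[i0]))


# ---------------------------------------------------------------------------
# workflow part 3: end optimization
# ---------------------------------------------------------------------------

def optimize_phase_end(growth_trace: SignalTrace, window: PhaseWindow,
                       params: DetectionParams, offset: float = 0.0,
                       estimate_offset: bool = False
                       ) -> tuple[PhaseWindow, FitResult]:
    """Trim ``phase_end`` to where exponential growth demonstrably stops.

    A temporary fit over [phase_start, midpoint of the window] is extended
    one sample at a time and refitted; each refit's RMSE is compared with
    its predecessor.  After ``rmse_abort_count`` consecutive relative
    increases the end moves back to the last sample before the degradation
    run began.  If the RMSE never degrades that way the end is unchanged.
    Returns the final window and the final exponential fit on it.
    """
    t = growth_trace.times
    v = growth_trace.values
    i0, i1 = growth_trace.window_indices(window.phase_start, window.phase_end)
    if i1 - i0 + 1 < 4:
        raise DetectionError("phase window holds fewer than 4 samples")
    if estimate_offset:
        offset = estimate_baseline(t[i0:i1 + 1], v[i0:i1 + 1])

    def relative_rmse(j: int) -> float:
        # RMSE divided by the window's signal range: scale-free, so the
        # exponentially growing amplitude itself is not read as
        # degradation when the window is extended
        fit = fit_exponential(t[i0:j + 1], v[i0:j + 1], t[i0], offset)
        rng = float(np.ptp(v[i0:j + 1]))
        return fit.rmse / rng if rng > 0 else math.inf

    j0 = i0 + (i1 - i0) // 2
    j0 = max(j0, i0 + 3)  # a fit needs at least 4 samples
    final_end = i1
    if j0 < i1:
        prev = relative_rmse(j0)
        consec = 0
        run_start = None
        for j in range(j0 + 1, i1 + 1):
            rmse = relative_rmse(j)
            if rmse > prev * (1.0 + params.rmse_increase_frac) \
                    and rmse > 1e-9:
                if consec == 0:
                    run_start = j
                consec += 1
                if consec >= params.rmse_abort_count:
                    final_end = run_start - 1
                    break
            else:
                consec = 0
            prev = rmse
    if final_end - i0 + 1 < 4:
        raise DetectionError(
            "optimized phase window holds fewer than 4 samples",
            diagnostics={"phase_start": float(t[i0]),
                         "phase_end": float(t[final_end])},
        )
    if estimate_offset:
        offset = estimate_baseline(t[i0:final_end + 1], v[i0:final_end + 1])
    fit = fit_exponential(t[i0:final_end + 1], v[i0:final_end + 1], t[i0],
                          offset)
    return replace(window, phase_end=float(t[final_end])), fit


# ---------------------------------------------------------------------------
# full workflow
# ---------------------------------------------------------------------------

def detect_exponential_phase(record: CultivationRecord, recipe: Recipe,
                             signal: str = "auto",
                             params: DetectionParams | None = None
                             ) -> tuple[PhaseWindow, FitResult]:
    """Run the full three-part workflow on a cultivation record.

    ``signal`` selects the growth signal: "our", "bsl" or "auto".  Auto
    prefers OUR (present or derivable from DO) and falls back to BSL when
    OUR is unavailable or its detection fails; OUR is the more broadly
    usable signal for microbial and animal cultures, while BSL is the
    signal of choice for dense plant-cell suspensions.  The result is
    deterministic for fixed inputs and parameters.
    """
    if params is None:
        params = DetectionParams.for_recipe(recipe)

    if signal == "auto":
        try:
            return detect_exponential_phase(record, recipe, "our", params)
        except (ConfigurationError, DetectionError) as exc:
            if not record.has("bsl"):
                raise
            log.info("OUR-based detection unavailable (%s); falling back "
                     "to BSL", exc)
            return detect_exponential_phase(record, recipe, "bsl", params)

    window, growth = initial_phase_window(record, recipe, signal, params)
    estimate_offset = signal == "bsl"
    window = optimize_phase_start(growth, window, params,
                                  estimate_offset=estimate_offset)
    window, fit = optimize_phase_end(growth, window, params,
                                     estimate_offset=estimate_offset)
    fit.flags["signal"] = signal
    if fit.mu <= 0:
        log.warning("detected growth rate is non-positive (mu=%.4g h^-1)",
                    fit.mu)
    return window, fit
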