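# Methods

This note documents the models, algorithms and numerical choices behind
`flaskkpi`, and what the synthetic validation does and does not show.

## Signals and physics

All times are hours since inoculation; all rates are h^-1.  Dissolved
oxygen (DO) is stored in % air saturation, where 100 % corresponds to the
saturation concentration `c* = p * xO2 * H(T)` (Henry's law; `p` total
pressure in atm, `xO2` the oxygen mole fraction of the incubator
atmosphere, `H` the Henry solubility in mol L^-1 atm^-1 at cultivation
temperature, supplied by the user — no temperature correlation is
shipped).  At gas-liquid quasi-steady state the oxygen transfer rate
equals the cells' uptake rate,

    OUR = OTR = kLa * c* * (1 - DO/100),

which is how an OUR trace is derived from DO when the logging device did
not export one; this requires both `kLa` and `c*`.  Supersaturated samples
(DO > 100 %) produce negative OUR values that are kept but flagged.  The
detector itself operates on unit-free anchors (minima, maxima,
thresholds), so DO stays in % units throughout detection.

## Phase detection

The detector automates what an experienced operator does by eye, in three
parts.  It is deterministic: identical inputs and parameters give
bit-identical results.

### Initial window from oxygen anchors

The candidate start is the DO maximum inside a search window keyed to the
recipe's growth-speed class (defaults: fast 6 h, medium 48 h, slow 240 h;
recipe-overridable).  Oxygen rises or stays level through equilibration
and lag and falls once net uptake begins, so its in-window maximum marks
growth onset; restricting the search prevents late artifacts (e.g. the
oxygen spike at substrate depletion) from stealing the anchor.  Ties are
broken toward the latest time, i.e. the sample closest to growth onset.

The candidate end is the DO minimum between the start of the experiment
and the first crossing of the recipe's oxygen threshold (default 15 %,
the midpoint of the conventional 10-20 % band below which exponential
growth is considered impossible).  Later minima occur under oxygen
limitation and are ignored.  Between the anchors, the growth signal is
scanned for a peak (local maximum with prominence >= 30 % of the window
range) or a plateau; whichever occurs earlier replaces the DO minimum as
the candidate end.  If the DO never draws down by more than five noise
standard deviations between the anchors, detection fails with a
diagnosis — there is no growth to fit.

Plateaus are found from average slopes over one minimum plateau duration
(fast 0.5 h, medium 2 h, slow 10 h) of a median-filtered,
Savitzky-Golay-smoothed copy of the signal: the earliest position after
the steepest climb whose duration-scale slope falls below 5 % of the
steepest slope.  Averaging over the full duration makes the test robust
to sample-level noise without a wide derivative kernel (which would smear
away short plateaus and suffer edge artifacts); the median filter keeps
isolated spikes — which belong to the peak branch — from inflating the
slope reference; starting after the steepest climb prevents the flat lag
from being mistaken for the end of growth.

If the growth signal's noise ratio (residual standard deviation after a
short local quadratic detrend, divided by the signal range) exceeds 0.02,
the signal is smoothed with a Savitzky-Golay filter (default window: the
smallest odd integer covering 5 % of the trace, minimum 5 points; order
2; endpoints by polynomial extrapolation).  The filter assumes an
equidistant grid; irregular grids are processed on an index basis with a
logged warning, and no implicit resampling ever happens.

### Exponential fitting

The model is `y(t) = c + y0 * exp(mu * (t - t0))`.  Fitting is ordinary
least squares on `log(y - c)` — deterministic and initialization-free —
with non-positive samples excluded from the regression; R^2 and RMSE are
always evaluated in the original signal space.  For OUR the baseline `c`
is zero (OUR is proportional to biomass).  For backscattered light the
optical baseline is estimated by a bounded one-dimensional search for the
`c` in `[0, min(y))` that minimizes the linear-space SSE of the log-linear
fit; on a clean signal this recovers the optical offset exactly.  A fixed
subtraction of the signal's initial level would instead remove the
inoculum's contribution `gain * X0` along with the optical offset, and
`gain * (X - X0)` is not exponential — for dense inocula (plant
suspensions start at ~20 % of final biomass) that distorts the growth
rate by tens of percent.  The baseline is re-estimated whenever the
window changes, because estimates over lag-contaminated windows are
biased upward.

### Start optimization

Each pass fits the reference curve on the *upper half* of the current
window — which the anchors keep clear of the lag — and extrapolates it
backward.  Walking from the window midpoint toward the start, the
residuals feed two one-sided Page (CUSUM) statistics with per-sample
allowance `0.5 * sigma + 0.02 * amplitude(t)`:

* `sigma` is the noise level estimated from the data by a 9-point local
  quadratic detrend, so a poor fit cannot inflate it and mask a boundary;
* the amplitude term tolerates smooth model imperfections (substrate
  depletion curving the "exponential"), which scale with the signal
  rather than with the noise — on noiseless data this keeps the
  statistics at zero and the start exactly at its anchor.

A statistic exceeding 8 noise units aborts the pass, and the start moves
to the statistic's last reset — the last sample before the systematic
departure began, which localizes a lag boundary to about one sample on
the fast presets.  When both statistics trip, the earlier (deeper)
position wins, so a contaminated fit misfitting good data just above the
boundary cannot push the start into the phase.  Passes repeat to a fixed
point (at most 25); the start never moves earlier than its anchor.

Cumulative residuals were chosen over fixed-size sliding-window R^2
comparisons after both variants were implemented and measured on the
preset scenarios: windowed R^2 shrinks toward the bottom of the window
for purely statistical reasons (the local signal range falls toward the
noise level), so any comparison against a running best aborts early, and
for slow growers, where a window covers a small fraction of an e-fold,
the windowed statistic fluctuates so strongly that iterated passes walk
the start deep into the growth phase.  The CUSUM concentrates all samples
below the midpoint into one test and has neither failure mode.

### End optimization

A temporary fit over `[start, midpoint]` is extended one sample at a
time and refitted.  Each refit's RMSE is compared with its predecessor
*relative to the window's signal range*: the raw RMSE of a growing
exponential rises with the signal amplitude itself, so an absolute
comparison reads every extension as degradation on clean data.  After 3
consecutive relative increases of more than 5 % (single noisy upticks
reset the counter; a 1e-9 floor ignores float jitter), the end moves back
to the last sample before the degradation run began.  The final
exponential fit is made on the optimized window.  The optimized window is
always nested inside the initial one.

## KPIs

* `mu_max` is the slope of the final fit.
* Biomass during the phase is reconstructed as
  `C_X(t) = C_X,0 * OUR(t) / OUR(onset)` — valid because qO2 is assumed
  constant during exponential growth.  The onset level is the median of
  the OUR samples before the detected start (the OUR is flat at
  `qO2 * C_X,0` throughout the lag), which is unbiased against small
  start-boundary errors and far less noisy than a single sample; with
  fewer than five pre-start samples the first window samples are used.
* `qO2` is the median of the pointwise ratios `OUR/C_X` over the window
  (robust to endpoint noise).
* Yields use endpoint differences, `Y_X/S = (X_end - X_0)/(S_0 - S_end)`,
  with endpoints supplied by the caller (offline measurements or
  simulator truth); the instantaneous-ratio form is dimensionally a yield
  only as a difference quotient.
* `C_X,max` is the maximum of the reconstructed (or supplied) biomass.

Units are carried as labels (g-based for microbes and plants, cell-based
for animal cultures) and checked, never converted.  Missing metadata
nulls only the affected KPI, with a recorded reason.

## Simulator

State `(X, S)` follows a Monod batch model with an oxygen-transfer cap:

    dX/dt = mu_max * S/(Ks+S) * X * min(1, OTR_max/(qO2*X)),  t > lag
    dS/dt = -(1/Y_XS) dX/dt,     OUR = min(qO2*X, OTR_max),
    DO/100 = 1 - OUR/OTR_max,    OTR_max = kLa * c*.

The quasi-steady DO (no dynamic DO equation) matches the equilibrium
assumption used in analysis and keeps the model analytically checkable:
before limitation and far from depletion the biomass is exactly
exponential, the conservation `Y_XS*(S0-S) = X-X0` holds to machine
precision, and the oxygen-limitation onset t* solves
`X0*exp(mu*(t*-lag)) = kLa*c*/qO2`.  Under limitation the OUR plateaus at
`kLa*c*` and DO pins at zero — the signature the end detector keys on.

Numerics: classical RK4 with 8 sub-steps per sampling interval (the
substrate-exhaustion corner is stiff); a sub-step overshooting `S < 0` is
projected back onto the conservation line `X + Y*S = const`, so only the
substrate actually available becomes biomass.  The lag is a hard switch
(`mu = 0` for `t <= lag`), with integration starting exactly at the lag
so no RK4 stage straddles the discontinuity and lag-phase samples sit
exactly on the initial state — giving crisp ground truth for
start-detection tests.  Halving the sampling step changes the biomass
trajectory by well under 0.1 %.

Rendering adds the sensor layer: per-channel Gaussian noise with standard
deviation expressed as a fraction of the clean channel's range, an
optional exponential DO equilibration artifact for the first fraction of
an hour, BSL as `offset + gain * X` (or `offset + gain * D` with
dead cells `D` accumulating first-order after substrate depletion, the
pattern seen in animal-cell cultures where scattering tracks dying
cells), an optional device-style OUR channel, and a purely cosmetic
two-segment pH drift.  Everything is reproducible from the configuration
seed.

Default noise levels are chosen as precision-grade repeatability of
optical sensor spots and derived channels: DO and OUR sigma = 0.2 % of
range, backscatter 1 % (5 % in the baffled-flask preset, where bubbles
make the optical channel noisy), pH 0.2 %.  Systematic sensor accuracy
(calibration offsets) is not modeled; the detector's anchors are
differential, so constant offsets would not move them.

### Preset scenarios

Six presets span the organism classes the workflow targets, with growth
rates, yields and oxygen uptake rates at the magnitudes reported for the
respective organisms, and sampling intervals at realistic device readout
rates:

| preset | mu_max (1/h) | signal | dt (h) | notes |
|---|---|---|---|---|
| ecoli_complex | 1.3 | OUR | 0.1 | rich medium, 0.5 h lag, O2-limited at ~3.4 h |
| ecoli_biener | 0.60 | OUR | 0.1 | defined glucose medium, Y=0.434 g/g, qO2=2.13e-2 mol/g/h |
| yeast_ypd | 0.47 | OUR | 0.15 | qO2=2.59e-3 mol/g/h, O2-limited |
| noisy_baffled | 0.47 | OUR | 0.15 | as yeast, BSL noise 5x (baffles/bubbles) |
| cho | 0.035 | OUR | 0.25 | cell-based units, dead-cell BSL, ends at depletion |
| vitis | 0.008 | BSL | 0.5 | plant suspension, dense inoculum, no OUR channel |

The vitis preset carries no OUR channel and no kLa metadata, so signal
auto-selection falls back to backscatter — mirroring practice, where
plant-cell oxygen signals are dominated by substrate-switch artifacts
while the dense suspension gives a clean backscatter trace.

## What the synthetic validation shows — and does not

Passing the validation suite shows the workflow recovers growth rates
within 1 % on clean signals and a few percent at realistic noise across
2.5 orders of magnitude in mu, places the phase boundaries within a few
samples of the true lag end and oxygen-limitation onset, and is
deterministic and internally consistent.  The simulator, however, renders
idealized Gaussian-noise sensors: it does not model calibration drift,
temperature transients from opening the incubator, sampling-induced
signal disturbances, non-linear BSL-to-biomass response at high density,
or genuinely diauxic second growth phases (the detector deliberately fits
only the first exponential phase).  Results on real flasks therefore
depend on signal quality in ways the synthetic tests cannot certify;
the recipe's oxygen threshold and growth-speed class remain the operator's
responsibility.

## Problem sizes used in the validation

Noiseless and noisy recovery run the six presets as configured (81-673
samples per trace; 50 seeds per preset for the noisy sweep); lag
robustness runs the fast preset at lags of 0-5 h, 20 seeds each; the
brute-force window-search comparison uses 30 random short cultivations of
100-200 samples, small enough for exhaustive enumeration of all nested
windows with at least 10 samples.
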