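"""Reading, writing and validation of shake-flask sensor logs and recipes.

Sensor logs are plain CSV files with a header row, a time column in hours
since inoculation and one column per measured channel (dissolved oxygen in
% air saturation, backscattered light in arbitrary units, pH, optionally a
device-computed oxygen uptake rate).  A ``column_map`` translates vendor
column names onto the canonical channel keys used throughout the package:

``do``      dissolved oxygen, % air saturation (100 % == saturation c*)
``bsl``     backscattered light, arbitrary units
``ph``      pH
``our``     oxygen uptake rate, mol L^-1 h^-1
``biomass`` biomass concentration, g L^-1 (or 1e6 cells mL^-1)

Recipes are small YAML (or JSON) files holding the per-organism detection
hints: the oxygen threshold below which exponential growth is assumed
impossible and the growth-speed class, plus optional overrides for the
detector parameters.  Unknown keys are rejected so that typos fail loudly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, RecipeError, TraceValidationError

log = logging.getLogger(__name__)

#: canonical channel keys and their default unit labels
CHANNEL_UNITS = {
    "do": "% air saturation",
    "bsl": "a.u.",
    "ph": "-",
    "our": "mol L^-1 h^-1",
    "biomass": "g L^-1",
}

GROWTH_SPEEDS = ("fast", "medium", "slow")

#: column names used by :func:`write_record_csv`; reading them back with
#: this map round-trips a record exactly.
DEFAULT_COLUMN_MAP = {key: key for key in CHANNEL_UNITS}
DEFAULT_COLUMN_MAP["time"] = "time_h"


@dataclass
class SignalTrace:
    """One time-stamped sensor channel.

    ``times`` are hours since inoculation, strictly increasing but not
    necessarily equidistant.  ``values`` must be finite; gaps have to be
    dropped before construction, never silently interpolated.
    """

    times: np.ndarray
    values: np.ndarray
    channel: str
    units: str = ""
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise TraceValidationError("times and values must be 1-D arrays")
        if self.times.size != self.values.size:
            raise TraceValidationError(
                f"times ({self.times.size}) and values ({self.values.size}) "
                "differ in length"
            )
        if self.times.size < 2:
            raise TraceValidationError("a trace needs at least 2 samples")
        if not np.all(np.isfinite(self.times)):
            raise TraceValidationError("times contain non-finite entries")
        if not np.all(np.isfinite(self.values)):
            raise TraceValidationError(
                f"channel {self.channel!r} contains NaN/inf values; drop or "
                "flag gaps before building a trace"
            )
        if np.any(np.diff(self.times) <= 0):
            raise TraceValidationError(
                f"times of channel {self.channel!r} are not strictly increasing"
            )
        if not self.units:
            self.units = CHANNEL_UNITS.get(self.channel, "")

    @property
    def n(self) -> int:
        return self.times.size

    def window_indices(self, t0: float, t1: float) -> tuple[int, int]:
        """Inclusive index bounds of samples with ``t0 <= t <= t1``."""
        i0 = int(np.searchsorted(self.times, t0, side="left"))
        i1 = int(np.searchsorted(self.times, t1, side="right")) - 1
        return i0, i1

    def with_values(self, values: np.ndarray, **extra_flags) -> "SignalTrace":
        """Copy of the trace with new values on the same time grid."""
        flags = dict(self.flags)
        flags.update(extra_flags)
        return SignalTrace(self.times.copy(), np.asarray(values, dtype=float),
                           self.channel, self.units, flags)


@dataclass
class CultivationRecord:
    """A flask's bundle of signal traces plus physical metadata.

    All traces share the same time origin (t = 0 is inoculation).  ``kla``
    (h^-1) and ``c_star`` (mol L^-1) are needed to derive an OUR trace from
    dissolved oxygen when the device did not export one.  ``c_x0`` and
    ``c_s0`` are the initial biomass and substrate concentrations.
    """

    traces: dict[str, SignalTrace]
    kla: float | None = None
    c_star: float | None = None
    c_x0: float | None = None
    c_s0: float | None = None
    flask_label: str = ""

    def __post_init__(self):
        if not any(k in self.traces for k in ("do", "our", "bsl")):
            raise TraceValidationError(
                "a record needs at least one of the DO, OUR or BSL channels"
            )

    def has(self, channel: str) -> bool:
        return channel in self.traces


@dataclass
class Recipe:
    """Per-organism hints steering the phase detection.

    ``o2_threshold`` is the dissolved-oxygen level (% air saturation) below
    which exponential growth is assumed impossible; the conventional range
    is 10-20 % and the default sits at its midpoint.  ``growth_speed``
    selects the time window in which the start of growth is searched
    (fast: E. coli, S. cerevisiae; medium: CHO, HEK; slow: plant cells).
    The remaining fields override detector defaults when set.
    """

    growth_speed: str
    o2_threshold: float = 15.0
    search_window_h: float | None = None
    smoothing_window_points: int | None = None
    smoothing_polyorder: int | None = None
    noise_threshold: float | None = None
    start_abort_z: float | None = None
    rmse_abort_count: int | None = None
    plateau_min_duration_h: float | None = None

    def __post_init__(self):
        if self.growth_speed not in GROWTH_SPEEDS:
            raise RecipeError(
                f"growth_speed must be one of {GROWTH_SPEEDS}, "
                f"got {self.growth_speed!r}"
            )
        if not (0.0 < float(self.o2_threshold) < 100.0):
            raise RecipeError(
                f"o2_threshold must lie in (0, 100), got {self.o2_threshold}"
            )


def recipe_from_dict(data: dict) -> Recipe:
    """Build a :class:`Recipe` from a parsed mapping, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise RecipeError("recipe must be a mapping")
    known = {f.name for f in fields(Recipe)}
    unknown = set(data) - known
    if unknown:
        raise RecipeError(f"unknown recipe keys: {sorted(unknown)}")
    if "growth_speed" not in data:
        raise RecipeError("recipe is missing the required key 'growth_speed'")
    try:
        return Recipe(**data)
    except TypeError as exc:  # wrong value types
        raise RecipeError(str(exc)) from exc


def load_recipe(path) -> Recipe:
    """Load a recipe from a YAML or JSON file."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise FormatError(f"could not parse recipe {path}: {exc}") from exc
    return recipe_from_dict(data)


def save_recipe(recipe: Recipe, path) -> None:
    data = {f.name: getattr(recipe, f.name) for f in fields(Recipe)
            if getattr(recipe, f.name) is not None}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def read_sensor_csv(path, column_map: dict[str, str] | None = None,
                    **record_kwargs) -> CultivationRecord:
    """Read a sensor log CSV into a :class:`CultivationRecord`.

    ``column_map`` maps canonical channel keys (plus the mandatory ``time``
    key) onto the CSV column names.  Rows whose time stamp cannot be parsed
    are dropped with a logged count; per channel, rows with unparseable
    values are likewise dropped.  Duplicate time stamps are collapsed by
    keeping the first occurrence; a strictly decreasing time stamp is fatal.
    """
    column_map = dict(column_map or DEFAULT_COLUMN_MAP)
    if "time" not in column_map:
        raise FormatError("column_map must map the 'time' key")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"could not read CSV {path}: {exc}") from exc
    time_col = column_map.pop("time")
    if time_col not in df.columns:
        raise FormatError(f"time column {time_col!r} not found in {path}")

    t = pd.to_numeric(df[time_col], errors="coerce").to_numpy(dtype=float)
    bad_time = ~np.isfinite(t)
    if bad_time.any():
        log.warning("%s: dropped %d rows with unparseable time stamps",
                    path, int(bad_time.sum()))
    df = df.loc[~bad_time]
    t = t[~bad_time]

    # collapse duplicate time stamps (keep first); strict decrease is fatal
    if t.size >= 2:
        dt = np.diff(t)
        if np.any(dt < 0):
            raise TraceValidationError(
                f"{path}: time stamps decrease after parsing"
            )
        dup = np.concatenate([[False], dt == 0])
        if dup.any():
            log.warning("%s: collapsed %d duplicate time stamps (kept first)",
                        path, int(dup.sum()))
            df = df.loc[~dup]
            t = t[~dup]

    traces = {}
    for channel, col in column_map.items():
        if col not in df.columns:
            continue
        v = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        ok = np.isfinite(v)
        dropped = int((~ok).sum())
        if dropped:
            log.warning("%s: channel %r: dropped %d unparseable values",
                        path, channel, dropped)
        if ok.sum() < 2:
            log.warning("%s: channel %r has fewer than 2 valid samples; "
                        "skipped", path, channel)
            continue
        traces[channel] = SignalTrace(t[ok], v[ok], channel)
    if not traces:
        raise FormatError(f"{path}: no mapped channel had parseable data")
    return CultivationRecord(traces=traces, **record_kwargs)


def write_record_csv(record: CultivationRecord, path) -> None:
    """Write a record to CSV (one row per time stamp, NaN for gaps).

    Floats are printed with 17 significant digits so that reading the file
    back recovers the exact binary values.
    """
    grids = [tr.times for tr in record.traces.values()]
    times = np.unique(np.concatenate(grids))
    data = {DEFAULT_COLUMN_MAP["time"]: times}
    for channel, tr in record.traces.items():
        col = np.full(times.size, np.nan)
        idx = np.searchsorted(times, tr.times)
        col[idx] = tr.values
        data[channel] = col
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
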