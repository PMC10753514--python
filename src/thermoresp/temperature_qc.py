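"""Cleaning, rounding and binning of body-temperature streams.

PIT-tag streams occasionally report single erratic values far above any
physiological temperature (misreads when the tag is only partially
energized); these are removed when isolated. Thermocouple channels record
only within a 30-50 degC window, so out-of-window values become missing.
Before variability indices are computed, all streams are rounded to the
0.1 degC tag resolution and binned into 1-min means so sensor types are
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISREAD_THRESHOLD_C = 45.0   # spike candidates exceed this
NEIGHBOR_NORMAL_C = 42.0     # ... and all neighbours within the window stay below
NEIGHBOR_WINDOW_S = 60.0

RANGE_C = (30.0, 50.0)       # thermocouple recording window, inclusive


class TemperatureQCError(ValueError):
    pass


@dataclass
class TemperatureSeries:
    """Timestamped readings from one bird's temperature sensor.

    ``data`` has columns ``t`` (seconds, strictly increasing), ``temp``
    (degC, NaN when removed) and ``flag`` (``ok``, ``misread_removed`` or
    ``out_of_range``).
    """

    bird_id: str
    sensor: str                      # "PIT" or "thermocouple"
    data: pd.DataFrame
    qc_counts: dict = field(default_factory=dict)

    def valid(self) -> pd.DataFrame:
        """Rows with a retained temperature value."""
        return self.data[self.data["temp"].notna()]


def remove_misreads(series: TemperatureSeries) -> TemperatureSeries:
    """Drop single erratically occurring PIT values >45 degC.

    A sample qualifies only when every *other* sample within +/-60 s is at
    most 42 degC, so sustained high plateaus (genuine hyperthermia) are
    preserved. Removed samples become NaN with flag ``misread_removed``;
    the count is recorded in ``qc_counts["misreads_removed"]``.
    """
    data = series.data.copy()
    t = data["t"].to_numpy(dtype=float)
    temp = data["temp"].to_numpy(dtype=float)
    cand = np.flatnonzero(temp > MISREAD_THRESHOLD_C)
    removed = []
    for i in cand:
        near = (np.abs(t - t[i]) <= NEIGHBOR_WINDOW_S) & (np.arange(len(t)) != i)
        near &= ~np.isnan(temp)
        if np.all(temp[near] <= NEIGHBOR_NORMAL_C):
            removed.append(i)
    if removed:
        idx = data.index[removed]
        data.loc[idx, "temp"] = np.nan
        data.loc[idx, "flag"] = "misread_removed"
    counts = dict(series.qc_counts)
    counts["misreads_removed"] = len(removed)
    return replace(series, data=data, qc_counts=counts)


def enforce_range(series: TemperatureSeries,
                  bounds: tuple[float, float] = RANGE_C) -> TemperatureSeries:
    """Flag thermocouple values outside the inclusive recording window."""
    lo, hi = bounds
    data = series.data.copy()
    temp = data["temp"].to_numpy(dtype=float)
    bad = (~np.isnan(temp)) & ((temp < lo) | (temp > hi))
    if bad.any():
        idx = data.index[bad]
        data.loc[idx, "temp"] = np.nan
        data.loc[idx, "flag"] = "out_of_range"
    counts = dict(series.qc_counts)
    counts["out_of_range"] = int(bad.sum())
    return replace(series, data=data, qc_counts=counts)


def round_and_bin(series: TemperatureSeries, bin_width_s: float = 60.0
                  ) -> TemperatureSeries:
    """Round to 0.1 degC, then average into non-overlapping time bins.

    Rounding precedes binning (the tag resolution applies to individual
    readings). Bins are anchored at integer multiples of ``bin_width_s``
    from the recording start; bins with no retained samples are missing.
    The returned series has one row per bin, timestamped at the bin start.
    """
    if bin_width_s <= 0:
        raise TemperatureQCError("bin width must be positive")
    valid = series.valid()
    t = valid["t"].to_numpy(dtype=float)
    temp = np.round(valid["temp"].to_numpy(dtype=float), 1)
    if len(t) == 0:
        empty = pd.DataFrame({"t": [], "temp": [], "flag": []})
        return replace(series, data=empty)
    t0 = series.data["t"].iloc[0]
    nbins = int(np.floor((series.data["t"].iloc[-1] - t0) / bin_width_s)) + 1
    which = np.floor((t - t0) / bin_width_s).astype(int)
    sums = np.bincount(which, weights=temp, minlength=nbins)
    counts = np.bincount(which, minlength=nbins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    data = pd.DataFrame({"t": t0 + bin_width_s * np.arange(nbins),
                         "temp": means,
                         "flag": np.where(counts > 0, "ok", "out_of_range")})
    data.loc[counts == 0, "flag"] = "ok"   # missing, not flagged: no samples
    return replace(series, data=data)


def qc_pipeline(series: TemperatureSeries) -> TemperatureSeries:
    """Sensor-appropriate cleaning: misread removal (PIT) or range (TC)."""
    if series.sensor == "PIT":
        return remove_misreads(series)
    return enforce_range(series)
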