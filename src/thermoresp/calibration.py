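"""Linear calibration of temperature sensors against a chamber reference.

The bench fixture reads every comparison unit at reference temperatures
spanning the daily range of body temperature (35/40/45 degC). Calibration
fits ordinary least squares of the *reference* on the *raw reading* —
the usable direction downstream, where raw field readings must be mapped
to true temperature — and is applied per sensor kind (PIT tag vs
thermocouple), pooling units; per-unit fits are available via
``grouping="unit"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import sensor_kind


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationFit:
    """Linear map reading -> reference for one sensor group."""

    group: str
    slope: float
    intercept: float
    r2: float
    n: int

    def apply(self, reading):
        return self.intercept + self.slope * np.asarray(reading, dtype=float)

    def inverse(self, calibrated):
        return (np.asarray(calibrated, dtype=float) - self.intercept) / self.slope


def fit_calibration(table: pd.DataFrame, grouping: str = "sensor"
                    ) -> dict[str, CalibrationFit]:
    """OLS of chamber reference on raw reading, per group.

    Parameters
    ----------
    table : fixture rows with columns ``reference_c``, ``reading_c`` and
        the grouping column (default ``sensor``).
    grouping : column defining calibration groups (``sensor`` pools units
        per sensor kind; ``unit`` fits each bench unit separately).

    Raises
    ------
    CalibrationError
        If a group has fewer than two distinct reference temperatures
        (degenerate regression).
    """
    if grouping not in table.columns:
        raise CalibrationError(f"no grouping column {grouping!r} in table")
    fits: dict[str, CalibrationFit] = {}
    for group, sub in table.groupby(grouping, sort=True):
        x = sub["reading_c"].to_numpy(dtype=float)
        y = sub["reference_c"].to_numpy(dtype=float)
        if len(np.unique(y)) < 2:
            raise CalibrationError(
                f"group {group!r} has a single reference level")
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (intercept + slope * x)
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        if not 0.8 < slope < 1.2:
            warnings.warn(f"calibration slope {slope:.3f} for group {group!r} "
                          "outside (0.8, 1.2)", stacklevel=2)
        fits[str(group)] = CalibrationFit(group=str(group), slope=float(slope),
                                          intercept=float(intercept),
                                          r2=float(r2), n=len(sub))
    return fits


def apply_calibration(series, fit: CalibrationFit):
    """Map a temperature series' raw readings through a calibration fit.

    QC flags and missing values are preserved; only ``temp`` changes.
    """
    if fit is None:
        raise CalibrationError(f"no calibration fit for series {series.bird_id}")
    data = series.data.copy()
    data["temp"] = fit.apply(data["temp"].to_numpy(dtype=float))
    return replace(series, data=data)


def fit_for_method(fits: dict[str, CalibrationFit], method: str
                   ) -> CalibrationFit | None:
    """Calibration fit applicable to a measurement method's sensor."""
    kind = sensor_kind(method)
    if kind is None:
        return None
    if kind not in fits:
        raise CalibrationError(f"no calibration fit for sensor kind {kind!r}")
    return fits[kind]


def fits_to_frame(fits: dict[str, CalibrationFit]) -> pd.DataFrame:
    return pd.DataFrame([{"group": f.group, "slope": f.slope,
                          "intercept": f.intercept, "r2": f.r2, "n": f.n}
                         for f in fits.values()])
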