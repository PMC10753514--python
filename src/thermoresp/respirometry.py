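"""Gas-exchange math for flow-through respirometry.

Converts multiplexed analyzer streams (excurrent O2 and CO2 fractions,
water-vapour pressure, barometric pressure, incurrent STPD dry flow) into
oxygen consumption, CO2 production, respiratory quotient and metabolic
power. The analyzer chain matches the study setup: air passes an RH meter,
then the CO2 analyzer, then chemical H2O/CO2 scrubbers, then the O2
analyzer — so O2 fractions are on a dry, CO2-free basis while CO2 is
measured upstream and dried mathematically.

Baseline (animal-free) periods bracketing each bird sample track analyzer
drift; incurrent reference fractions are interpolated between the
bracketing baseline means before rates are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import BASELINE

#: oxyjoule equivalent (J per ml O2) is OXY_A + OXY_B * RQ
OXY_A = 16.0
OXY_B = 5.164

#: seconds trimmed from each end of a baseline segment (washout guard)
BASELINE_TRIM_S = 60


class RespirometryError(ValueError):
    pass


@dataclass
class GasRates:
    """Per-sample gas exchange rates (ml/min STPD) and metabolic power."""

    vo2: np.ndarray
    vco2: np.ndarray
    rq: np.ndarray
    watts: np.ndarray


def scrub_water_math(f_wet, wvp, bp):
    """Dry-correct a gas fraction measured in humid air.

    Dilution by water vapour scales every dry-gas fraction by
    ``(bp - wvp) / bp``; the dry-equivalent fraction is therefore
    ``f_wet * bp / (bp - wvp)``.

    Parameters
    ----------
    f_wet : fraction measured upstream of the scrubbers
    wvp : water vapour pressure, kPa
    bp : barometric pressure, kPa
    """
    f_wet = np.asarray(f_wet, dtype=float)
    wvp = np.asarray(wvp, dtype=float)
    bp = np.asarray(bp, dtype=float)
    if np.any(wvp < 0):
        raise RespirometryError("water vapour pressure must be >= 0")
    if np.any(wvp >= bp):
        raise RespirometryError("water vapour pressure must be below barometric")
    out = f_wet * bp / (bp - wvp)
    return float(out) if out.ndim == 0 else out


def compute_gas_rates(fri, fio2, feo2, fico2, feco2):
    """O2 consumption and CO2 production (ml/min STPD) by mass balance.

    ``fio2``/``feo2`` are incurrent/excurrent O2 fractions on the dry,
    CO2-free basis the O2 analyzer reports (it sits downstream of the
    scrubbers, and is baselined on the same scrubbed incurrent air).
    ``fico2``/``feco2`` are dry CO2 fractions. ``fri`` is the incurrent
    dry mass-flow in ml/min STPD.

    The steady-state solution for this analyzer order is::

        VO2  = FRi (1 - FiCO2) [FiO2 - FeO2 (1 - FiO2) / (1 - FeO2)]
        VCO2 = FRi [FeCO2 (1 - FiCO2)(1 - FiO2) /
                    ((1 - FeCO2)(1 - FeO2)) - FiCO2]

    which reduces to the familiar ``FRi (FiO2 - FeO2) / (1 - FeO2)`` when
    incurrent CO2 is negligible.
    """
    fri = np.asarray(fri, dtype=float)
    fio2 = np.asarray(fio2, dtype=float)
    feo2 = np.asarray(feo2, dtype=float)
    fico2 = np.asarray(fico2, dtype=float)
    feco2 = np.asarray(feco2, dtype=float)
    if np.any(fri <= 0):
        raise RespirometryError("incurrent flow must be positive")
    for name, f in (("fio2", fio2), ("feo2", feo2),
                    ("fico2", fico2), ("feco2", feco2)):
        if np.any((f < 0) | (f >= 1)):
            raise RespirometryError(f"{name} outside [0, 1)")
    vo2 = fri * (1 - fico2) * (fio2 - feo2 * (1 - fio2) / (1 - feo2))
    vco2 = fri * (feco2 * (1 - fico2) * (1 - fio2)
                  / ((1 - feco2) * (1 - feo2)) - fico2)
    if vo2.ndim == 0:
        return float(vo2), float(vco2)
    return vo2, vco2


def excurrent_fractions(fri, fio2, fico2, vo2, vco2):
    """Forward model: analyzer fractions produced by known true rates.

    Exact inverse of :func:`compute_gas_rates`; used by the synthetic
    generator and by round-trip tests. Returns ``(feo2, feco2)`` on the
    same (dry CO2-free / dry) bases the analyzers report.
    """
    fri = np.asarray(fri, dtype=float)
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    fio2_full = fio2 * (1 - fico2)          # dry basis including CO2
    fre = fri - vo2 + vco2                  # dry excurrent flow
    feco2 = (fri * fico2 + vco2) / fre
    feo2_full = (fri * fio2_full - vo2) / fre
    feo2 = feo2_full / (1 - feco2)
    return feo2, feco2


def to_watts(vo2, rq, warn=True):
    """Convert O2 consumption (ml/min) to metabolic power (W).

    Uses the oxyjoule equivalent ``(16 + 5.164 RQ) J per ml O2``; division
    by 60 converts J/min to W. RQ outside the physiological [0.7, 1.0]
    band triggers a warning (values are never clamped).
    """
    vo2 = np.asarray(vo2, dtype=float)
    rq = np.asarray(rq, dtype=float)
    if np.any(vo2 < 0):
        raise RespirometryError("vo2 must be >= 0")
    if warn and np.any((rq < 0.7) | (rq > 1.0)):
        warnings.warn("RQ outside [0.7, 1.0]; oxyjoule conversion may be "
                      "extrapolating", stacklevel=2)
    out = vo2 * (OXY_A + OXY_B * rq) / 60.0
    return float(out) if out.ndim == 0 else out


# --- baseline drift correction ----------------------------------------------


def _segments(channel: np.ndarray) -> list[tuple[str, int, int]]:
    """Contiguous runs of the channel marker as (label, start_idx, stop_idx)."""
    change = np.flatnonzero(channel[1:] != channel[:-1]) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [len(channel)]))
    return [(channel[a], int(a), int(b)) for a, b in zip(starts, stops)]


def correct_baseline_drift(trace: pd.DataFrame) -> pd.DataFrame:
    """Attach interpolated incurrent reference fractions to a gas trace.

    For every animal sample the incurrent references (``fio2``, ``fico2``)
    are linearly interpolated between the means of the baseline segments
    bracketing it; the first and last 60 s of each baseline are discarded
    as a washout guard. ``feco2_wet`` baseline readings are dried with
    :func:`scrub_water_math` before averaging.

    Parameters
    ----------
    trace : DataFrame with columns ``t``, ``feo2``, ``feco2_wet``, ``wvp``,
        ``bp``, ``fri``, ``channel`` (BASELINE or channel number as str).

    Returns
    -------
    Copy of ``trace`` with added ``fio2`` and ``fico2`` columns.

    Raises
    ------
    RespirometryError
        If any bird segment lacks a baseline on either side.
    """
    channel = trace["channel"].to_numpy(dtype=object).astype(str)
    t = trace["t"].to_numpy(dtype=float)
    feo2 = trace["feo2"].to_numpy(dtype=float)
    feco2_dry = scrub_water_math(trace["feco2_wet"].to_numpy(dtype=float),
                                 trace["wvp"].to_numpy(dtype=float),
                                 trace["bp"].to_numpy(dtype=float))
    segs = _segments(channel)

    base_t, base_o2, base_co2 = [], [], []
    for label, a, b in segs:
        if label != BASELINE:
            continue
        tt = t[a:b]
        keep = (tt >= tt[0] + BASELINE_TRIM_S) & (tt <= tt[-1] - BASELINE_TRIM_S)
        if not keep.any():       # very short baseline: use it untrimmed
            keep = np.ones_like(tt, dtype=bool)
        base_t.append(tt[keep].mean())
        base_o2.append(feo2[a:b][keep].mean())
        base_co2.append(feco2_dry[a:b][keep].mean())
    base_t = np.asarray(base_t)
    base_o2 = np.asarray(base_o2)
    base_co2 = np.asarray(base_co2)

    for label, a, b in segs:
        if label == BASELINE:
            continue
        if not ((base_t < t[a]).any() and (base_t > t[b - 1]).any()):
            raise RespirometryError(
                f"bird segment (channel {label}, t={t[a]:.0f}..{t[b-1]:.0f} s) "
                "is not bracketed by baselines")

    out = trace.copy()
    # np.interp is exactly the piecewise-linear bridge between baseline means
    out["fio2"] = np.interp(t, base_t, base_o2)
    out["fico2"] = np.interp(t, base_t, base_co2)
    return out


def rate_series(trace: pd.DataFrame) -> pd.DataFrame:
    """Per-second rates for all animal samples of a drift-corrected trace.

    Returns a DataFrame ``t, channel, setpoint, cycle, vo2, vco2, rq,
    watts`` covering every non-baseline sample. RQ is computed per second;
    watts uses the per-second RQ without clamping.
    """
    if "fio2" not in trace.columns:
        trace = correct_baseline_drift(trace)
    mask = trace["channel"].astype(str) != BASELINE
    sub = trace.loc[mask]
    feco2 = scrub_water_math(sub["feco2_wet"].to_numpy(dtype=float),
                             sub["wvp"].to_numpy(dtype=float),
                             sub["bp"].to_numpy(dtype=float))
    vo2, vco2 = compute_gas_rates(sub["fri"].to_numpy(dtype=float),
                                  sub["fio2"].to_numpy(dtype=float),
                                  sub["feo2"].to_numpy(dtype=float),
                                  sub["fico2"].to_numpy(dtype=float),
                                  feco2)
    with np.errstate(divide="ignore", invalid="ignore"):
        rq = np.where(vo2 > 0, vco2 / np.where(vo2 > 0, vo2, 1.0), np.nan)
    watts = vo2 * (OXY_A + OXY_B * rq) / 60.0
    cols = {"t": sub["t"].to_numpy(dtype=float),
            "channel": sub["channel"].to_numpy(),
            "vo2": vo2, "vco2": vco2, "rq": rq, "watts": watts}
    for extra in ("setpoint", "cycle"):
        if extra in sub.columns:
            cols[extra] = sub[extra].to_numpy()
    return pd.DataFrame(cols)
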