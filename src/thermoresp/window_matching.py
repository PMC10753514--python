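"""RMR extraction via the stablest-2-min rule, with body-temperature matching.

For every 10-min bird sample the contiguous 2-min window with the lowest
standard deviation of the metabolic-power series is located (stride 1 s,
earliest window on ties). RMR at each ambient temperature is the lowest of
those window means across that temperature's cycles. Mean body temperature
is then extracted over the same (closed) time interval; if no reading
falls inside it, the single reading closest in time is used and flagged
as a fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class WindowError(ValueError):
    pass


@dataclass
class MetabolicEstimate:
    """RMR and matched body temperature for one bird x ambient temperature."""

    bird_id: str
    t_air: float
    window: tuple[float, float]      # (start_s, end_s), absolute time
    vo2: float
    vco2: float
    rq: float
    rmr_w: float
    tb_mean: float = np.nan
    tb_fallback: bool = False


def find_stablest_window(t: np.ndarray, x: np.ndarray, width_s: float = 120.0
                         ) -> tuple[tuple[float, float], float]:
    """Most stable contiguous window of a per-second series.

    Returns ``((start_s, end_s), mean)`` for the window of ``width_s``
    seconds minimizing the sample standard deviation of ``x``; ties break
    to the earliest start. The window spans ``width_s`` consecutive 1 Hz
    samples, i.e. the closed interval [start, start + width - 1].
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    w = int(width_s)
    n = len(x)
    if n < w:
        raise WindowError(f"segment ({n} s) shorter than window ({w} s)")
    # center for numerical stability of the cumsum variance
    xc = x - x.mean()
    c1 = np.concatenate(([0.0], np.cumsum(xc)))
    c2 = np.concatenate(([0.0], np.cumsum(xc**2)))
    s1 = c1[w:] - c1[:-w]
    s2 = c2[w:] - c2[:-w]
    var = (s2 - s1**2 / w) / (w - 1)
    i = int(np.argmin(np.round(var, 15)))     # earliest on (near-)exact ties
    mean = s1[i] / w + x.mean()
    return (float(t[i]), float(t[i + w - 1])), float(mean)


def window_table(rates: pd.DataFrame, width_s: float = 120.0,
                 on: str = "watts") -> pd.DataFrame:
    """Stablest-window summary per (channel, cycle) segment of a night.

    ``rates`` is the per-second output of
    :func:`thermoresp.respirometry.rate_series`. The search runs on the
    ``on`` column (metabolic watts by default, configurable to ``vo2``);
    gas quantities are averaged over the selected window.
    """
    rows = []
    for (cycle, channel), seg in rates.groupby(["cycle", "channel"], sort=True):
        t = seg["t"].to_numpy(dtype=float)
        (w0, w1), _ = find_stablest_window(t, seg[on].to_numpy(dtype=float),
                                           width_s)
        inwin = (t >= w0) & (t <= w1)
        win = seg.loc[inwin]
        rows.append({"cycle": cycle, "channel": channel,
                     "setpoint": float(seg["setpoint"].iloc[0]),
                     "start_s": w0, "end_s": w1,
                     "vo2": float(win["vo2"].mean()),
                     "vco2": float(win["vco2"].mean()),
                     "rq": float(win["rq"].mean()),
                     "watts": float(win["watts"].mean())})
    return pd.DataFrame(rows)


def extract_rmr(bird_id: str, t_air: float, windows: pd.DataFrame
                ) -> MetabolicEstimate | None:
    """Lowest stablest-window mean across one temperature's cycles.

    ``windows`` holds that bird's per-cycle window summaries at ``t_air``.
    Returns None (missing estimate) when no valid window exists.
    """
    if len(windows) == 0:
        return None
    best = windows.loc[windows["watts"].idxmin()]
    return MetabolicEstimate(
        bird_id=bird_id, t_air=float(t_air),
        window=(float(best["start_s"]), float(best["end_s"])),
        vo2=float(best["vo2"]), vco2=float(best["vco2"]),
        rq=float(best["rq"]), rmr_w=float(best["watts"]))


def match_tb(estimate: MetabolicEstimate, series) -> MetabolicEstimate:
    """Attach mean body temperature over the RMR window (closed interval).

    Falls back to the single reading closest in time to the window when no
    reading lies inside it, setting ``tb_fallback``. An empty series
    leaves ``tb_mean`` missing.
    """
    if series is None:
        return estimate
    valid = series.valid()
    if len(valid) == 0:
        return estimate
    t = valid["t"].to_numpy(dtype=float)
    temp = valid["temp"].to_numpy(dtype=float)
    w0, w1 = estimate.window
    inside = (t >= w0) & (t <= w1)
    if inside.any():
        estimate.tb_mean = float(temp[inside].mean())
        estimate.tb_fallback = False
    else:
        dist = np.where(t < w0, w0 - t, np.where(t > w1, t - w1, 0.0))
        estimate.tb_mean = float(temp[int(np.argmin(dist))])
        estimate.tb_fallback = True
    return estimate


def analysis_table(per_bird_windows: dict, birds: list, temps: dict,
                   on: str = "watts") -> pd.DataFrame:
    """One row per bird x ambient temperature: the input to statistics.

    ``per_bird_windows`` maps bird_id -> window summary table (all cycles);
    ``temps`` maps bird_id -> calibrated, QC'd TemperatureSeries.
    """
    rows = []
    for bird in birds:
        windows = per_bird_windows.get(bird.bird_id)
        if windows is None or len(windows) == 0:
            continue
        for t_air, sub in windows.groupby("setpoint"):
            est = extract_rmr(bird.bird_id, t_air, sub)
            if est is None:
                continue
            est = match_tb(est, temps.get(bird.bird_id))
            rows.append({"bird_id": bird.bird_id, "method": bird.method,
                         "t_air": est.t_air, "mass": bird.mass_pre,
                         "age": bird.age, "sex": bird.sex,
                         "start_s": est.window[0], "end_s": est.window[1],
                         "vo2": est.vo2, "vco2": est.vco2, "rq": est.rq,
                         "rmr_w": est.rmr_w, "tb_mean": est.tb_mean,
                         "tb_fallback": est.tb_fallback})
    return pd.DataFrame(rows)
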