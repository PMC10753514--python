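"""Temporal-variability indices of overnight body-temperature profiles.

Two per-bird indices of the 1-min-binned night profile:

* the coefficient of variation, CV = 100 x SD / mean — order-insensitive;
* the consecutive disparity index,
  D = (1 / (n - 1)) * sum |ln(x_{t+1} / x_t)| — mean absolute log-ratio of
  consecutive values, which is scale-free *and* sensitive to the
  chronological order of the series.

Pairs spanning a missing bin are skipped and the divisor reduced
accordingly, so gaps do not manufacture spurious disparity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class VariabilityError(ValueError):
    pass


def coefficient_of_variation(x) -> float:
    """CV in percent: 100 x sample SD (n-1 denominator) / mean."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 2:
        raise VariabilityError("CV needs at least two values")
    mean = x.mean()
    if mean <= 0:
        raise VariabilityError("CV undefined for non-positive mean")
    return float(100.0 * x.std(ddof=1) / mean)


def disparity_index(x) -> float:
    """Consecutive disparity index D of a (possibly gapped) series.

    ``x`` may contain NaN for missing bins; consecutive pairs that span a
    gap are skipped and the divisor is the number of retained pairs.
    """
    x = np.asarray(x, dtype=float)
    if np.nansum(~np.isnan(x)) < 2:
        raise VariabilityError("D needs at least two values")
    if np.any(x[~np.isnan(x)] <= 0):
        raise VariabilityError("D requires strictly positive values")
    ratio = x[1:] / x[:-1]
    ok = ~np.isnan(ratio)
    if ok.sum() == 0:
        raise VariabilityError("no consecutive pairs without a gap")
    return float(np.sum(np.abs(np.log(ratio[ok]))) / ok.sum())


def variability_table(binned: dict, birds: list) -> pd.DataFrame:
    """Per-bird CV and D of the 1-min-binned calibrated night profile.

    ``binned`` maps bird_id -> TemperatureSeries after QC, rounding and
    binning; control birds (no temperature stream) are skipped.
    """
    rows = []
    method = {b.bird_id: b.method for b in birds}
    for bird_id, series in binned.items():
        x = series.data["temp"].to_numpy(dtype=float)
        n = int(np.sum(~np.isnan(x)))
        if n < 2:
            continue
        rows.append({"bird_id": bird_id, "method": method[bird_id],
                     "cv": coefficient_of_variation(x),
                     "d_index": disparity_index(x), "n_bins": n})
    return pd.DataFrame(rows)
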