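"""CSV interchange formats for the pipeline's stage boundaries."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from .config import BirdRecord
from .temperature_qc import TemperatureSeries

GAS_VARIABLES = ("feo2", "feco2_wet", "wvp", "bp", "fri", "setpoint", "cycle")


def gas_to_tidy(gas: pd.DataFrame) -> pd.DataFrame:
    """Wide per-second gas trace -> tidy (timestamp_s, variable, value, channel)."""
    tidy = gas.melt(id_vars=["t", "channel"],
                    value_vars=[v for v in GAS_VARIABLES if v in gas.columns],
                    var_name="variable", value_name="value")
    tidy = tidy.rename(columns={"t": "timestamp_s"})
    return tidy.sort_values(["timestamp_s", "variable"], kind="stable",
                            ignore_index=True)


def gas_from_tidy(tidy: pd.DataFrame) -> pd.DataFrame:
    wide = tidy.pivot_table(index=["timestamp_s", "channel"],
                            columns="variable", values="value",
                            sort=False).reset_index()
    wide = wide.rename(columns={"timestamp_s": "t"})
    wide["cycle"] = wide["cycle"].astype(int)
    return wide.sort_values("t", ignore_index=True)


def write_birds(birds: list, path) -> None:
    pd.DataFrame([dataclasses.asdict(b) for b in birds]).to_csv(path,
                                                                index=False)


def read_birds(path) -> list:
    df = pd.read_csv(path)
    return [BirdRecord(**{k: rec[k] for k in
                          ("bird_id", "method", "mass_capture", "mass_pre",
                           "mass_post", "age", "sex", "night", "channel")})
            for rec in df.to_dict("records")]


def write_temps(temps: dict, path) -> None:
    frames = []
    for series in temps.values():
        df = series.data.copy()
        df.insert(0, "bird_id", series.bird_id)
        df.insert(1, "sensor", series.sensor)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_temps(path) -> dict:
    df = pd.read_csv(path)
    out = {}
    for (bird_id, sensor), sub in df.groupby(["bird_id", "sensor"], sort=True):
        data = sub[["t", "temp", "flag"]].reset_index(drop=True)
        out[bird_id] = TemperatureSeries(bird_id=bird_id, sensor=sensor,
                                         data=data)
    return out


def birds_frame(birds: list) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(b) for b in birds])


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
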