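"""Synthetic overnight respirometry + body-temperature experiments.

Emulates the study's recordings so the full pipeline is testable without
live birds: multiplexed 1 Hz analyzer streams with slow baseline drift, a
quiescent metabolic plateau hidden inside each 10-min bird sample,
per-sensor body-temperature streams (PIT tags with occasional misread
spikes, thermocouples with a 30-50 degC recording window), a bench
calibration fixture, and per-bird metadata. Ground truth (true RMR, true
temperature levels, sensor gains/offsets, plateau windows, injected spike
positions) is retained alongside the output for recovery testing.

One overnight run hosts five birds, one per method including the
un-instrumented control; multiple runs fill the design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import (BASELINE, BirdRecord, ConfigurationError,
                     ExperimentConfig, sensor_kind)
from .respirometry import OXY_A, OXY_B, excurrent_fractions
from .temperature_qc import TemperatureSeries

#: minimum spacing between injected misread spikes, so each is "single
#: erratically occurring" for the isolated-spike QC rule
SPIKE_MIN_GAP_S = 130


def _ar1(rng: np.random.Generator, n: int, sd: float, tau_s: float) -> np.ndarray:
    """Stationary AR(1) series at 1 Hz with marginal SD ``sd``."""
    if sd == 0:
        return np.zeros(n)
    phi = np.exp(-1.0 / tau_s)
    e = rng.normal(0.0, sd * np.sqrt(1 - phi**2), size=n)
    x0 = rng.normal(0.0, sd)
    x, _ = lfilter([1.0], [1.0, -phi], e, zi=[phi * x0])
    return x


@dataclass
class ExperimentTruth:
    """Generator ground truth retained for recovery tests."""

    #: bird_id -> {setpoint: true RMR in W} (noiseless physiological value)
    rmr_w: dict = field(default_factory=dict)
    #: bird_id -> {setpoint: true mean body temperature level, degC}
    tb_level: dict = field(default_factory=dict)
    #: (bird_id, cycle) -> (start_s, end_s, plateau watts incl. cycle jitter)
    plateau: dict = field(default_factory=dict)
    #: bird_id -> (gain, offset) of that bird's temperature sensor
    sensor: dict = field(default_factory=dict)
    #: bird_id -> sorted array of injected misread-spike times (s)
    spikes: dict = field(default_factory=dict)
    #: calibration unit -> (gain, offset)
    calib_units: dict = field(default_factory=dict)
    #: night -> dict of drift parameters and flow
    night: dict = field(default_factory=dict)
    fio2: float = 0.0
    fico2: float = 0.0

    @property
    def n_spikes(self) -> int:
        return int(sum(len(v) for v in self.spikes.values()))


@dataclass
class SyntheticExperiment:
    """Everything one simulated study produces, plus its ground truth."""

    config: ExperimentConfig
    birds: list                      # list[BirdRecord]
    gas: list                        # one DataFrame per night
    temps: dict                      # bird_id -> TemperatureSeries
    calibration: pd.DataFrame
    truth: ExperimentTruth


# --- birds -------------------------------------------------------------------


def generate_birds(config: ExperimentConfig,
                   rng: np.random.Generator) -> list[BirdRecord]:
    """Assign birds to methods, nights and channels with balanced metadata."""
    birds = []
    n_nights = config.n_birds_per_method
    methods = list(config.methods)
    k = 0
    for night in range(n_nights):
        chans = rng.permutation(len(methods)) + 1
        for method, chan in zip(methods, chans):
            k += 1
            # mass_mean parametrizes the mass at measurement (pre), the
            # covariate entering the physiological model and the statistics
            pre = float(np.clip(rng.normal(config.mass_mean, config.mass_sd),
                                10.5, 24.2))
            capture = pre + abs(rng.normal(0.3, 0.1))
            post = pre - abs(rng.normal(0.8, 0.15))
            birds.append(BirdRecord(
                bird_id=f"B{k:03d}", method=method,
                mass_capture=round(capture, 1), mass_pre=round(pre, 1),
                mass_post=round(post, 1),
                age="2cy" if rng.random() < 0.5 else "3cy+",
                sex="F" if rng.random() < 0.5 else "M",
                night=night, channel=int(chan)))
    return birds


# --- calibration fixture -----------------------------------------------------


def generate_calibration_fixture(config: ExperimentConfig,
                                 units: list | None = None,
                                 rng: np.random.Generator | None = None,
                                 truth: ExperimentTruth | None = None
                                 ) -> pd.DataFrame:
    """Bench fixture: paired (sensor reading, chamber reference) rows.

    Each comparison unit is a thermocouple or PIT tag read at the reference
    temperatures (default 35/40/45 degC). ``units`` may supply explicit
    ``(unit_id, sensor, gain, offset)`` tuples; by default ``calib_n_units``
    units are drawn from the sensor population, alternating PIT and
    thermocouple channels.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if units is None:
        units = []
        for u in range(1, config.calib_n_units + 1):
            kind = "PIT" if u % 2 else "thermocouple"
            units.append((f"U{u:02d}", kind,
                          rng.normal(1.0, config.sensor_gain_sd),
                          rng.normal(0.0, config.sensor_offset_sd)))
    if not units:
        raise ConfigurationError("calibration fixture needs at least one sensor unit")
    rows = []
    for unit_id, kind, gain, offset in units:
        if truth is not None:
            truth.calib_units[unit_id] = (gain, offset)
        for ref in config.calib_refs:
            reading = gain * ref + offset + rng.normal(0.0, config.calib_noise_sd)
            rows.append((unit_id, kind, float(ref), float(reading)))
    return pd.DataFrame(rows, columns=["unit", "sensor", "reference_c", "reading_c"])


# --- metabolic traces --------------------------------------------------------


def _true_rmr_w(config: ExperimentConfig, mass: float, intercept: float,
                setpoint: float) -> float:
    """Noiseless RMR (W) at one ambient temperature.

    Temperature acts multiplicatively on the reference-mass baseline;
    mass and the bird intercept act additively (matching the additive
    covariate structure of the downstream model).
    """
    ratios = {25.0: 1.0,
              5.0: config.rmr_ratio_5v25,
              -15.0: config.rmr_ratio_5v25 * config.rmr_ratio_m15v5}
    # interpolate multiplicatively for non-default setpoints
    sp = float(setpoint)
    if sp in ratios:
        ratio = ratios[sp]
    else:
        ratio = float(np.interp(sp, [-15.0, 5.0, 25.0],
                                [ratios[-15.0], ratios[5.0], ratios[25.0]]))
    return config.rmr_base_25 * ratio + config.mass_slope * (mass - config.mass_ref) \
        + intercept


def _segment_vo2(rng: np.random.Generator, config: ExperimentConfig,
                 n: int, plateau_vo2: float) -> tuple[np.ndarray, int, int]:
    """True VO2 trace of one 10-min sample with a hidden quiescent plateau."""
    width = int(config.plateau_min * 60)
    start = int(rng.integers(0, n - width + 1))
    excess = np.clip(config.activity_excess
                     + _ar1(rng, n, config.activity_sd, 30.0), 0.05, None)
    vo2 = plateau_vo2 * (1.0 + excess)
    vo2[start:start + width] = plateau_vo2
    return vo2, start, start + width


def _night_gas(rng: np.random.Generator, config: ExperimentConfig,
               night: int, night_birds: list, bird_state: dict,
               truth: ExperimentTruth) -> pd.DataFrame:
    """Multiplexed 1 Hz analyzer stream for one overnight run."""
    n = config.total_min * 60
    t = np.arange(n, dtype=float)
    T = float(n)

    fri = max(float(rng.normal(config.flow_mean, config.flow_sd)), 100.0)
    phase_o2, phase_co2 = rng.uniform(0, 2 * np.pi, size=2)
    slope_o2 = rng.choice([-1, 1]) * config.o2_drift_linear
    slope_co2 = rng.choice([-1, 1]) * config.co2_drift_linear
    period = config.drift_period_h * 3600.0
    drift_o2 = slope_o2 * t / T + config.o2_drift_sin_amp * np.sin(
        2 * np.pi * t / period + phase_o2)
    drift_co2 = slope_co2 * t / T + config.co2_drift_sin_amp * np.sin(
        2 * np.pi * t / period + phase_co2)
    truth.night[night] = {"fri": fri, "slope_o2": slope_o2,
                          "sin_amp_o2": config.o2_drift_sin_amp,
                          "phase_o2": phase_o2, "period_s": period}

    bp = config.bp_kpa
    # default: animal-free (baseline) air everywhere
    feo2 = np.full(n, config.fio2)
    feco2_dry = np.full(n, config.fico2)
    wvp = np.full(n, 0.02)          # dried incurrent air
    channel = np.full(n, BASELINE, dtype=object)
    cycle_idx = np.zeros(n, dtype=int)

    by_channel = {b.channel: b for b in night_birds}
    setpoints = config.cycle_setpoints()
    for cyc in range(config.n_cycles):
        sp = setpoints[cyc]
        for label, a, b in config.cycle_schedule(cyc):
            cycle_idx[a:b] = cyc
            if label == BASELINE:
                continue
            bird = by_channel[int(label)]
            st = bird_state[bird.bird_id]
            rmr_w = _true_rmr_w(config, bird.mass_pre, st["intercept"], sp)
            plateau_w = rmr_w * (1.0 + rng.normal(0.0, config.cycle_jitter_sd))
            plateau_vo2 = plateau_w * 60.0 / (OXY_A + OXY_B * st["rq"])
            vo2, ps, pe = _segment_vo2(rng, config, b - a, plateau_vo2)
            vco2 = st["rq"] * vo2
            fe_o2, fe_co2 = excurrent_fractions(fri, config.fio2, config.fico2,
                                                vo2, vco2)
            channel[a:b] = label
            feo2[a:b] = fe_o2
            feco2_dry[a:b] = fe_co2
            wvp[a:b] = config.wvp_animal_kpa
            truth.plateau[(bird.bird_id, cyc)] = (float(a + ps), float(a + pe),
                                                  plateau_w)
            truth.rmr_w.setdefault(bird.bird_id, {})[sp] = rmr_w

    feo2 = feo2 + drift_o2 + rng.normal(0.0, config.o2_noise_sd, n)
    feco2_wet = feco2_dry * (bp - wvp) / bp + drift_co2 \
        + rng.normal(0.0, config.co2_noise_sd, n)
    return pd.DataFrame({
        "t": t, "feo2": feo2, "feco2_wet": np.clip(feco2_wet, 0.0, None),
        "wvp": wvp, "bp": bp, "fri": fri, "channel": channel,
        "setpoint": config.setpoint_at(t), "cycle": cycle_idx, "night": night})


# --- body-temperature traces -------------------------------------------------


def _tb_level_curve(config: ExperimentConfig, method: str,
                    t: np.ndarray) -> np.ndarray:
    """Method-specific true temperature level tracking the chamber program.

    Core methods sit at ``tb_core_25`` in thermoneutrality and drop by
    ``tb_drop_subTNZ`` below it; the cutaneous method shows an additional
    ambient-dependent deficit. Levels ramp linearly over ``tb_ramp_min``
    after each setpoint change.
    """
    def level(sp: float) -> float:
        lev = config.tb_core_25 - (config.tb_drop_subTNZ if sp < 25.0 else 0.0)
        if method == "CU":
            deficit = float(np.interp(sp, [-15.0, 5.0, 25.0],
                                      [config.cu_deficit_m15,
                                       config.cu_deficit_5, 0.0]))
            lev -= deficit
        return lev

    knots_t, knots_v = [0.0], [level(config.chamber_program[0][0])]
    edge = 0.0
    ramp = config.tb_ramp_min * 60.0
    for i, (sp, dur) in enumerate(config.chamber_program):
        if i > 0:
            knots_t.extend([edge, edge + ramp])
            knots_v.extend([level(config.chamber_program[i - 1][0]), level(sp)])
        edge += dur * 60.0
    knots_t.append(edge)
    knots_v.append(level(config.chamber_program[-1][0]))
    return np.interp(t, knots_t, knots_v)


def _place_spikes(rng: np.random.Generator, n: int, rate: float) -> np.ndarray:
    """Isolated spike positions: binomial count, pairwise gap > SPIKE_MIN_GAP_S."""
    k = rng.binomial(n, rate)
    pos: list[int] = []
    attempts = 0
    while len(pos) < k and attempts < 100 * max(k, 1):
        cand = int(rng.integers(0, n))
        if all(abs(cand - p) > SPIKE_MIN_GAP_S for p in pos):
            pos.append(cand)
        attempts += 1
    return np.array(sorted(pos), dtype=int)


def _bird_temperature(rng: np.random.Generator, config: ExperimentConfig,
                      bird: BirdRecord, tb_intercept: float,
                      truth: ExperimentTruth) -> TemperatureSeries | None:
    kind = sensor_kind(bird.method)
    if kind is None:
        return None
    n = config.total_min * 60
    t = np.arange(n, dtype=float)
    level = _tb_level_curve(config, bird.method, t)
    w_sd = config.wander_sd * (config.cu_noise_scale if bird.method == "CU" else 1.0)
    tb = level + tb_intercept + _ar1(rng, n, w_sd, config.wander_tau_s)
    if bird.method == "CL":
        tb = tb + _ar1(rng, n, config.cl_jitter_sd * config.cl_jitter_scale,
                       config.cl_jitter_tau_s)

    gain, offset = truth.sensor[bird.bird_id]
    truth.tb_level[bird.bird_id] = {
        float(sp): float(config.tb_core_25
                         - (config.tb_drop_subTNZ if sp < 25.0 else 0.0)
                         - (float(np.interp(sp, [-15.0, 5.0, 25.0],
                                            [config.cu_deficit_m15,
                                             config.cu_deficit_5, 0.0]))
                            if bird.method == "CU" else 0.0))
        for sp, _ in config.chamber_program}

    if kind == "PIT":
        reading = gain * tb + offset + rng.normal(0.0, config.pit_noise_sd, n)
        reading = np.round(reading, 1)          # 0.1 degC tag resolution
        spikes = _place_spikes(rng, n, config.misread_rate)
        if len(spikes):
            reading[spikes] = np.round(rng.uniform(46.0, 50.0, len(spikes)), 1)
        truth.spikes[bird.bird_id] = t[spikes]
        keep = np.ones(n, dtype=bool)
    else:
        reading = gain * tb + offset + rng.normal(0.0, config.tc_noise_sd, n)
        lo, hi = config.tc_window
        keep = (reading >= lo) & (reading <= hi)   # device recording window
        truth.spikes[bird.bird_id] = np.array([])
    data = pd.DataFrame({"t": t[keep], "temp": reading[keep]})
    data["flag"] = "ok"
    return TemperatureSeries(bird_id=bird.bird_id, sensor=kind, data=data)


# --- top level ---------------------------------------------------------------


def generate_experiment(config: ExperimentConfig) -> SyntheticExperiment:
    """Generate one complete seeded study.

    Returns birds, one multiplexed gas trace per night, per-bird raw
    temperature series, the bench calibration table, and the retained
    ground truth. Two calls with the same config produce identical output.
    """
    rng = np.random.default_rng(config.seed)
    truth = ExperimentTruth(fio2=config.fio2, fico2=config.fico2)
    birds = generate_birds(config, rng)
    calib = generate_calibration_fixture(config, rng=rng, truth=truth)

    bird_state = {}
    for b in birds:
        bird_state[b.bird_id] = {
            "intercept": rng.normal(0.0, config.rmr_intercept_sd),
            "rq": float(np.clip(rng.normal(config.rq_mean, config.rq_sd),
                                0.7, 1.0)),
            "tb_intercept": rng.normal(0.0, config.tb_intercept_sd),
        }
        truth.sensor[b.bird_id] = (rng.normal(1.0, config.sensor_gain_sd),
                                   rng.normal(0.0, config.sensor_offset_sd))

    gas, temps = [], {}
    for night in range(config.n_birds_per_method):
        night_birds = [b for b in birds if b.night == night]
        gas.append(_night_gas(rng, config, night, night_birds, bird_state, truth))
        for b in night_birds:
            series = _bird_temperature(rng, config, b,
                                       bird_state[b.bird_id]["tb_intercept"],
                                       truth)
            if series is not None:
                temps[b.bird_id] = series
    return SyntheticExperiment(config=config, birds=birds, gas=gas,
                               temps=temps, calibration=calib, truth=truth)
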