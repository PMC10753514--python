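"""Experiment configuration and the multiplexed measurement schedule.

The overnight protocol puts five birds (one per measurement method,
including the un-instrumented control) in individual chambers inside a
climate cabinet. The cabinet steps through an ambient-temperature program
(default 25, 5, -15, 5, 25 degC; 160 min per step except a final 80 min
block), while a multiplexer cycles the gas analyzers through the chambers:
each 80-min measurement cycle starts and ends with a 15-min baseline on
animal-free air, bracketing five sequential 10-min bird samples.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import yaml

METHODS = ("IP", "CL", "SC", "CU", "C")
#: methods measured with an implanted PIT tag
PIT_METHODS = ("IP", "SC")
#: methods measured with a type-T thermocouple
THERMOCOUPLE_METHODS = ("CL", "CU")

BASELINE = "BASELINE"


class ConfigurationError(ValueError):
    """Raised for invalid experiment configurations."""


@dataclass(frozen=True)
class ExperimentConfig:
    """Parameters of a synthetic overnight respirometry experiment.

    The defaults encode the study conditions: 13 birds per method, the
    25/5/-15/5/25 degC chamber program, 594 +/- 22 ml/min STPD flow, a 29%
    RMR increase at 5 vs 25 degC, a further 53% increase at -15 vs 5 degC,
    a 0.026 W/g mass effect, and cutaneous temperature deficits of 2.35
    and 2.7 degC below thermoneutrality. Absolute baselines (rmr_base_25,
    tb_core_25) are free choices documented in docs/methods.md.
    """

    n_birds_per_method: int = 13
    methods: Sequence[str] = METHODS
    #: (setpoint degC, duration min) steps of the climate-chamber program
    chamber_program: Sequence[tuple[float, int]] = (
        (25.0, 160), (5.0, 160), (-15.0, 160), (5.0, 160), (25.0, 80))
    baseline_min: int = 15
    birds_per_cycle: int = 5
    sample_min: int = 10

    # --- gas / analyzer ---
    flow_mean: float = 594.0       # ml/min STPD, incurrent dry flow
    flow_sd: float = 22.0          # between-night SD of the metered flow
    fio2: float = 0.2095           # incurrent O2 fraction (dry, CO2-free basis)
    fico2: float = 0.0004          # incurrent CO2 fraction (dry)
    bp_kpa: float = 101.3          # barometric pressure
    wvp_animal_kpa: float = 0.6    # excurrent water vapour pressure (bird evaporation)
    o2_noise_sd: float = 2e-5      # per-sample analyzer noise, O2 fraction
    co2_noise_sd: float = 5e-6     # per-sample analyzer noise, CO2 fraction
    o2_drift_linear: float = 5e-4  # total linear baseline drift over the night
    o2_drift_sin_amp: float = 2e-4
    co2_drift_linear: float = 5e-5
    co2_drift_sin_amp: float = 2e-5
    drift_period_h: float = 12.0
    analyzer_lag_s: int = 0        # optional channel-to-analyzer lag (default none)

    # --- physiology: metabolic rate ---
    rmr_base_25: float = 0.18      # W at reference mass, thermoneutrality
    rmr_ratio_5v25: float = 1.29   # multiplicative RMR effect, 5 vs 25 degC
    rmr_ratio_m15v5: float = 1.53  # multiplicative RMR effect, -15 vs 5 degC
    mass_slope: float = 0.026      # W/g, additive mass effect
    mass_ref: float = 17.0         # g, reference mass for rmr_base_25
    mass_mean: float = 17.0        # g, population mean capture mass
    mass_sd: float = 1.2
    rmr_intercept_sd: float = 0.012   # W, between-bird intercept
    cycle_jitter_sd: float = 0.02     # relative SD of the per-cycle resting plateau
    plateau_min: float = 3.0          # quiescent plateau width within a sample
    activity_excess: float = 0.25     # mean relative VO2 excess outside the plateau
    activity_sd: float = 0.15         # fluctuation of the activity excess
    rq_mean: float = 0.80
    rq_sd: float = 0.03

    # --- physiology: body temperature ---
    tb_core_25: float = 38.0       # degC, nocturnal core temperature in the TNZ
    tb_drop_subTNZ: float = 1.5    # degC, core drop below thermoneutrality
    cu_deficit_5: float = 2.35     # degC, cutaneous deficit at 5 degC
    cu_deficit_m15: float = 2.7    # degC, cutaneous deficit at -15 degC
    tb_intercept_sd: float = 0.3   # degC, between-bird intercept
    wander_sd: float = 1.0         # degC, slow within-night wander (all methods)
    wander_tau_s: float = 1800.0
    tb_ramp_min: float = 10.0      # ramp of the tb level after a setpoint change
    cu_noise_scale: float = 1.0    # multiplier on the CU wander amplitude
    cl_jitter_scale: float = 1.0   # multiplier on the CL probe-movement jitter
    cl_jitter_sd: float = 0.25     # degC at scale 1.0
    cl_jitter_tau_s: float = 120.0
    pit_noise_sd: float = 0.05     # degC, PIT sensor noise (before 0.1 quantization)
    tc_noise_sd: float = 0.03      # degC, thermocouple noise
    misread_rate: float = 2e-5     # per-sample probability of an IP/SC spike
    tc_window: tuple[float, float] = (30.0, 50.0)  # thermocouple recording window

    # --- sensors / calibration ---
    sensor_offset_sd: float = 0.2  # degC, population SD of sensor offsets
    sensor_gain_sd: float = 0.005  # population SD of sensor gains around 1
    calib_n_units: int = 33        # bench comparison units
    calib_refs: Sequence[float] = (35.0, 40.0, 45.0)
    calib_noise_sd: float = 0.05   # degC, bench reading noise

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_birds_per_method <= 0:
            raise ConfigurationError("n_birds_per_method must be positive")
        if self.baseline_min <= 0 or self.sample_min <= 0:
            raise ConfigurationError("schedule durations must be positive")
        if self.birds_per_cycle <= 0:
            raise ConfigurationError("birds_per_cycle must be positive")
        if any(dur <= 0 for _, dur in self.chamber_program):
            raise ConfigurationError("chamber program durations must be positive")
        if self.total_min % self.cycle_min:
            raise ConfigurationError(
                f"chamber program ({self.total_min} min) is not a whole "
                f"number of {self.cycle_min} min measurement cycles")
        if self.rmr_ratio_5v25 <= 1 or self.rmr_ratio_m15v5 <= 1:
            raise ConfigurationError("rmr ratios must exceed 1")
        if self.cu_deficit_5 < 0 or self.cu_deficit_m15 < 0:
            raise ConfigurationError("cutaneous deficits must be >= 0")
        if self.flow_sd < 0:
            raise ConfigurationError("flow_sd must be >= 0")
        if not 0 <= self.misread_rate < 1:
            raise ConfigurationError("misread_rate must be a probability")

    # --- schedule arithmetic -------------------------------------------------

    @property
    def cycle_min(self) -> int:
        """Length of one measurement cycle: 15 + 5x10 + 15 = 80 min."""
        return 2 * self.baseline_min + self.birds_per_cycle * self.sample_min

    @property
    def total_min(self) -> int:
        return sum(dur for _, dur in self.chamber_program)

    @property
    def n_cycles(self) -> int:
        return self.total_min // self.cycle_min

    def cycle_setpoints(self) -> list[float]:
        """Chamber setpoint of each measurement cycle, in order."""
        out: list[float] = []
        for setpoint, dur in self.chamber_program:
            out.extend([setpoint] * (dur // self.cycle_min))
        return out

    def setpoint_at(self, t_s: "object"):
        """Chamber setpoint at time(s) ``t_s`` seconds since lights-off."""
        import numpy as np

        edges, sets = [0.0], []
        for setpoint, dur in self.chamber_program:
            edges.append(edges[-1] + dur * 60.0)
            sets.append(setpoint)
        idx = np.clip(np.searchsorted(edges, np.asarray(t_s), side="right") - 1,
                      0, len(sets) - 1)
        return np.asarray(sets)[idx]

    def cycle_schedule(self, cycle: int) -> list[tuple[str, int, int]]:
        """Segments of one cycle as ``(label, start_s, end_s)`` tuples.

        Labels are ``BASELINE`` or the channel number as a string.
        """
        t0 = cycle * self.cycle_min * 60
        base = self.baseline_min * 60
        samp = self.sample_min * 60
        segs = [(BASELINE, t0, t0 + base)]
        t = t0 + base
        for ch in range(1, self.birds_per_cycle + 1):
            segs.append((str(ch), t, t + samp))
            t += samp
        segs.append((BASELINE, t, t + base))
        return segs

    # --- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        d["chamber_program"] = [list(p) for p in self.chamber_program]
        d["calib_refs"] = list(self.calib_refs)
        d["tc_window"] = list(self.tc_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "methods" in d:
            d["methods"] = tuple(d["methods"])
        if "chamber_program" in d:
            d["chamber_program"] = tuple(tuple(p) for p in d["chamber_program"])
        if "calib_refs" in d:
            d["calib_refs"] = tuple(d["calib_refs"])
        if "tc_window" in d:
            d["tc_window"] = tuple(d["tc_window"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d.get("generator", d))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"generator": self.to_dict()}, fh, sort_keys=False)


@dataclass(frozen=True)
class BirdRecord:
    """Metadata for one bird: identity, method, biometrics, channel."""

    bird_id: str
    method: str
    mass_capture: float
    mass_pre: float
    mass_post: float
    age: str            # "2cy" or "3cy+"
    sex: str            # "F" or "M"
    night: int          # overnight run hosting this bird
    channel: int        # multiplexer channel 1..5

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigurationError(f"unknown method {self.method!r}")
        if not 1 <= self.channel <= 5:
            raise ConfigurationError("channel must be 1..5")


def sensor_kind(method: str) -> str | None:
    """Sensor type used by a measurement method (None for controls)."""
    if method in PIT_METHODS:
        return "PIT"
    if method in THERMOCOUPLE_METHODS:
        return "thermocouple"
    return None
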