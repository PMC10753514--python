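import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import fsolve

import thermoresp as tr
from thermoresp.respirometry import (RespirometryError, correct_baseline_drift,
                                     excurrent_fractions, rate_series)
from thermoresp.synthetic import generate_experiment

from conftest import quiet_config


class TestScrubWaterMath:
    def test_dry_air_unchanged(self):
        assert tr.scrub_water_math(0.004, 0.0, 101.0) == 0.004

    def test_reference_value(self):
        np.testing.assert_allclose(tr.scrub_water_math(0.004, 1.0, 101.0),
                                   0.004 * 101.0 / 100.0, rtol=1e-12)

    def test_zero_fraction_stays_zero(self):
        assert tr.scrub_water_math(0.0, 2.0, 101.0) == 0.0

    def test_saturated_air_rejected(self):
        with pytest.raises(RespirometryError):
            tr.scrub_water_math(0.004, 101.0, 101.0)

    @given(f=st.floats(0, 0.05), wvp=st.floats(0, 5), bp=st.floats(90, 105))
    def test_exact_inverse_of_dilution(self, f, wvp, bp):
        diluted = f * (bp - wvp) / bp
        np.testing.assert_allclose(tr.scrub_water_math(diluted, wvp, bp), f,
                                   rtol=1e-12, atol=1e-15)


def _oracle_rates(fri, fio2, feo2, fico2, feco2):
    """Independent numerical solution of the steady-state mass balance.

    Solves for (vo2, vco2) such that the forward chamber model reproduces
    the analyzer readings, without using the closed-form equations.
    """
    def eqs(v):
        vo2, vco2 = v
        fio2_full = fio2 * (1 - fico2)
        fre = fri - vo2 + vco2
        feco2_m = (fri * fico2 + vco2) / fre
        feo2_m = (fri * fio2_full - vo2) / fre / (1 - feco2_m)
        return feo2_m - feo2, feco2_m - feco2

    return fsolve(eqs, [1.0, 1.0], xtol=1e-13)


class TestComputeGasRates:
    def test_matches_independent_mass_balance_solver(self):
        fri, fio2, fico2 = 600.0, 0.2095, 0.0
        feo2, feco2 = 0.2065, 0.0030
        vo2, vco2 = tr.compute_gas_rates(fri, fio2, feo2, fico2, feco2)
        ref_vo2, ref_vco2 = _oracle_rates(fri, fio2, feo2, fico2, feco2)
        np.testing.assert_allclose([vo2, vco2], [ref_vo2, ref_vco2], rtol=1e-9)

    def test_matches_solver_with_incurrent_co2(self):
        args = (594.0, 0.2095, 0.2086, 0.0004, 0.0018)
        np.testing.assert_allclose(tr.compute_gas_rates(*args),
                                   _oracle_rates(*args), rtol=1e-9)

    def test_no_gas_exchange_gives_zero_rates(self):
        vo2, vco2 = tr.compute_gas_rates(600.0, 0.2095, 0.2095, 0.0004, 0.0004)
        assert vo2 == pytest.approx(0.0, abs=1e-12)
        assert vco2 == pytest.approx(0.0, abs=1e-12)

    def test_linearity_in_flow(self):
        a = tr.compute_gas_rates(600.0, 0.2095, 0.2065, 0.0004, 0.0030)
        b = tr.compute_gas_rates(1200.0, 0.2095, 0.2065, 0.0004, 0.0030)
        np.testing.assert_allclose(np.array(b), 2 * np.array(a), rtol=1e-12)

    def test_round_trip_with_forward_model(self):
        feo2, feco2 = excurrent_fractions(594.0, 0.2095, 0.0004, 0.9, 0.72)
        vo2, vco2 = tr.compute_gas_rates(594.0, 0.2095, feo2, 0.0004, feco2)
        np.testing.assert_allclose([vo2, vco2], [0.9, 0.72], rtol=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(RespirometryError):
            tr.compute_gas_rates(0.0, 0.2095, 0.2065, 0.0, 0.003)
        with pytest.raises(RespirometryError):
            tr.compute_gas_rates(600.0, 1.2, 0.2065, 0.0, 0.003)


class TestToWatts:
    def test_zero_consumption_is_zero_power(self):
        assert tr.to_watts(0.0, 0.85) == 0.0

    def test_oxyjoule_reference_value(self):
        # 1 ml/min at RQ=1: (16 + 5.164) J/ml over 60 s
        np.testing.assert_allclose(tr.to_watts(1.0, 1.0),
                                   (16.0 + 5.164) / 60.0, rtol=1e-12)

    def test_monotone_in_vo2(self):
        v = np.linspace(0.1, 2.0, 25)
        w = tr.to_watts(v, 0.8)
        assert np.all(np.diff(w) > 0)

    def test_warns_outside_physiological_rq(self):
        with pytest.warns(UserWarning):
            tr.to_watts(1.0, 1.3)
        with pytest.raises(RespirometryError):
            tr.to_watts(-1.0, 0.8)


def _toy_trace(base_first, base_last, n_base=900, n_bird=600):
    """One cycle: baseline, one bird segment, baseline, linear drift."""
    n = 2 * n_base + n_bird
    t = np.arange(n, dtype=float)
    feo2 = np.empty(n)
    feo2[:n_base] = base_first
    feo2[-n_base:] = base_last
    feo2[n_base:n_base + n_bird] = 0.2000   # animal depletion, arbitrary
    channel = np.array(["BASELINE"] * n_base + ["1"] * n_bird
                       + ["BASELINE"] * n_base, dtype=object)
    return pd.DataFrame({"t": t, "feo2": feo2,
                         "feco2_wet": 0.001, "wvp": 0.0, "bp": 101.3,
                         "fri": 600.0, "channel": channel})


class TestBaselineDrift:
    def test_constant_baselines_interpolate_to_constant(self):
        out = correct_baseline_drift(_toy_trace(0.2095, 0.2095))
        np.testing.assert_allclose(out["fio2"], 0.2095, rtol=1e-12)

    def test_linear_midpoint(self):
        out = correct_baseline_drift(_toy_trace(0.2095, 0.2093))
        mid = out.loc[out["channel"] == "1", "fio2"].to_numpy()
        center = mid[len(mid) // 2]
        assert abs(center - 0.2094) < 2e-7

    def test_unbracketed_segment_rejected(self):
        trace = _toy_trace(0.2095, 0.2095)
        trace = trace[trace["t"] < 1200].copy()     # drop the closing baseline
        with pytest.raises(RespirometryError, match="channel 1"):
            correct_baseline_drift(trace)

    def test_recovers_injected_drift_within_noise(self):
        cfg = quiet_config(n_birds_per_method=1, o2_noise_sd=2e-5,
                           o2_drift_linear=5e-4, o2_drift_sin_amp=2e-4, seed=2)
        exp = generate_experiment(cfg)
        gas = exp.gas[0]
        out = correct_baseline_drift(gas)
        night = exp.truth.night[0]
        t = out["t"].to_numpy()
        true_fio2 = (exp.truth.fio2 + night["slope_o2"] * t / t[-1]
                     + night["sin_amp_o2"]
                     * np.sin(2 * np.pi * t / night["period_s"]
                              + night["phase_o2"]))
        mask = out["channel"] != "BASELINE"
        resid = (out.loc[mask, "fio2"] - true_fio2[mask]).abs()
        assert resid.max() < 3 * cfg.o2_noise_sd


def test_noise_free_end_to_end_recovery_within_0p1_percent():
    """Constant true VO2, no noise, linear drift only -> exact recovery."""
    cfg = quiet_config(n_birds_per_method=1, o2_drift_linear=5e-4,
                       co2_drift_linear=5e-5, activity_sd=0.0,
                       plateau_min=10.0, seed=4)
    exp = generate_experiment(cfg)
    rates = rate_series(correct_baseline_drift(exp.gas[0]))
    for bird in exp.birds:
        true = exp.truth.rmr_w[bird.bird_id]
        sub = rates[rates["channel"] == str(bird.channel)]
        for sp, grp in sub.groupby("setpoint"):
            np.testing.assert_allclose(grp["watts"], true[sp], rtol=1e-3)
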