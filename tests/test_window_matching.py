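import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thermoresp as tr
from thermoresp.temperature_qc import TemperatureSeries
from thermoresp.window_matching import WindowError, window_table


def brute_force_window(t, x, width):
    """Exhaustive stablest-window search (the oracle)."""
    best = None
    for i in range(len(x) - width + 1):
        sd = np.std(x[i:i + width], ddof=1)
        if best is None or sd < best[0]:
            best = (sd, i)
    i = best[1]
    return (t[i], t[i + width - 1]), float(np.mean(x[i:i + width]))


class TestFindStablestWindow:
    @given(st.integers(0, 40))
    @settings(max_examples=25)
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(120, 600))
        t = np.arange(n, dtype=float)
        x = rng.normal(0.3, 0.05, n) + 0.1 * np.sin(t / 50)
        win, mean = tr.find_stablest_window(t, x, 120)
        owin, omean = brute_force_window(t, x, 120)
        assert win == owin
        assert mean == pytest.approx(omean, rel=1e-9)

    def test_constant_segment_breaks_ties_earliest(self):
        t = np.arange(300, dtype=float)
        win, mean = tr.find_stablest_window(t, np.full(300, 0.25), 120)
        assert win == (0.0, 119.0)
        assert mean == pytest.approx(0.25)

    def test_degenerate_segment_equal_to_width(self):
        t = np.arange(120, dtype=float) + 500
        x = np.linspace(0.2, 0.3, 120)
        win, mean = tr.find_stablest_window(t, x, 120)
        assert win == (500.0, 619.0)
        assert mean == pytest.approx(x.mean())

    def test_too_short_segment_rejected(self):
        with pytest.raises(WindowError):
            tr.find_stablest_window(np.arange(100.0), np.zeros(100), 120)

    def test_window_lands_inside_generated_plateau(self, small_experiment,
                                                   small_processed):
        exp = small_experiment
        total = 0
        overhangs = []
        for bird in exp.birds:
            wins = small_processed["windows"][bird.bird_id]
            for _, row in wins.iterrows():
                ps, pe, _ = exp.truth.plateau[(bird.bird_id, int(row["cycle"]))]
                total += 1
                overhangs.append(max(ps - row["start_s"],
                                     row["end_s"] - pe, 0.0))
        overhangs = np.asarray(overhangs)
        assert total == len(exp.birds) * exp.config.n_cycles
        # analyzer noise can beat a one-sample activity step at the plateau
        # edge, so allow a few seconds of overhang on rare windows
        assert (overhangs == 0).mean() > 0.95
        assert overhangs.max() <= 5.0


class TestExtractRmr:
    def _windows(self, means):
        return pd.DataFrame({
            "cycle": range(len(means)), "channel": "1", "setpoint": 5.0,
            "start_s": 0.0, "end_s": 119.0, "vo2": 1.0, "vco2": 0.8,
            "rq": 0.8, "watts": means})

    def test_lowest_cycle_selected(self):
        est = tr.extract_rmr("B1", 5.0, self._windows([0.30, 0.28]))
        assert est.rmr_w == pytest.approx(0.28)

    def test_single_morning_cycle_used_as_is(self):
        est = tr.extract_rmr("B1", 25.0, self._windows([0.31]))
        assert est.rmr_w == pytest.approx(0.31)

    def test_no_windows_gives_missing_estimate(self):
        assert tr.extract_rmr("B1", 5.0, self._windows([])) is None

    @given(st.integers(0, 20))
    @settings(max_examples=10)
    def test_pointwise_decrease_never_raises_rmr(self, seed):
        # RMR is a minimum of cycle-window means: lowering any single
        # contributing rate sample cannot raise it
        rng = np.random.default_rng(seed)
        means = rng.normal(0.3, 0.03, 4)
        before = tr.extract_rmr("B1", 5.0, self._windows(means)).rmr_w
        j = int(rng.integers(0, 4))
        lowered = means.copy()
        lowered[j] -= rng.uniform(0, 0.05)   # one sample lower in cycle j
        after = tr.extract_rmr("B1", 5.0, self._windows(lowered)).rmr_w
        assert after <= before + 1e-12
        assert after == pytest.approx(min(lowered), rel=1e-12)


class TestMatchTb:
    def _estimate(self, w0=1000.0, w1=1119.0):
        return tr.MetabolicEstimate("B1", 5.0, (w0, w1), 1.0, 0.8, 0.8, 0.3)

    def _series(self, t, temps):
        return TemperatureSeries("B1", "PIT", pd.DataFrame(
            {"t": np.asarray(t, dtype=float),
             "temp": np.asarray(temps, dtype=float), "flag": "ok"}))

    def test_mean_inside_window(self):
        t = np.arange(1000, 1120)
        est = tr.match_tb(self._estimate(), self._series(t, [37.9] * 120))
        assert est.tb_mean == pytest.approx(37.9)
        assert est.tb_fallback is False

    def test_boundary_readings_included(self):
        est = tr.match_tb(self._estimate(),
                          self._series([1000.0, 1119.0], [37.0, 39.0]))
        assert est.tb_mean == pytest.approx(38.0)
        assert est.tb_fallback is False

    def test_fallback_to_nearest_reading(self):
        # nearest reading 360 s before the window start (the "-6 min" case)
        est = tr.match_tb(self._estimate(),
                          self._series([640.0, 2000.0], [37.2, 38.8]))
        assert est.tb_mean == pytest.approx(37.2)
        assert est.tb_fallback is True

    def test_empty_series_leaves_tb_missing(self):
        est = tr.match_tb(self._estimate(), self._series([], []))
        assert np.isnan(est.tb_mean)

    def test_no_series_leaves_tb_missing(self):
        est = tr.match_tb(self._estimate(), None)
        assert np.isnan(est.tb_mean)


def test_extracted_rmr_recovers_generator_truth(small_experiment,
                                                small_processed):
    exp = small_experiment
    analysis = tr.window_matching.analysis_table(
        small_processed["windows"], exp.birds,
        small_processed["cleaned_temps"])
    assert len(analysis) == len(exp.birds) * 3
    for _, row in analysis.iterrows():
        true = exp.truth.rmr_w[row["bird_id"]][row["t_air"]]
        assert row["rmr_w"] == pytest.approx(true, rel=0.10)
    # extraction is a minimum over cycles, so the small bias is downward
    ratio = analysis["rmr_w"].to_numpy() / np.array(
        [exp.truth.rmr_w[b][t] for b, t in
         zip(analysis["bird_id"], analysis["t_air"])])
    assert 0.93 < ratio.mean() < 1.005
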