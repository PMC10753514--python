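import dataclasses

import pytest
from hypothesis import HealthCheck, settings

import thermoresp as tr

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """Three nights, five birds each: fast but fully structured."""
    return tr.ExperimentConfig(n_birds_per_method=3, seed=7)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return tr.generate_experiment(small_config)


@pytest.fixture(scope="session")
def small_processed(small_experiment):
    return tr.process_experiment(small_experiment)


@pytest.fixture(scope="session")
def default_run():
    """One full default-config study, analysed end to end (shared)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return tr.analyze_experiment(tr.ExperimentConfig(seed=0))


def quiet_config(**kw):
    """Config with all noise and drift silenced (exact recovery checks)."""
    base = dict(o2_noise_sd=0.0, co2_noise_sd=0.0, o2_drift_sin_amp=0.0,
                co2_drift_sin_amp=0.0, o2_drift_linear=0.0,
                co2_drift_linear=0.0, cycle_jitter_sd=0.0,
                rmr_intercept_sd=0.0, flow_sd=0.0,
                pit_noise_sd=0.0, tc_noise_sd=0.0, wander_sd=0.0,
                tb_intercept_sd=0.0, cl_jitter_sd=0.0, misread_rate=0.0,
                sensor_offset_sd=0.0, sensor_gain_sd=0.0, calib_noise_sd=0.0)
    base.update(kw)
    return tr.ExperimentConfig(**base)
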