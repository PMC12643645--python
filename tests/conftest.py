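import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20160931 % 2**31)


def simulate_strata(n_strata, size, draw_exposures, beta_true, design_fn, seed):
    """Direct stratum simulator used across tests: exposures drawn per day,
    case day sampled softmax-proportional to exp(design . beta_true)."""
    from heatpm.synthetic import sample_case_days

    rng = np.random.default_rng(seed)
    frame = draw_exposures(rng, n_strata, size)
    frame["stratum_id"] = np.repeat(np.arange(n_strata), size)
    return sample_case_days(frame, beta_true, design_fn, seed=seed + 1)


@pytest.fixture
def small_bundle():
    """One modest end-to-end pipeline run shared across pipeline tests."""
    from heatpm.pipeline import RunConfig, run
    from heatpm.synthetic import SimulationConfig

    cfg = RunConfig(
        sim=SimulationConfig(n_zips=40, n_enrollees=3000,
                             date_start="2004-01-01", date_end="2012-12-31",
                             rng_seed=7),
        mc_iterations=500)
    return cfg, run(cfg)


@pytest.fixture(scope="session")
def shared_small_bundle():
    from heatpm.pipeline import RunConfig, run
    from heatpm.synthetic import SimulationConfig

    cfg = RunConfig(
        sim=SimulationConfig(n_zips=40, n_enrollees=3000,
                             date_start="2004-01-01", date_end="2012-12-31",
                             rng_seed=7),
        mc_iterations=500)
    return cfg, run(cfg)
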