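import numpy as np
import pytest
from hypothesis import settings

import chinook_pva as cp

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def small_params():
    """Reduced-scale configuration for fast ensemble tests."""
    return cp.default_parameters().evolve(n_runs=40, horizon_years=40)


@pytest.fixture(scope="session")
def small_baseline(small_params):
    return cp.run_ensemble(small_params, cp.ScenarioSpec("baseline", 1.0), seed=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
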