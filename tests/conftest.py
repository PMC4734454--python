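import numpy as np
import pytest

from emobook import ModelParams, preset_params
from emobook.scheduler import run as run_simulation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def micro_params():
    """A very short run configuration for fast structural tests."""
    return ModelParams(record_minutes=1440.0, stab_min_minutes=120.0,
                       stab_multiplier=0.0, lhw=720.0, lps=0.5,
                       log_events=True)


@pytest.fixture(scope="session")
def micro_run():
    """One shared short logged run (1 recorded day) for audits."""
    params = ModelParams(record_minutes=1440.0, stab_min_minutes=120.0,
                         stab_multiplier=0.0, lhw=720.0, lps=0.5,
                         log_events=True)
    return run_simulation(params, 2024)
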