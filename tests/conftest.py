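import numpy as np
import pytest

from fhodquant.types import AssayCondition, SimulationParams


@pytest.fixture
def cond():
    return AssayCondition(construct_id="FHOD3L-CT", formin_conc_nm=10.0)


@pytest.fixture
def noiseless():
    return SimulationParams(seed=0, noise_sd=0.0, frame_interval_s=2.5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
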