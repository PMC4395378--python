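import numpy as np
import pytest
from hypothesis import settings

from chanevo.cable import CableParams, Conductances

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_params() -> CableParams:
    return CableParams()


@pytest.fixture(scope="session")
def default_conductances(default_params) -> Conductances:
    return Conductances.fitted(120.0, 36.0, default_params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
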