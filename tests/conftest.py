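import numpy as np
import pytest
from hypothesis import settings

from mtcrosstalk import Params

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def params():
    """Default parameter set."""
    return Params()


@pytest.fixture
def small_params():
    """Small, fast cell for engine-level tests."""
    return Params(n_mem_beads=40, n_nuc_beads=20, Nmt=10, t_total=20.0,
                  record_every=0.5)


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(1234))
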