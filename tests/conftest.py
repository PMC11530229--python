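import numpy as np
import pytest
from hypothesis import settings

from msicoreg import PhantomSpec, make_phantom

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_phantom():
    """The standard 3-segment contiguous phantom (no warp)."""
    return make_phantom(PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def translated_phantom():
    return make_phantom(PhantomSpec(warp=("translation", 5, 3), seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
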