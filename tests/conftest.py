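import numpy as np
import pytest

from presans.pre import PREPhysics, K_SOLOMON_BLOEMBERGEN
from presans.synthetic import default_physics, default_tag_site, make_toy_complex


@pytest.fixture(scope="session")
def physics() -> PREPhysics:
    """Standard nitroxide physics: tau_c = 81 ns, 850 MHz, SB constant."""
    return default_physics()


@pytest.fixture(scope="session")
def toy_complex():
    return make_toy_complex(3, 30, seed=1)


@pytest.fixture(scope="session")
def tag_site(toy_complex):
    return default_tag_site(toy_complex, "A", 15)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
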