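import numpy as np
import pytest

from latticepick.core import ParticleSet
from latticepick.synthetic import make_fig3_fixture


@pytest.fixture(scope="session")
def fig3():
    """The two-patch hexagonal fixture (noise-free, spacing 8)."""
    return make_fig3_fixture()


@pytest.fixture(scope="session")
def fig3_seeds(fig3):
    return ParticleSet([s.copy() for s in fig3.seeds], "fig3")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
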