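import numpy as np
import pytest

from bubblephantom import GridSpec, MaterialParams, air_mixture, make_linear_decompression


@pytest.fixture
def air():
    """Sensitivity-baseline air mixture (modal solubilities, D = 1.4e-9)."""
    return air_mixture()


@pytest.fixture
def gel_mixture():
    """Collagen-gel air mixture (fitted transport values)."""
    return air_mixture(L_N2=0.0145, L_O2=0.027, D=2.5e-9)


@pytest.fixture
def gel_material():
    return MaterialParams(gamma=0.07, mu=40.0)


@pytest.fixture
def stiff_material():
    return MaterialParams(gamma=0.056, mu=2.0e6)


@pytest.fixture
def small_grid():
    return GridSpec(h=8e-5, shape=(8, 8, 8))


@pytest.fixture
def ascent_profile():
    """30 m of seawater to the surface in 3.75 min."""
    return make_linear_decompression(30.0, 225.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
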