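import numpy as np
import pytest

from caneseg import generate_scene
from caneseg.synthdata import default_density_model


@pytest.fixture(scope="session")
def small_scenes():
    """Four deterministic 128x128 scenes with non-zero density spread."""
    return [generate_scene(size=128, density=default_density_model(), seed=10 + i)
            for i in range(4)]


@pytest.fixture(scope="session")
def exact_scenes():
    """Scenes generated with sigma = 0 densities: masses are exactly mu * pixels."""
    return [generate_scene(size=128, seed=40 + i) for i in range(3)]


@pytest.fixture(scope="session")
def tiny_model():
    """A small seeded MDSC model reused by inference-only tests."""
    from caneseg import build_model

    return build_model("MDSC", input_size=256, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
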