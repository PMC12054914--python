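import numpy as np
import pytest

from sandfix import build_factor_stack, erosion_fields, generate_scene


@pytest.fixture(scope="session")
def scene():
    """One moderately sized synthetic scene shared by read-only tests."""
    return generate_scene(nrows=40, ncols=40, cellsize_m=1000.0, n_stations=4, years=1, seed=1)


@pytest.fixture(scope="session")
def stack(scene):
    return build_factor_stack(scene)


@pytest.fixture(scope="session")
def fields(stack):
    return erosion_fields(stack)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
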