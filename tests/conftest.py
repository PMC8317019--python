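import numpy as np
import pytest

from eqrecon import (
    CyclicGroup,
    regular_representation,
    trivial_representation,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(params=[1, 2, 4], ids=lambda m: f"Z{m}")
def on_grid_group(request):
    return CyclicGroup(request.param)


@pytest.fixture
def z4():
    return CyclicGroup(4)


@pytest.fixture
def z4_trivial(z4):
    return trivial_representation(z4)


@pytest.fixture
def z4_regular(z4):
    return regular_representation(z4)
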