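import numpy as np
import pytest

import callusim as cs
from callusim.scenarios import toy_fixture


@pytest.fixture
def desk_params():
    return cs.desk_profile()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def domain_5mm():
    return cs.build_domain(5.0, 0.25)


@pytest.fixture
def conservation_box():
    return toy_fixture("conservation_box")


@pytest.fixture
def gradient_corridor():
    return toy_fixture("gradient_corridor")
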