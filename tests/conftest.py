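import numpy as np
import pytest

from boldopt.grid import build_ground_truth, build_space


@pytest.fixture(scope="session")
def study1():
    return build_space(1)


@pytest.fixture(scope="session")
def study2():
    return build_space(2)


@pytest.fixture(scope="session")
def truth_surface(study2):
    return build_ground_truth(study2)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
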