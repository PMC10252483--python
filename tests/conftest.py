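import numpy as np
import pytest

from tumorherd.phantom import PhantomParams, generate_slice


@pytest.fixture(scope="session")
def class1_slice():
    return generate_slice(PhantomParams(class_id=1, seed=11))


@pytest.fixture(scope="session")
def class2_slice():
    return generate_slice(PhantomParams(class_id=2, seed=11))


@pytest.fixture(scope="session")
def skull_slice():
    return generate_slice(PhantomParams(class_id=2, seed=11, skull=True))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
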