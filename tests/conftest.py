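import numpy as np
import pytest

import lpsmri as lp


@pytest.fixture(scope="session")
def shearlet64():
    return lp.build_shearlet_system(64, 64, 3)


@pytest.fixture(scope="session")
def dce_phantom():
    return lp.generate_dce_phantom(seed=7)


@pytest.fixture(scope="session")
def bowel_phantom():
    return lp.generate_bowel_phantom(lp.BowelPhantomConfig(), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_complex(rng, shape):
    return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
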