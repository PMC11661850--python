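import numpy as np
import pytest

from hvae.so3 import cg_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def table4():
    return cg_table(4)


@pytest.fixture(scope="session")
def table8():
    return cg_table(8)


def random_unit_vector(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def angles_of(v):
    v = np.asarray(v, dtype=float)
    v = v / np.linalg.norm(v)
    theta = np.arccos(np.clip(v[2], -1.0, 1.0))
    phi = np.arctan2(v[1], v[0]) % (2 * np.pi)
    return theta, phi
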