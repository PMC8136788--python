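import numpy as np
import pytest

from dnastack import (
    build_pair,
    build_stack,
    build_tetrad,
    build_triad,
    load_fixture,
    load_template,
)


@pytest.fixture(scope="session")
def fixture_table():
    return load_fixture()


@pytest.fixture(scope="session")
def gc_pair():
    return build_pair(load_template("G"), load_template("C"))


@pytest.fixture(scope="session")
def at_pair():
    return build_pair(load_template("A"), load_template("T"))


@pytest.fixture(scope="session")
def na_tetrad():
    return build_tetrad("Na+")


@pytest.fixture()
def gc_stack():
    layers = [build_pair(load_template("G"), load_template("C")) for _ in range(2)]
    return build_stack(layers, rise=3.4, twist=36.0)


@pytest.fixture(scope="session")
def cgc_triad():
    pair = build_pair(load_template("G"), load_template("C"))
    return build_triad(pair, load_template("C", protonated=True))


def random_rotation(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
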