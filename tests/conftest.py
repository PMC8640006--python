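import numpy as np
import pytest

from deltapot.aev import AEVParams
from deltapot.chem import Molecule
from deltapot.synthetic import PlantedCorrection, ToyBaseline, load_templates

ELEMENTS = ("H", "C", "N", "O")


@pytest.fixture(scope="session")
def templates():
    return load_templates()


@pytest.fixture(scope="session")
def baseline():
    return ToyBaseline()


@pytest.fixture(scope="session")
def correction():
    return PlantedCorrection()


@pytest.fixture(scope="session")
def small_aev():
    """Reduced descriptor used throughout the tests for speed."""
    return AEVParams(n_radial_shells=8, n_angular_shells=4, n_theta=4)


def random_cluster(rng, n_atoms=None, scale=1.5, min_dist=0.7):
    """Random H/C/N/O cluster with no clashing pairs."""
    if n_atoms is None:
        n_atoms = int(rng.integers(2, 9))
    while True:
        coords = rng.normal(scale=scale, size=(n_atoms, 3))
        if n_atoms == 1:
            break
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        if np.min(d[~np.eye(n_atoms, dtype=bool)]) > min_dist:
            break
    elements = tuple(rng.choice(ELEMENTS, size=n_atoms))
    return Molecule(elements, coords)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
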