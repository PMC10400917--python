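import numpy as np
import pytest

from efsam import synth
from efsam.ensembles import Atom, Ensemble


@pytest.fixture(scope="session")
def toy_reference():
    """The pinned folded toy reference structure."""
    return synth.build_toy_protein()


@pytest.fixture(scope="session")
def gfg():
    """Fully extended Gly-Phe-Gly tripeptide."""
    return synth.make_gfg_tripeptide()


@pytest.fixture(scope="session")
def helix15():
    return synth.make_helix(15)


def make_point_ensemble(coords, names=None, elements=None, resnums=None):
    """Small ad-hoc ensemble from raw coordinates (one atom per residue by
    default), for straight-from-formula oracle tests."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n = coords.shape[1]
    names = names or ["CA"] * n
    elements = elements or ["C"] * n
    resnums = resnums if resnums is not None else list(range(1, n + 1))
    atoms = [
        Atom(names[i], elements[i], "ALA", int(resnums[i])) for i in range(n)
    ]
    return Ensemble(atoms, coords)


@pytest.fixture
def point_ensemble_factory():
    return make_point_ensemble


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


@pytest.fixture
def rotation_factory():
    return random_rotation
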