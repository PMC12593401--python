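import numpy as np
import pytest

from cspkit import (
    CrystalStructure,
    Lattice,
    LennardJonesCalculator,
    RelaxSettings,
    relax,
)
from cspkit.fixtures import FixtureSpec, make_fixture


@pytest.fixture(scope="session")
def lj_fcc():
    """LJ fcc toy: (fixture, relaxed structure, relaxed energy)."""
    fx = make_fixture(FixtureSpec("lj_fcc"))
    res = relax(fx.structure, fx.calculator, RelaxSettings(mode="variable_cell"))
    assert res.converged
    return fx, res.structure, res.energy


@pytest.fixture(scope="session")
def diatomic():
    """Rigid-diatomic molecular crystal with its bonded-LJ teacher."""
    return make_fixture(FixtureSpec("rigid_diatomic_crystal"))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_skewed_lattice(rng, lo=4.0, hi=9.0, max_shear=0.5):
    """Moderately skewed random right-handed cell."""
    cell = np.diag(rng.uniform(lo, hi, 3))
    shear = rng.uniform(-max_shear, max_shear, (3, 3))
    shear[np.triu_indices(3)] = 0.0
    cell = cell + shear * cell.diagonal()[:, None] * 0.3
    if np.linalg.det(cell) < 0:
        cell[2] *= -1
    return Lattice(cell)
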