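import numpy as np
import pytest

from rgetaway import Molecule, make_chain_molecule, make_random_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20261002)


@pytest.fixture
def chain4():
    """Collinear all-carbon 4-chain, unit spacing; analytic R3m = 0.15."""
    return make_chain_molecule(4)


@pytest.fixture
def chain5():
    """Collinear all-carbon 5-chain, unit spacing; analytic R3m = 2/15."""
    return make_chain_molecule(5)


@pytest.fixture
def methane():
    """Tetrahedral CH4: max topological distance 2, so R3 vanishes."""
    d = 1.09 / np.sqrt(3)
    coords = np.array(
        [[0, 0, 0], [d, d, d], [d, -d, -d], [-d, d, -d], [-d, -d, d]]
    )
    bonds = frozenset({(0, 1), (0, 2), (0, 3), (0, 4)})
    return Molecule(["C", "H", "H", "H", "H"], coords, bonds, "methane")


@pytest.fixture
def random_trees():
    """A batch of random tree-bonded molecules with generic geometry."""
    return [make_random_tree(n_atoms=4 + (s % 12), seed=s) for s in range(50)]


def random_rotation(rng):
    """Haar-ish random proper rotation via QR."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
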