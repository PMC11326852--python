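import numpy as np
import pytest

from phaseformer.presets import toy_dipeptide_dataset
from phaseformer.xtal import Atom, FragmentStructure, UnitCell


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240814)


def random_point_structure(rng, n_atoms=5, cell=(9.3, 8.1, 7.6)):
    """Random all-carbon point-atom structure inside a cell."""
    cell = UnitCell(*cell)
    pos = rng.uniform(0, 1, size=(n_atoms, 3)) * cell.edges
    atoms = [Atom("C", p) for p in pos]
    return FragmentStructure(atoms, [("GLY", (0, n_atoms))], cell)


@pytest.fixture(scope="session")
def toy_dataset():
    """The canonical 8-example toy dipeptide set (16^3 grids, J=2)."""
    return toy_dipeptide_dataset(n=8, seed=11)


@pytest.fixture(scope="session")
def toy_examples(toy_dataset):
    return toy_dataset.examples
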