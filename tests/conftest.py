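import numpy as np
import pytest

import qubodock as qd

# the co-crystallized aldose-reductase inhibitor used in the redocking study
ZOPOLRESTAT_SMILES = (
    "C1=CC=C2C(=C1)C(=NN(C2=O)CC3=NC4=CC(=CC=C4S3)C(F)(F)F)CC(=O)O"
)


@pytest.fixture(scope="session")
def zopolrestat():
    return qd.load_compound(ZOPOLRESTAT_SMILES, name="zopolrestat")


@pytest.fixture(scope="session")
def zopolrestat_frag(zopolrestat):
    return qd.decompose(zopolrestat)


@pytest.fixture(scope="session")
def chain_instance():
    """Planted 4-fragment geometric-mode instance, 20 variables."""
    return qd.generate_instance(qd.GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def energy_instance():
    """Small energy-mode instance exercising the UFF pair path."""
    return qd.generate_instance(
        qd.GeneratorConfig(seed=5, mode="energy", n_fragments=3, placements_per_fragment=3)
    )


@pytest.fixture
def two_var_qubo():
    """The hand-expanded 2-fragment, 1-placement-each instance:
    dG = (-1, -2), conn(0, 1) = -1, weights (1, 5, 5, 25)."""
    comp = qd.load_compound("CCCC", name="butane")
    frag = qd.decompose(comp)
    placements = [
        qd.Placement(0, 0, np.zeros((frag.fragments[0].num_atoms, 3)), -1.0),
        qd.Placement(1, 1, np.zeros((frag.fragments[1].num_atoms, 3)), -2.0),
    ]
    pset = qd.PlacementSet(placements, frag)
    terms = [qd.PairTerm(0, 1, 0, -1)]
    return qd.build_qubo(pset, terms, qd.Weights(1, 5, 5, 25))
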