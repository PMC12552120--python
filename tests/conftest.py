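import numpy as np
import pytest

from gems.fixtures import ScenarioSpec, make_scenario, make_toy_ligand, make_toy_protein
from gems.similarity import KabschAligner


@pytest.fixture(scope="session")
def scenario():
    """One planted-similarity scenario shared by the filtering/baseline tests."""
    return make_scenario(ScenarioSpec(seed=1))


@pytest.fixture(scope="session")
def aligner():
    return KabschAligner()


@pytest.fixture(scope="session")
def toy_protein():
    return make_toy_protein(30, seed=7)


@pytest.fixture(scope="session")
def toy_ligands():
    names = ["phenol", "picoline", "naphthalene", "ibuprofen", "ribose"]
    return [make_toy_ligand(n, decoration_count=i % 3, seed=11 + i)
            for i, n in enumerate(names)]


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
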