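import numpy as np
import pytest

import dp5


@pytest.fixture(scope="session")
def small_spec():
    return dp5.SyntheticSpec(n_molecules=30, seed=101)


@pytest.fixture(scope="session")
def small_corpus(small_spec):
    corpus, truth = dp5.generate_corpus(small_spec)
    return corpus, truth


@pytest.fixture(scope="session")
def small_db(small_corpus):
    corpus, _ = small_corpus
    return dp5.build_error_database(corpus, dp5.DescriptorParams(), seed=101)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_molecule(elements, bonds, coords, molecule_id="m", shifts=None,
                  energy=0.0):
    """Hand-built molecule helper for geometry-level tests."""
    conf = dp5.Conformer(coordinates=np.asarray(coords, dtype=float),
                         relative_energy=energy, calculated_shifts=shifts)
    return dp5.Molecule(molecule_id=molecule_id, elements=list(elements),
                        bonds=list(bonds), conformers=[conf])
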