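import numpy as np
import pytest

from mcfold import SolventModelParams, generate_fixture_peptide, make_single_dihedral_system


@pytest.fixture(scope="session")
def peptide6():
    """Six-residue synthetic peptide with its rotatable-dihedral tree."""
    return generate_fixture_peptide(6, seed=1)


@pytest.fixture(scope="session")
def toy_dihedral():
    """Four-atom chain with a single torsion term V = 1 + cos(φ)."""
    return make_single_dihedral_system(k=1.0, n=1.0, phase=0.0)


@pytest.fixture()
def params():
    return SolventModelParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
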