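import numpy as np
import pytest

from enscontact.structio import ContactMap, ProteinStructure, ResidueRecord
from enscontact.synthetic import SyntheticProteinSpec, make_corpus, make_native


def make_chain(coords_by_residue, sequence=None, chain_id="A"):
    """Assemble a ProteinStructure from {atom: xyz} dicts per residue."""
    sequence = sequence or "A" * len(coords_by_residue)
    residues = [
        ResidueRecord(chain_id, k + 1, sequence[k],
                      {n: np.asarray(x, dtype=float) for n, x in atoms.items()})
        for k, atoms in enumerate(coords_by_residue)
    ]
    return ProteinStructure("fixture", residues)


@pytest.fixture
def twelve_residue_cm():
    """The worked 12-residue contact map used by the graph examples."""
    return ContactMap(12, {(3, 10), (2, 10), (4, 9), (1, 11), (5, 8)})


@pytest.fixture(scope="session")
def helix_native():
    """Ideal all-helix chain of 30 residues."""
    spec = SyntheticProteinSpec(L=30, seed=1)
    native, cm, seq = make_native(spec, recipe=[("H", 30)])
    return native, cm, seq


@pytest.fixture(scope="session")
def strand_native():
    spec = SyntheticProteinSpec(L=12, seed=1)
    native, cm, seq = make_native(spec, recipe=[("E", 12)])
    return native, cm, seq


@pytest.fixture(scope="session")
def mixed_native():
    """A compact mixed-topology native with medium and long contacts."""
    spec = SyntheticProteinSpec(L=60, seed=3)
    return make_native(spec)


@pytest.fixture(scope="session")
def mini_corpus():
    """Small corpus for pipeline integration tests (fast conditions)."""
    template = SyntheticProteinSpec(L=40, n_decoys=40, msa_depth=60)
    return make_corpus(8, template, seed=11, test_fraction=0.25)
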