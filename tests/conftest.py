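import numpy as np
import pytest

from qnasom import MoleculeGraph, SimConfig, generate_dataset, generate_molecules


def make_ring(n: int, element: str = "C") -> MoleculeGraph:
    bonds = frozenset(
        (i, (i + 1) % n) if i < (i + 1) % n else ((i + 1) % n, i) for i in range(n)
    )
    return MoleculeGraph(
        mol_id=f"ring{n}",
        elements=(element,) * n,
        som_flags=(False,) * n,
        bonds=bonds,
    )


@pytest.fixture(scope="session")
def benzene() -> MoleculeGraph:
    return make_ring(6)


@pytest.fixture(scope="session")
def ethane() -> MoleculeGraph:
    return MoleculeGraph("ethane", ("C", "C"), (False, False), frozenset({(0, 1)}))


@pytest.fixture(scope="session")
def toluene() -> MoleculeGraph:
    ring = make_ring(6)
    return MoleculeGraph(
        "toluene",
        ring.elements + ("C",),
        (False,) * 7,
        ring.bonds | {(0, 6)},
    )


# Hand-written two-record SDF: ethanol with explicit hydrogens and a SOM on
# the SDF atom 2 (the second carbon), plus a methane record without a SOM
# field.  Hydrogen suppression must remap SOM index 2 -> internal index 1.
ETHANOL_SDF = """\
ethanol
     test          2D

  9  8  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.0000    0.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    1.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000   -1.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.0000    0.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.0000    1.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.0000   -1.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.0000    1.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  1  4  1  0
  1  5  1  0
  1  6  1  0
  2  7  1  0
  2  8  1  0
  3  9  1  0
M  END
> <SOM>
2

> <ISOFORM>
CYP3A4

> <REACTION>
C-oxidation

$$$$
methane
     test          2D

  1  0  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
M  END
$$$$
"""


@pytest.fixture()
def ethanol_sdf(tmp_path):
    path = tmp_path / "ethanol.sdf"
    path.write_text(ETHANOL_SDF)
    return path


@pytest.fixture(scope="session")
def sim_molecules():
    """50 annotated synthetic molecules, fixed seed."""
    return generate_molecules(SimConfig(n_molecules=50, rng_seed=12345))


@pytest.fixture(scope="session")
def sim_dataset():
    """Per-atom dataset of 200 synthetic molecules at imbalance 0.05."""
    return generate_dataset(SimConfig(n_molecules=200, rng_seed=20240501))


def permuted(mol: MoleculeGraph, perm: np.ndarray) -> MoleculeGraph:
    """Relabel atoms of a molecule: new index perm[i] holds old atom i."""
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    elements = tuple(mol.elements[inv[j]] for j in range(mol.n_atoms))
    flags = tuple(mol.som_flags[inv[j]] for j in range(mol.n_atoms))
    bonds = frozenset(tuple(sorted((int(perm[i]), int(perm[j])))) for i, j in mol.bonds)
    return MoleculeGraph(mol.mol_id, elements, flags, bonds, mol.isoform, mol.reaction)
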