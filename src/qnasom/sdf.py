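"""Reading and writing SOM-annotated SDF files.

Molecules are exposed as hydrogen-suppressed graphs: only heavy atoms are
kept, and sites of metabolism (SOMs) are per-atom boolean flags.  The
annotation convention is an SDF data field ``> <SOM>`` holding the 1-based
indices of the SOM atoms in the original atom block (i.e. before hydrogen
suppression); optional ``> <ISOFORM>`` and ``> <REACTION>`` fields carry the
metabolizing cytochrome P450 isoform and the reaction category.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

__all__ = [
    "MoleculeGraph",
    "SdfRecordError",
    "SomAnnotationError",
    "read_sdf",
    "write_sdf",
    "connectivity_matrix",
]

RDLogger.DisableLog("rdApp.*")


class SdfRecordError(ValueError):
    """A record in an SDF file could not be parsed as a molecule."""


class SomAnnotationError(ValueError):
    """A SOM annotation refers to an invalid atom (out of range, hydrogen,
    duplicated, or part of a discarded fragment)."""


@dataclass(frozen=True)
class MoleculeGraph:
    """Hydrogen-suppressed molecular graph with per-atom SOM flags.

    Atom indices are 0-based over heavy atoms; bonds are unordered pairs
    ``(i, j)`` stored with ``i < j``.  Bond order is deliberately discarded:
    the downstream descriptors use the topological 0/1 connectivity matrix
    only.
    """

    mol_id: str
    elements: tuple[str, ...]
    som_flags: tuple[bool, ...]
    bonds: frozenset[tuple[int, int]]
    isoform: str | None = None
    reaction: str | None = None

    def __post_init__(self) -> None:
        n = len(self.elements)
        if n < 1:
            raise ValueError(f"{self.mol_id}: molecule must have at least one atom")
        if len(self.som_flags) != n:
            raise ValueError(f"{self.mol_id}: som_flags length != atom count")
        if any(el == "H" for el in self.elements):
            raise ValueError(f"{self.mol_id}: hydrogens are not allowed in a heavy-atom graph")
        for i, j in self.bonds:
            if not (0 <= i < j < n):
                raise ValueError(f"{self.mol_id}: invalid bond ({i}, {j}) for {n} atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def som_indices(self) -> tuple[int, ...]:
        """0-based internal indices of SOM atoms."""
        return tuple(i for i, f in enumerate(self.som_flags) if f)

    def degree(self, i: int) -> int:
        return sum(1 for b in self.bonds if i in b)


def connectivity_matrix(molecule: MoleculeGraph) -> np.ndarray:
    """Topological 0/1 adjacency matrix of the heavy-atom graph.

    Symmetric, zero diagonal; entry (i, k) is 1 iff a bond joins atoms i
    and k, regardless of bond order.
    """
    n = molecule.n_atoms
    C = np.zeros((n, n), dtype=float)
    for i, j in molecule.bonds:
        C[i, j] = C[j, i] = 1.0
    return C


_SOM_SPLIT = re.compile(r"[\s,;]+")


def _parse_som_field(raw: str, mol_id: str) -> list[int]:
    tokens = [t for t in _SOM_SPLIT.split(raw.strip()) if t]
    indices: list[int] = []
    for tok in tokens:
        try:
            indices.append(int(tok))
        except ValueError:
            raise SomAnnotationError(f"{mol_id}: SOM field token {tok!r} is not an integer") from None
    if len(set(indices)) != len(indices):
        raise SomAnnotationError(f"{mol_id}: duplicate SOM indices in {indices}")
    return indices


def _largest_component(n: int, bonds: set[tuple[int, int]]) -> list[int]:
    """Vertices of the largest connected component (ties: smallest index)."""
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    seen = [False] * n
    best: list[int] = []
    for start in range(n):
        if seen[start]:
            continue
        comp, stack = [], [start]
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for w in adj[v]:
                if not seen[w]:
                    seen[w] = True
                    stack.append(w)
        if len(comp) > len(best):
            best = sorted(comp)
    return best


def _graph_from_rdkit(mol: Chem.Mol, mol_id: str) -> MoleculeGraph:
    """Build a hydrogen-suppressed MoleculeGraph from an RDKit mol.

    SOM indices in the ``SOM`` property are 1-based over the full SDF atom
    block (hydrogens included) and are remapped to heavy-atom numbering.
    """
    n_total = mol.GetNumAtoms()
    heavy_sdf_indices = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() != 1]
    if not heavy_sdf_indices:
        raise SdfRecordError(f"{mol_id}: no heavy atoms")
    heavy_rank = {sdf_i: k for k, sdf_i in enumerate(heavy_sdf_indices)}

    if mol.HasProp("SOM"):
        som_1based = _parse_som_field(mol.GetProp("SOM"), mol_id)
    else:
        som_1based = []
        warnings.warn(f"{mol_id}: no SOM field; all atoms labeled non-SOM", stacklevel=3)

    som_heavy: set[int] = set()
    for idx in som_1based:
        if not (1 <= idx <= n_total):
            raise SomAnnotationError(
                f"{mol_id}: SOM index {idx} outside atom block (1..{n_total})"
            )
        atom = mol.GetAtomWithIdx(idx - 1)
        if atom.GetAtomicNum() == 1:
            raise SomAnnotationError(f"{mol_id}: SOM index {idx} points at a hydrogen")
        som_heavy.add(heavy_rank[idx - 1])

    bonds: set[tuple[int, int]] = set()
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in heavy_rank and j in heavy_rank:
            a, c = sorted((heavy_rank[i], heavy_rank[j]))
            bonds.add((a, c))

    keep = _largest_component(len(heavy_sdf_indices), bonds)
    if len(keep) < len(heavy_sdf_indices):
        warnings.warn(
            f"{mol_id}: multiple fragments; keeping largest component "
            f"({len(keep)}/{len(heavy_sdf_indices)} heavy atoms)",
            stacklevel=3,
        )
        dropped_soms = som_heavy - set(keep)
        if dropped_soms:
            raise SomAnnotationError(
                f"{mol_id}: SOM atom(s) in a discarded fragment"
            )
    remap = {old: new for new, old in enumerate(keep)}
    elements = tuple(
        mol.GetAtomWithIdx(heavy_sdf_indices[old]).GetSymbol() for old in keep
    )
    som_flags = tuple(old in som_heavy for old in keep)
    kept_bonds = frozenset(
        (remap[i], remap[j]) for i, j in bonds if i in remap and j in remap
    )

    isoform = mol.GetProp("ISOFORM").strip() if mol.HasProp("ISOFORM") else None
    reaction = mol.GetProp("REACTION").strip() if mol.HasProp("REACTION") else None
    return MoleculeGraph(
        mol_id=mol_id,
        elements=elements,
        som_flags=som_flags,
        bonds=kept_bonds,
        isoform=isoform or None,
        reaction=reaction or None,
    )


def read_sdf(path: str | Path) -> list[MoleculeGraph]:
    """Read a multi-record MDL V2000 SDF with SOM annotations.

    Hydrogens are suppressed and SOM indices remapped from SDF atom-block
    numbering to heavy-atom internal numbering.  Records without a ``SOM``
    field yield all-negative labels with a warning.  A malformed record
    raises :class:`SdfRecordError` naming the record ordinal.
    """
    path = Path(path)
    if not path.read_text().strip():  # empty SDF: zero records
        return []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    molecules: list[MoleculeGraph] = []
    for ordinal, mol in enumerate(supplier, start=1):
        if mol is None:
            raise SdfRecordError(f"{path.name}: record {ordinal} is not a valid molfile")
        name = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        mol_id = name or f"record{ordinal}"
        molecules.append(_graph_from_rdkit(mol, mol_id))
    return molecules


def _to_rdkit(molecule: MoleculeGraph) -> Chem.Mol:
    rw = Chem.RWMol()
    for el in molecule.elements:
        atom = Chem.Atom(el)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    for i, j in sorted(molecule.bonds):
        rw.AddBond(i, j, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    mol.SetProp("_Name", molecule.mol_id)
    if molecule.som_indices:
        mol.SetProp("SOM", " ".join(str(i + 1) for i in molecule.som_indices))
    else:
        mol.SetProp("SOM", "")
    if molecule.isoform:
        mol.SetProp("ISOFORM", molecule.isoform)
    if molecule.reaction:
        mol.SetProp("REACTION", molecule.reaction)
    return mol


def write_sdf(molecules: list[MoleculeGraph], path: str | Path) -> None:
    """Write graphs as a V2000 SDF with SOM/ISOFORM/REACTION data fields.

    All bonds are written as single bonds (bond order is not modeled) and
    atom order is the internal heavy-atom order, so read→write→read is a
    fixed point.
    """
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for molecule in molecules:
            writer.write(_to_rdkit(molecule))
    finally:
        writer.close()
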