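"""Per-atom classification datasets for SOM prediction.

Each heavy atom of each annotated molecule becomes one machine-learning
instance with features (P, Q) and a binary label (1 = site of metabolism).
Datasets keep molecule identity for every instance so that train/test
splitting can be done at the molecule level, never splitting a molecule's
atoms across partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .descriptors import QnaResult
from .sdf import MoleculeGraph

__all__ = [
    "REACTION_TYPES",
    "ISOFORMS",
    "AtomInstance",
    "SomDataset",
    "build_dataset",
    "filter_by_group",
    "imbalance_ratio",
]

#: The seven metabolizing-reaction categories used for subset compilation.
REACTION_TYPES: tuple[str, ...] = (
    "aliphatic hydroxylation",
    "aromatic hydroxylation",
    "C-oxidation",
    "N-dealkylation",
    "N-oxidation",
    "O-dealkylation",
    "S-oxidation",
)

#: The five major drug-metabolizing cytochrome P450 isoforms.
ISOFORMS: tuple[str, ...] = ("CYP1A2", "CYP2C9", "CYP2C19", "CYP2D6", "CYP3A4")

_COLUMNS = ["mol_id", "atom_index", "P", "Q", "label", "synthetic"]


@dataclass(frozen=True)
class AtomInstance:
    """One classification row: an atom with its descriptors and SOM label."""

    mol_id: str
    atom_index: int
    P: float
    Q: float
    label: int
    synthetic: bool = False


class SomDataset:
    """Ordered collection of atom instances with molecule-level grouping.

    Backed by a DataFrame with columns mol_id, atom_index, P, Q, label,
    synthetic.  ``group_key`` records the (reaction_type, isoform) filter
    that produced the dataset, if any.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        group_key: tuple[str | None, str | None] = (None, None),
    ) -> None:
        missing = [c for c in _COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"dataset frame missing columns {missing}")
        self._frame = frame.reset_index(drop=True)
        self.group_key = group_key
        labels = self._frame["label"]
        if not labels.isin([0, 1]).all():
            raise ValueError("labels must be 0 or 1")

    # -- basic accessors -------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def __len__(self) -> int:
        return len(self._frame)

    @property
    def features(self) -> np.ndarray:
        """(n, 2) array of the P and Q columns."""
        return self._frame[["P", "Q"]].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self._frame["label"].to_numpy(dtype=int)

    @property
    def mol_ids(self) -> np.ndarray:
        return self._frame["mol_id"].to_numpy(dtype=object)

    @property
    def molecules(self) -> list[str]:
        """Unique mol_ids in first-appearance order."""
        return list(dict.fromkeys(self._frame["mol_id"]))

    @property
    def n_positive(self) -> int:
        return int((self._frame["label"] == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self._frame["label"] == 0).sum())

    def instances(self) -> list[AtomInstance]:
        return [
            AtomInstance(
                mol_id=r.mol_id,
                atom_index=int(r.atom_index),
                P=float(r.P),
                Q=float(r.Q),
                label=int(r.label),
                synthetic=bool(r.synthetic),
            )
            for r in self._frame.itertuples(index=False)
        ]

    def subset_by_molecules(self, mol_ids: Iterable[str]) -> "SomDataset":
        wanted = set(mol_ids)
        mask = self._frame["mol_id"].isin(wanted)
        return SomDataset(self._frame[mask].copy(), self.group_key)

    def with_features(self, X: np.ndarray) -> "SomDataset":
        """Copy of the dataset with the (P, Q) columns replaced (e.g. after
        normalization)."""
        if X.shape != (len(self), 2):
            raise ValueError(f"feature array shape {X.shape} != ({len(self)}, 2)")
        frame = self._frame.copy()
        frame[["P", "Q"]] = X
        return SomDataset(frame, self.group_key)

    # -- i/o ---------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self._frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SomDataset":
        frame = pd.read_csv(path, sep="\t")
        if "synthetic" not in frame.columns:
            frame["synthetic"] = False
        return cls(frame)


def build_dataset(
    molecules: Sequence[MoleculeGraph],
    descriptors: Mapping[str, QnaResult] | Sequence[QnaResult],
    group_key: tuple[str | None, str | None] = (None, None),
) -> SomDataset:
    """One instance per heavy atom, ordered by molecule then atom index.

    ``descriptors`` may be a mapping mol_id -> QnaResult or a sequence
    parallel to ``molecules``.
    """
    if isinstance(descriptors, Mapping):
        lookup = dict(descriptors)
    else:
        lookup = {d.mol_id: d for d in descriptors}
    rows = []
    for mol in molecules:
        try:
            qna = lookup[mol.mol_id]
        except KeyError:
            raise KeyError(f"no descriptors for molecule {mol.mol_id!r}") from None
        if qna.n_atoms != mol.n_atoms:
            raise ValueError(
                f"{mol.mol_id}: descriptor length {qna.n_atoms} != atom count {mol.n_atoms}"
            )
        for i in range(mol.n_atoms):
            rows.append(
                (mol.mol_id, i, qna.P[i], qna.Q[i], int(mol.som_flags[i]), False)
            )
    frame = pd.DataFrame(rows, columns=_COLUMNS)
    return SomDataset(frame, group_key)


def filter_by_group(
    molecules: Sequence[MoleculeGraph],
    descriptors: Mapping[str, QnaResult] | Sequence[QnaResult],
    reaction_type: str | None = None,
    isoform: str | None = None,
) -> SomDataset:
    """Dataset restricted to molecules matching the reaction/isoform labels.

    Both criteria empty is the identity.  Unknown category names raise with
    the list of valid names.
    """
    if reaction_type is not None and reaction_type not in REACTION_TYPES:
        raise ValueError(
            f"unknown reaction type {reaction_type!r}; valid: {list(REACTION_TYPES)}"
        )
    if isoform is not None and isoform not in ISOFORMS:
        raise ValueError(f"unknown isoform {isoform!r}; valid: {list(ISOFORMS)}")
    selected = [
        m
        for m in molecules
        if (reaction_type is None or m.reaction == reaction_type)
        and (isoform is None or m.isoform == isoform)
    ]
    return build_dataset(selected, descriptors, group_key=(reaction_type, isoform))


def imbalance_ratio(dataset: SomDataset) -> float:
    """#SOM / #non-SOM instances; the study sets have ratio <= 0.05."""
    n0 = dataset.n_negative
    if n0 == 0:
        raise ValueError("imbalance ratio undefined: no negative instances")
    return dataset.n_positive / n0
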