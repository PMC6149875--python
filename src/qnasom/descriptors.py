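"""Per-atom QNA (Quantitative Neighborhoods of Atoms) descriptors.

Every heavy atom *i* of a molecule gets a pair of values (P_i, Q_i) built
from the topological connectivity matrix C and two tabulated electronic
constants of its element, the ionization potential IP and the electron
affinity EA (both in eV):

    A_i = (IP_i + EA_i) / 2          (Mulliken-type electronegativity)
    B_i = (IP_i - EA_i)^(-1/2)       (inverse-sqrt chemical hardness)
    E   = exp(-C / 2)                (matrix exponential of -C/2)

    P_i = B_i * sum_k E_ik * B_k
    Q_i = B_i * sum_k E_ik * A_k * B_k

The exponential kernel propagates the influence of every atom to every
other with a weight that decays with topological distance, so each atom's
(P, Q) pair depends on the whole molecule while remaining attached to that
single atom — which is exactly what makes the descriptors convenient for
atom-level site-of-metabolism labeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .sdf import MoleculeGraph, connectivity_matrix

__all__ = [
    "ElementElectronicTable",
    "QnaResult",
    "NormalizationParams",
    "load_element_table",
    "matrix_exp_neg_half",
    "compute_pq",
    "fit_normalizer",
    "apply_normalizer",
]


@dataclass(frozen=True)
class ElementElectronicTable:
    """Mapping element symbol -> (IP, EA) in eV, with IP > EA for every
    entry so that B = (IP-EA)^(-1/2) is real and positive."""

    values: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for symbol, (ip, ea) in self.values.items():
            if not ip > ea:
                raise ValueError(f"element {symbol}: IP ({ip}) must exceed EA ({ea})")

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.values

    def ab(self, symbol: str) -> tuple[float, float]:
        """Atomic terms (A, B) = ((IP+EA)/2, (IP-EA)^(-1/2))."""
        ip, ea = self.values[symbol]
        return (ip + ea) / 2.0, (ip - ea) ** -0.5


def load_element_table(path: str | Path | None = None) -> ElementElectronicTable:
    """Load the element table; defaults to the packaged reference values.

    The file is tab-separated with columns symbol, IP, EA; lines starting
    with ``#`` are comments.
    """
    if path is None:
        text = resources.files("qnasom").joinpath("data/elements.tsv").read_text()
    else:
        text = Path(path).read_text()
    values: dict[str, tuple[float, float]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        symbol, ip, ea = line.split()
        values[symbol] = (float(ip), float(ea))
    required = {"H", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I"}
    missing = required - values.keys()
    if missing:
        raise ValueError(f"element table missing required symbols: {sorted(missing)}")
    return ElementElectronicTable(values)


_DEFAULT_TABLE: ElementElectronicTable | None = None


def default_element_table() -> ElementElectronicTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_element_table()
    return _DEFAULT_TABLE


def matrix_exp_neg_half(C: np.ndarray) -> np.ndarray:
    """exp(-C/2) for a symmetric matrix, via eigendecomposition.

    C must be symmetric (the adjacency matrix of the molecular graph); the
    result is symmetrized to remove round-off asymmetry.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {C.shape}")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("connectivity matrix must be symmetric")
    w, V = np.linalg.eigh(C)
    E = (V * np.exp(-0.5 * w)) @ V.T
    return (E + E.T) / 2.0


@dataclass(frozen=True)
class QnaResult:
    """Raw (pre-normalization) per-atom descriptor pairs for one molecule."""

    mol_id: str
    P: np.ndarray
    Q: np.ndarray

    def __post_init__(self) -> None:
        if self.P.shape != self.Q.shape or self.P.ndim != 1:
            raise ValueError("P and Q must be 1-D arrays of equal length")
        if not (np.isfinite(self.P).all() and np.isfinite(self.Q).all()):
            raise ValueError(f"{self.mol_id}: non-finite descriptor values")

    @property
    def n_atoms(self) -> int:
        return self.P.shape[0]


def compute_pq(
    molecule: MoleculeGraph, table: ElementElectronicTable | None = None
) -> QnaResult:
    """Compute raw QNA descriptors (P_i, Q_i) for every heavy atom."""
    if table is None:
        table = default_element_table()
    unknown = sorted({el for el in molecule.elements if el not in table})
    if unknown:
        raise KeyError(
            f"{molecule.mol_id}: element(s) {unknown} not in the electronic table"
        )
    A = np.empty(molecule.n_atoms)
    B = np.empty(molecule.n_atoms)
    for i, el in enumerate(molecule.elements):
        A[i], B[i] = table.ab(el)
    E = matrix_exp_neg_half(connectivity_matrix(molecule))
    P = B * (E @ B)
    Q = B * (E @ (A * B))
    return QnaResult(mol_id=molecule.mol_id, P=P, Q=Q)


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature z-scoring parameters fitted on a training partition.

    A zero-variance feature is mapped to 0 rather than dividing by zero.
    """

    mean: np.ndarray
    sd: np.ndarray
    fitted_on: str = ""

    def __post_init__(self) -> None:
        if (self.sd < 0).any():
            raise ValueError("standard deviations must be non-negative")


def fit_normalizer(values: np.ndarray, fitted_on: str = "") -> NormalizationParams:
    """Fit per-feature mean and population SD on rows of (P, Q) features."""
    X = np.atleast_2d(np.asarray(values, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit a normalizer")
    return NormalizationParams(
        mean=X.mean(axis=0), sd=X.std(axis=0, ddof=0), fitted_on=fitted_on
    )


def apply_normalizer(params: NormalizationParams, rows: np.ndarray) -> np.ndarray:
    """(x - mean) / sd per feature; zero-variance features map to 0."""
    X = np.atleast_2d(np.asarray(rows, dtype=float))
    sd = np.where(params.sd == 0, 1.0, params.sd)
    Z = (X - params.mean) / sd
    Z[:, params.sd == 0] = 0.0
    return Z
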