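"""SMOTE oversampling of the minority (SOM) class, written from scratch.

Synthetic minority rows are placed uniformly at random on the segment
between a minority point and one of its k nearest minority neighbors
(Euclidean metric in (P, Q) descriptor space):

    x_new = x + delta * (x_nn - x),   delta ~ U[0, 1]

Originals are kept unchanged; synthetic rows carry ``synthetic=True`` and a
fresh ``smote:`` mol_id namespace so they can never leak through a
molecule-level split into a test or validation fold.  Balancing is meant to
be applied to training partitions only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .dataset import SomDataset

__all__ = ["SmoteConfig", "smote_oversample"]


@dataclass(frozen=True)
class SmoteConfig:
    """k_neighbors=5 and target_ratio=1.0 reproduce the study protocol:
    five nearest neighbors, minority:majority ratio of one after
    oversampling."""

    k_neighbors: int = 5
    target_ratio: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.target_ratio <= 0:
            raise ValueError("target_ratio must be positive")


def _minority_neighbor_table(X_min: np.ndarray, k: int) -> np.ndarray:
    """(n_min, k) indices of each minority point's k nearest minority
    neighbors, self excluded, distance ties broken by lower index."""
    D = cdist(X_min, X_min)
    n = X_min.shape[0]
    np.fill_diagonal(D, np.inf)
    # lexsort: primary key distance, secondary key column index (stable)
    order = np.lexsort((np.tile(np.arange(n), (n, 1)), D), axis=1)
    return order[:, :k]


def smote_oversample(dataset: SomDataset, config: SmoteConfig) -> SomDataset:
    """Oversample label-1 rows until minority:majority = target_ratio.

    The number of synthetic points is spread as evenly as possible over the
    minority rows; the remainder is assigned to rows drawn at random.  With
    a fixed seed the output is reproducible bit-exactly.  Raises if fewer
    than 2 minority rows exist; clamps k to n_minority - 1 with a warning.
    """
    frame = dataset.frame
    min_mask = (frame["label"] == 1).to_numpy()
    n_min = int(min_mask.sum())
    n_maj = len(frame) - n_min
    if n_min < 2:
        raise ValueError(f"SMOTE needs at least 2 minority rows, got {n_min}")

    n_target = int(round(config.target_ratio * n_maj))
    n_syn = n_target - n_min
    if n_syn <= 0:
        return SomDataset(frame.copy(), dataset.group_key)

    k = config.k_neighbors
    if k > n_min - 1:
        warnings.warn(
            f"k_neighbors={k} exceeds minority size - 1; clamping to {n_min - 1}",
            stacklevel=2,
        )
        k = n_min - 1

    rng = np.random.default_rng(config.rng_seed)
    X_min = frame.loc[min_mask, ["P", "Q"]].to_numpy(dtype=float)
    neighbors = _minority_neighbor_table(X_min, k)

    counts = np.full(n_min, n_syn // n_min, dtype=int)
    remainder = n_syn - counts.sum()
    if remainder:
        counts[rng.choice(n_min, size=remainder, replace=False)] += 1

    sources = np.repeat(np.arange(n_min), counts)
    chosen = neighbors[sources, rng.integers(0, k, size=n_syn)]
    delta = rng.random(n_syn)
    X_new = X_min[sources] + delta[:, None] * (X_min[chosen] - X_min[sources])

    synthetic = pd.DataFrame(
        {
            "mol_id": [f"smote:{i:06d}" for i in range(n_syn)],
            "atom_index": np.zeros(n_syn, dtype=int),
            "P": X_new[:, 0],
            "Q": X_new[:, 1],
            "label": np.ones(n_syn, dtype=int),
            "synthetic": np.ones(n_syn, dtype=bool),
        }
    )
    out = pd.concat([frame, synthetic], ignore_index=True)
    return SomDataset(out, dataset.group_key)
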