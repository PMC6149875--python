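"""Evaluation protocols and metrics for atom-level SOM classification.

Metrics: sensitivity Se = TP/(TP+FN), specificity Sp = TN/(TN+FP),
balanced accuracy BA = (Se+Sp)/2, and the rank-based (Mann-Whitney) AUC
with the tie-correction that counts tied pairs as one half.

Protocols: repeated random 2:1 train/test splits (default five repeats)
and leave-one-molecule-out cross-validation.  All splits are at the
molecule level — every atom of a molecule lands on the same side — because
atoms of one molecule have strongly dependent descriptors and atom-level
splitting would leak near-duplicates across the boundary.  The feature
normalizer is fitted on the training partition of each repeat, and SMOTE
balancing (when requested) is applied to the training partition only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy.stats import rankdata

from .classifiers import ClassifierSpec, fit, predict_proba
from .dataset import SomDataset
from .descriptors import apply_normalizer, fit_normalizer
from .smote import SmoteConfig, smote_oversample

__all__ = [
    "ConfusionCounts",
    "EvalRecord",
    "EvalReport",
    "confusion",
    "metrics",
    "auc",
    "molecule_splits",
    "repeated_split_eval",
    "loo_eval",
    "top_k_hit_rate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(labels: Sequence[int], hard_predictions: Sequence[int]) -> ConfusionCounts:
    """Standard confusion counts with label 1 (SOM) as the positive class."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(hard_predictions, dtype=int)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary")
    return ConfusionCounts(
        TP=int(((y == 1) & (p == 1)).sum()),
        FP=int(((y == 0) & (p == 1)).sum()),
        TN=int(((y == 0) & (p == 0)).sum()),
        FN=int(((y == 1) & (p == 0)).sum()),
    )


def metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(Se, Sp, BA) from confusion counts; raises if a class is absent."""
    if counts.TP + counts.FN == 0:
        raise ValueError("sensitivity undefined: no positive instances")
    if counts.TN + counts.FP == 0:
        raise ValueError("specificity undefined: no negative instances")
    se = counts.TP / (counts.TP + counts.FN)
    sp = counts.TN / (counts.TN + counts.FP)
    return se, sp, (se + sp) / 2.0


def auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 * P(tie)."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass(frozen=True)
class EvalRecord:
    """Metrics of one evaluation repeat (or of the pooled LOO pass)."""

    se: float
    sp: float
    ba: float
    auc: float

    def __post_init__(self) -> None:
        if abs(self.ba - (self.se + self.sp) / 2.0) > 1e-12:
            raise ValueError("BA must equal (Se + Sp) / 2")
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")


@dataclass
class EvalReport:
    """Per-repeat metric records plus mean +/- SD aggregation."""

    records: list[EvalRecord]
    protocol: str
    classifier: str
    balanced: bool
    top_k: dict[int, float] = field(default_factory=dict)

    def _values(self, name: str) -> np.ndarray:
        return np.array([getattr(r, name) for r in self.records])

    def mean(self, name: str) -> float:
        return float(self._values(name).mean())

    def sd(self, name: str) -> float:
        v = self._values(name)
        return float(v.std(ddof=1)) if len(v) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "classifier": self.classifier,
            "balanced": self.balanced,
            "repeats": [
                {"se": r.se, "sp": r.sp, "ba": r.ba, "auc": r.auc}
                for r in self.records
            ],
            "aggregate": {
                name: {"mean": self.mean(name), "sd": self.sd(name)}
                for name in ("se", "sp", "ba", "auc")
            },
            "top_k": {str(k): v for k, v in self.top_k.items()},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def summary(self) -> str:
        lines = [
            f"protocol: {self.protocol}   classifier: {self.classifier}   "
            f"balanced: {self.balanced}   repeats: {len(self.records)}",
            f"{'metric':<6}{'mean':>10}{'sd':>10}",
        ]
        for name in ("se", "sp", "ba", "auc"):
            lines.append(f"{name:<6}{self.mean(name):>10.3f}{self.sd(name):>10.3f}")
        for k in sorted(self.top_k):
            lines.append(f"top-{k} hit rate: {self.top_k[k]:.1f}%")
        return "\n".join(lines)


def molecule_splits(
    molecules: Sequence[str],
    repeats: int,
    train_fraction: float,
    seed: int,
) -> Iterator[tuple[list[str], list[str]]]:
    """Repeated random molecule-level splits (train_ids, test_ids)."""
    mols = list(molecules)
    n_train = int(round(train_fraction * len(mols)))
    if n_train < 1 or n_train >= len(mols):
        raise ValueError(f"cannot split {len(mols)} molecules at fraction {train_fraction}")
    rng = np.random.default_rng(seed)
    for _ in range(repeats):
        order = rng.permutation(len(mols))
        yield (
            [mols[i] for i in order[:n_train]],
            [mols[i] for i in order[n_train:]],
        )


def _prepare_fold(
    dataset: SomDataset,
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    balance: bool,
    smote_seed: int,
) -> tuple[SomDataset, SomDataset]:
    """Normalize on train, optionally SMOTE train, and verify no leakage."""
    train = dataset.subset_by_molecules(train_ids)
    test = dataset.subset_by_molecules(test_ids)
    norm = fit_normalizer(train.features, fitted_on="train-fold")
    train = train.with_features(apply_normalizer(norm, train.features))
    test = test.with_features(apply_normalizer(norm, test.features))
    if balance:
        train = smote_oversample(train, SmoteConfig(rng_seed=smote_seed))
    overlap = set(train.frame.loc[~train.frame["synthetic"], "mol_id"]) & set(test.mol_ids)
    if overlap:
        raise AssertionError(f"molecule(s) on both sides of a split: {sorted(overlap)[:5]}")
    if test.frame["synthetic"].any():
        raise AssertionError("synthetic rows leaked into a test fold")
    return train, test


def repeated_split_eval(
    dataset: SomDataset,
    spec: ClassifierSpec,
    repeats: int = 5,
    train_fraction: float = 2.0 / 3.0,
    balance: bool = False,
    seed: int = 0,
    compute_top_k: bool = False,
) -> EvalReport:
    """Repeated random 2:1 molecule-level splits, averaged over repeats.

    Per repeat: fit the normalizer on the training partition, optionally
    SMOTE-balance the training partition, fit, then score the untouched
    test partition.  ``compute_top_k`` additionally reports molecule-level
    top-k hit rates (k = 1, 2, 3) averaged over repeats.
    """
    records = []
    topk_acc: dict[int, list[float]] = {1: [], 2: [], 3: []}
    splits = molecule_splits(dataset.molecules, repeats, train_fraction, seed)
    for r, (train_ids, test_ids) in enumerate(splits):
        train, test = _prepare_fold(dataset, train_ids, test_ids, balance, seed * 1000 + r)
        model = fit(spec, train)
        scores = predict_proba(model, test)
        hard = (scores >= 0.5).astype(int)
        se, sp, ba = metrics(confusion(test.labels, hard))
        records.append(EvalRecord(se=se, sp=sp, ba=ba, auc=auc(test.labels, scores)))
        if compute_top_k:
            groups = _per_molecule(test, scores)
            for k in topk_acc:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    topk_acc[k].append(top_k_hit_rate(groups, k))
    top_k = (
        {k: float(np.mean(v)) for k, v in topk_acc.items() if v} if compute_top_k else {}
    )
    return EvalReport(
        records=records,
        protocol=f"repeated-split({repeats}x, {train_fraction:.2f})",
        classifier=spec.kind,
        balanced=balance,
        top_k=top_k,
    )


def loo_eval(
    dataset: SomDataset,
    spec: ClassifierSpec,
    balance: bool = False,
    seed: int = 0,
) -> EvalReport:
    """Leave-one-molecule-out cross-validation with pooled scoring.

    Out-of-fold scores are pooled over all molecules before computing a
    single AUC (a per-fold AUC is undefined when a fold holds only one
    class), and Se/Sp/BA are computed on the pooled hard predictions.
    """
    mols = dataset.molecules
    if len(mols) < 3:
        raise ValueError("leave-one-out needs at least 3 molecules")
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for f, held_out in enumerate(mols):
        train_ids = [m for m in mols if m != held_out]
        train, test = _prepare_fold(dataset, train_ids, [held_out], balance, seed * 1000 + f)
        model = fit(spec, train)
        pooled_scores.append(predict_proba(model, test))
        pooled_labels.append(test.labels)
    scores = np.concatenate(pooled_scores)
    labels = np.concatenate(pooled_labels)
    hard = (scores >= 0.5).astype(int)
    se, sp, ba = metrics(confusion(labels, hard))
    record = EvalRecord(se=se, sp=sp, ba=ba, auc=auc(labels, scores))
    return EvalReport(
        records=[record],
        protocol=f"leave-one-out({len(mols)} molecules)",
        classifier=spec.kind,
        balanced=balance,
    )


def _per_molecule(test: SomDataset, scores: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group (scores, labels) arrays by molecule, in dataset order."""
    frame = test.frame
    out = []
    for mol_id in test.molecules:
        mask = (frame["mol_id"] == mol_id).to_numpy()
        out.append((scores[mask], test.labels[mask]))
    return out


def top_k_hit_rate(
    molecule_scores: Sequence[tuple[np.ndarray, np.ndarray]], k: int
) -> float:
    """Percentage of molecules whose k top-scoring atoms include a SOM.

    ``molecule_scores`` is a sequence of (scores, labels) pairs, one per
    molecule.  Ties in score are broken by lower atom index.  Molecules
    without any true SOM are excluded with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    hits = total = 0
    for scores, labels in molecule_scores:
        if labels.sum() == 0:
            warnings.warn("molecule without a SOM excluded from top-k", stacklevel=2)
            continue
        # stable sort on -score keeps lower atom index first among ties
        top = np.argsort(-np.asarray(scores), kind="stable")[:k]
        total += 1
        hits += int(np.asarray(labels)[top].any())
    if total == 0:
        raise ValueError("no molecule with a SOM to score")
    return 100.0 * hits / total
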