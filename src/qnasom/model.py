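"""Model-object front end for the SOM prediction pipeline.

``SomModel`` wraps a per-atom dataset plus a classifier configuration;
``fit()`` runs the evaluation protocol (repeated 2:1 splits or
leave-one-molecule-out), trains a final classifier on the full dataset,
and returns a ``SomResults`` carrying the metric estimates with their
spread, the fitted classifier, and a ``summary()`` table — in the spirit
of the model/results split used by statsmodels.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .classifiers import ClassifierSpec, FittedModel, fit as fit_classifier, predict_proba
from .dataset import SomDataset, build_dataset, imbalance_ratio
from .descriptors import (
    NormalizationParams,
    apply_normalizer,
    compute_pq,
    fit_normalizer,
)
from .evaluation import EvalReport, loo_eval, repeated_split_eval
from .sdf import MoleculeGraph, read_sdf
from .smote import SmoteConfig, smote_oversample

__all__ = ["SomModel", "SomResults"]


class SomModel:
    """Atom-level SOM classifier over QNA descriptors.

    Parameters
    ----------
    dataset : SomDataset with raw (unnormalized) P, Q features.
    classifier : one of naive_bayes/random_forest/rbf_network/mlp (or the
        short aliases nb/rf/rbf/mlp).  Default random_forest, the
        best-performing configuration on both balanced and imbalanced sets.
    balance : SMOTE-balance training partitions to a 1:1 class ratio.
    seed : master RNG seed for splits, SMOTE, and classifier training.
    """

    def __init__(
        self,
        dataset: SomDataset,
        classifier: str = "random_forest",
        balance: bool = True,
        seed: int = 0,
        **hyperparameters,
    ) -> None:
        self.dataset = dataset
        self.spec = ClassifierSpec(
            kind=classifier, hyperparameters=hyperparameters, rng_seed=seed
        )
        self.balance = balance
        self.seed = seed

    @classmethod
    def from_sdf(cls, path: str | Path, **kwargs) -> "SomModel":
        """Build the model from a SOM-annotated SDF file."""
        molecules = read_sdf(path)
        descriptors = [compute_pq(m) for m in molecules]
        return cls(build_dataset(molecules, descriptors), **kwargs)

    @classmethod
    def from_molecules(cls, molecules: Sequence[MoleculeGraph], **kwargs) -> "SomModel":
        descriptors = [compute_pq(m) for m in molecules]
        return cls(build_dataset(molecules, descriptors), **kwargs)

    def fit(
        self,
        protocol: str = "repeated-split",
        repeats: int = 5,
        compute_top_k: bool = False,
    ) -> "SomResults":
        """Evaluate with the chosen protocol and train the final model.

        protocol: "repeated-split" (2:1 train/test, ``repeats`` times) or
        "loo" (leave-one-molecule-out); use ``protocol=None`` to skip
        evaluation and only train on the full dataset.
        """
        report = None
        if protocol == "repeated-split":
            report = repeated_split_eval(
                self.dataset,
                self.spec,
                repeats=repeats,
                balance=self.balance,
                seed=self.seed,
                compute_top_k=compute_top_k,
            )
        elif protocol == "loo":
            report = loo_eval(
                self.dataset, self.spec, balance=self.balance, seed=self.seed
            )
        elif protocol is not None:
            raise ValueError(f"unknown protocol {protocol!r}")

        normalizer = fit_normalizer(self.dataset.features, fitted_on="full-dataset")
        train = self.dataset.with_features(
            apply_normalizer(normalizer, self.dataset.features)
        )
        if self.balance:
            train = smote_oversample(train, SmoteConfig(rng_seed=self.seed))
        final = fit_classifier(self.spec, train, normalizer_id=normalizer.fitted_on)
        return SomResults(self, final, normalizer, report)


class SomResults:
    """Fitted classifier, its normalizer, and the evaluation report."""

    def __init__(
        self,
        model: SomModel,
        fitted: FittedModel,
        normalizer: NormalizationParams,
        report: EvalReport | None,
    ) -> None:
        self.model = model
        self.fitted = fitted
        self.normalizer = normalizer
        self.report = report

    def predict_proba(self, molecules: Sequence[MoleculeGraph]) -> list[np.ndarray]:
        """Per-molecule arrays of SOM probabilities, one value per heavy atom."""
        out = []
        for mol in molecules:
            qna = compute_pq(mol)
            X = apply_normalizer(self.normalizer, np.column_stack([qna.P, qna.Q]))
            out.append(predict_proba(self.fitted, X))
        return out

    def rank_atoms(self, molecule: MoleculeGraph) -> list[tuple[int, float]]:
        """(atom_index, probability) pairs sorted best-first, ties broken
        by lower atom index."""
        (scores,) = self.predict_proba([molecule])
        order = np.argsort(-scores, kind="stable")
        return [(int(i), float(scores[i])) for i in order]

    def summary(self) -> str:
        n = len(self.model.dataset)
        head = [
            "SOM prediction results",
            f"instances: {n}  (SOM: {self.model.dataset.n_positive}, "
            f"non-SOM: {self.model.dataset.n_negative}, "
            f"imbalance ratio: {imbalance_ratio(self.model.dataset):.4f})",
            f"classifier: {self.fitted.spec.kind}   "
            f"balanced training: {self.model.balance}   seed: {self.model.seed}",
        ]
        if self.report is not None:
            head.append(self.report.summary())
        else:
            head.append("(no evaluation protocol was run)")
        return "\n".join(head)
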