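"""Dataset assembly, group filtering, imbalance accounting, and the
from-scratch SMOTE balancer."""

import numpy as np
import pandas as pd
import pytest

from qnasom import (
    REACTION_TYPES,
    SmoteConfig,
    SomDataset,
    build_dataset,
    compute_pq,
    filter_by_group,
    imbalance_ratio,
    smote_oversample,
)


def make_dataset(n_pos: int, n_neg: int, rng_seed: int = 0) -> SomDataset:
    """Synthetic descriptor-space dataset with given class counts."""
    rng = np.random.default_rng(rng_seed)
    n = n_pos + n_neg
    frame = pd.DataFrame(
        {
            "mol_id": [f"m{i // 10}" for i in range(n)],
            "atom_index": np.arange(n) % 10,
            "P": rng.normal(size=n),
            "Q": rng.normal(size=n),
            "label": [1] * n_pos + [0] * n_neg,
            "synthetic": False,
        }
    )
    return SomDataset(frame)


class TestBuildDataset:
    def test_one_instance_per_heavy_atom(self, sim_molecules):
        descriptors = [compute_pq(m) for m in sim_molecules]
        dataset = build_dataset(sim_molecules, descriptors)
        assert len(dataset) == sum(m.n_atoms for m in sim_molecules)
        assert dataset.n_positive == sum(sum(m.som_flags) for m in sim_molecules)

    def test_instance_order_is_molecule_then_atom(self, sim_molecules):
        descriptors = [compute_pq(m) for m in sim_molecules]
        dataset = build_dataset(sim_molecules, descriptors)
        expected = [
            (m.mol_id, i) for m in sim_molecules for i in range(m.n_atoms)
        ]
        got = list(zip(dataset.frame["mol_id"], dataset.frame["atom_index"]))
        assert got == expected

    def test_zero_som_molecule_contributes_only_negatives(self, sim_molecules):
        no_som = [m for m in sim_molecules if not any(m.som_flags)]
        assert no_som, "fixture should contain molecules without SOMs"
        dataset = build_dataset(no_som, [compute_pq(m) for m in no_som])
        assert dataset.n_positive == 0

    def test_missing_descriptors_rejected(self, sim_molecules):
        with pytest.raises(KeyError, match="no descriptors"):
            build_dataset(sim_molecules[:3], [compute_pq(sim_molecules[0])])


class TestFilterByGroup:
    def test_empty_filter_is_identity(self, sim_molecules):
        descriptors = [compute_pq(m) for m in sim_molecules]
        full = build_dataset(sim_molecules, descriptors)
        filtered = filter_by_group(sim_molecules, descriptors)
        pd.testing.assert_frame_equal(filtered.frame, full.frame)

    def test_combined_filter_keeps_only_matches(self, sim_molecules):
        descriptors = [compute_pq(m) for m in sim_molecules]
        dataset = filter_by_group(
            sim_molecules,
            descriptors,
            reaction_type="O-dealkylation",
            isoform="CYP2C19",
        )
        wanted = {
            m.mol_id
            for m in sim_molecules
            if m.reaction == "O-dealkylation" and m.isoform == "CYP2C19"
        }
        assert set(dataset.molecules) == wanted
        assert dataset.group_key == ("O-dealkylation", "CYP2C19")

    def test_reaction_subsets_partition_labeled_records(self, sim_molecules):
        descriptors = [compute_pq(m) for m in sim_molecules]
        total = 0
        seen: set[str] = set()
        for reaction in REACTION_TYPES:
            sub = filter_by_group(sim_molecules, descriptors, reaction_type=reaction)
            assert not (set(sub.molecules) & seen)
            seen |= set(sub.molecules)
            total += len(sub)
        labeled = [m for m in sim_molecules if m.reaction is not None]
        assert total == sum(m.n_atoms for m in labeled)

    def test_unknown_names_list_valid_categories(self, sim_molecules):
        descriptors = [compute_pq(m) for m in sim_molecules]
        with pytest.raises(ValueError, match="aliphatic hydroxylation"):
            filter_by_group(sim_molecules, descriptors, reaction_type="bogus")
        with pytest.raises(ValueError, match="CYP1A2"):
            filter_by_group(sim_molecules, descriptors, isoform="CYP9Z9")


class TestImbalanceRatio:
    def test_arithmetic(self):
        assert imbalance_ratio(make_dataset(5, 100)) == pytest.approx(0.05)
        assert imbalance_ratio(make_dataset(0, 50)) == 0.0

    def test_all_positive_rejected(self):
        with pytest.raises(ValueError, match="no negative"):
            imbalance_ratio(make_dataset(5, 0))

    def test_generator_hits_requested_ratio(self, sim_dataset):
        assert imbalance_ratio(sim_dataset) == pytest.approx(0.05, abs=0.01)


class TestSmote:
    def test_duplicate_minority_points_synthesize_in_place(self):
        frame = pd.DataFrame(
            {
                "mol_id": ["a", "b", "c", "d", "e", "f"],
                "atom_index": 0,
                "P": [1.0, 1.0, 0.0, 2.0, 3.0, 4.0],
                "Q": [1.0, 1.0, 0.0, 2.0, 3.0, 4.0],
                "label": [1, 1, 0, 0, 0, 0],
                "synthetic": False,
            }
        )
        out = smote_oversample(SomDataset(frame), SmoteConfig(k_neighbors=1, rng_seed=0))
        new = out.frame[out.frame["synthetic"]]
        assert (new["P"] == 1.0).all() and (new["Q"] == 1.0).all()

    def test_synthetic_points_lie_on_neighbor_segments(self):
        dataset = make_dataset(40, 800, rng_seed=5)
        out = smote_oversample(dataset, SmoteConfig(rng_seed=9))
        X_min = dataset.frame.loc[dataset.frame["label"] == 1, ["P", "Q"]].to_numpy()
        new = out.frame.loc[out.frame["synthetic"], ["P", "Q"]].to_numpy()
        assert len(new) == 800 - 40
        # each synthetic point must be a convex combination of two minority
        # points: check it lies on some segment between minority points
        for p in new[:200]:
            d = X_min - p
            # p on segment (a, b) iff d_a and d_b are antiparallel
            cross = np.abs(d[:, None, 0] * d[None, :, 1] - d[:, None, 1] * d[None, :, 0])
            dot = (d[:, None, :] * d[None, :, :]).sum(axis=2)
            on_segment = (cross < 1e-8) & (dot <= 1e-12)
            assert on_segment.any()

    def test_majority_rows_bit_identical_and_ratio_one(self):
        dataset = make_dataset(50, 1000, rng_seed=1)
        out = smote_oversample(dataset, SmoteConfig(rng_seed=2))
        maj_before = dataset.frame[dataset.frame["label"] == 0].reset_index(drop=True)
        maj_after = out.frame[(out.frame["label"] == 0)].reset_index(drop=True)
        pd.testing.assert_frame_equal(maj_before, maj_after)
        assert out.n_positive == out.n_negative

    def test_reproducible_with_fixed_seed(self):
        dataset = make_dataset(30, 600, rng_seed=4)
        a = smote_oversample(dataset, SmoteConfig(rng_seed=77))
        b = smote_oversample(dataset, SmoteConfig(rng_seed=77))
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_too_few_minority_rejected_and_k_clamped(self):
        with pytest.raises(ValueError, match="at least 2 minority"):
            smote_oversample(make_dataset(1, 50), SmoteConfig())
        with pytest.warns(UserWarning, match="clamping"):
            out = smote_oversample(make_dataset(3, 50), SmoteConfig(k_neighbors=5))
        assert out.n_positive == out.n_negative

    def test_synthetic_cloud_mean_matches_closed_form(self):
        # independent oracle: E[x_new] = mean_i (x_i + 0.5 * (nnbar_i - x_i))
        # when counts are even over sources, neighbors uniform over k, and
        # delta ~ U[0,1]
        rng = np.random.default_rng(10)
        n_min, k = 20, 5
        X_min = rng.normal(size=(n_min, 2))
        n_maj = 20 + n_min * 500  # forces exactly 500 synthetics per source
        frame = pd.DataFrame(
            {
                "mol_id": [f"r{i}" for i in range(n_min + n_maj)],
                "atom_index": 0,
                "P": np.concatenate([X_min[:, 0], rng.normal(8, 1, n_maj)]),
                "Q": np.concatenate([X_min[:, 1], rng.normal(8, 1, n_maj)]),
                "label": [1] * n_min + [0] * n_maj,
                "synthetic": False,
            }
        )
        out = smote_oversample(SomDataset(frame), SmoteConfig(k_neighbors=k, rng_seed=3))
        new = out.frame.loc[out.frame["synthetic"], ["P", "Q"]].to_numpy()

        from scipy.spatial.distance import cdist

        D = cdist(X_min, X_min)
        np.fill_diagonal(D, np.inf)
        expected = np.zeros(2)
        for i in range(n_min):
            nn = np.argsort(D[i], kind="stable")[:k]
            expected += X_min[i] + 0.5 * (X_min[nn].mean(axis=0) - X_min[i])
        expected /= n_min
        mc_err = 4 * new.std(axis=0) / np.sqrt(len(new))
        assert np.abs(new.mean(axis=0) - expected).max() < mc_err.max() + 0.02


class TestTsvRoundTrip:
    def test_dataset_tsv_round_trip(self, sim_dataset, tmp_path):
        path = tmp_path / "d.tsv"
        sim_dataset.to_tsv(path)
        back = SomDataset.from_tsv(path)
        assert (back.labels == sim_dataset.labels).all()
        assert np.allclose(back.features, sim_dataset.features)
        assert back.molecules == sim_dataset.molecules
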