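"""Pair-feature fusion and the classical scorer family."""

import numpy as np
import pytest

from seqsimrank.base import load_scorer
from seqsimrank.data import TaskSpec, build_ranking_dataset
from seqsimrank.distribution import (
    DISTRIBUTION_MODELS,
    train_distribution_model,
)
from seqsimrank.features import PairFeatureScheme, default_scheme, make_pair_features
from seqsimrank.metrics import auc_score


class TestPairFeatures:
    def test_concat_scheme(self):
        out = make_pair_features([1, 2], [3, 4], PairFeatureScheme("concat"))
        np.testing.assert_array_equal(out, [1, 2, 3, 4])

    def test_symmetric_scheme_values(self):
        out = make_pair_features([1, 2], [3, 4], PairFeatureScheme("symmetric"))
        np.testing.assert_array_equal(out, [2, 2, 3, 8])

    def test_symmetric_scheme_is_order_invariant(self):
        scheme = PairFeatureScheme("symmetric")
        a = make_pair_features([1.5, -2, 0.25], [0.5, 3, -1], scheme)
        b = make_pair_features([0.5, 3, -1], [1.5, -2, 0.25], scheme)
        np.testing.assert_array_equal(a, b)

    def test_symmetric_requires_equal_dims(self):
        with pytest.raises(ValueError, match="equal dims"):
            make_pair_features([1, 2], [1, 2, 3], PairFeatureScheme("symmetric"))

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            PairFeatureScheme("hadamard")

    def test_default_scheme_by_task_kind(self, homo_dataset, hetero_dataset):
        assert default_scheme(homo_dataset.task).name == "symmetric"
        assert default_scheme(hetero_dataset.task).name == "concat"


class TestDistributionScorers:
    def test_rf_recovers_planted_signal(self, homo_dataset):
        scorer = train_distribution_model("rf", homo_dataset, seed=1)
        pairs, y, _ = homo_dataset.pairs_in("test")
        assert auc_score(scorer.score_pairs(pairs, homo_dataset.task), y) >= 0.95

    def test_shuffled_labels_give_null_auc(self, homo_bench):
        # label permutation destroys the pair->label mapping; held-out AUC
        # (averaged over seeds to tame the small-test-set variance) is chance
        corpus, labels, _ = homo_bench
        from seqsimrank.data import PairLabelSet

        pairs = list(labels.positives) + list(labels.negatives)
        task = TaskSpec("homogeneous", corpus)
        values = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            perm = rng.permutation(len(pairs))
            half = len(pairs) // 2
            shuffled = PairLabelSet(
                tuple(pairs[i] for i in perm[:half]),
                tuple(pairs[i] for i in perm[half:]),
            )
            ds = build_ranking_dataset(task, shuffled, seed=seed)
            scorer = train_distribution_model("rf", ds, seed=seed)
            tpairs, ty, _ = ds.pairs_in("test")
            values.append(auc_score(scorer.score_pairs(tpairs, task), ty))
        assert 0.42 <= np.mean(values) <= 0.58

    def test_single_class_training_rejected(self, homo_bench):
        from seqsimrank.data import PairLabelSet, RankingDataset

        corpus, labels, _ = homo_bench
        task = TaskSpec("homogeneous", corpus)
        ds = build_ranking_dataset(task, labels, seed=1)
        all_pos = {
            q: [(c, 1) for c, _ in cands] for q, cands in ds.groups.items()
        }
        broken = RankingDataset(all_pos, ds.partition, task, 1)
        with pytest.raises(ValueError, match="both classes"):
            train_distribution_model("rf", broken, seed=1)

    def test_unknown_name_lists_valid_models(self, homo_dataset):
        with pytest.raises(ValueError, match="svm"):
            train_distribution_model("xgboost", homo_dataset, seed=1)

    def test_symmetric_scorer_is_exactly_order_invariant(self, homo_dataset):
        scorer = train_distribution_model("knn", homo_dataset, seed=1)
        pairs, _, _ = homo_dataset.pairs_in("test")
        forward = scorer.score_pairs(pairs[:50], homo_dataset.task)
        backward = scorer.score_pairs([(b, a) for a, b in pairs[:50]], homo_dataset.task)
        np.testing.assert_array_equal(forward, backward)

    def test_scoring_is_deterministic_and_bounded(self, homo_dataset):
        scorer = train_distribution_model("mlp", homo_dataset, seed=1)
        pairs, _, _ = homo_dataset.pairs_in("valid")
        s1 = scorer.score_pairs(pairs, homo_dataset.task)
        s2 = scorer.score_pairs(pairs, homo_dataset.task)
        np.testing.assert_array_equal(s1, s2)
        assert np.all((s1 >= 0) & (s1 <= 1))
        assert len(scorer.score_pairs([], homo_dataset.task)) == 0
        rep = scorer.score_pairs([pairs[0], pairs[0]], homo_dataset.task)
        assert rep[0] == rep[1]

    def test_mnb_handles_negative_features_via_recorded_shift(self, homo_dataset):
        scorer = train_distribution_model("mnb", homo_dataset, seed=1)
        assert scorer.feature_shift is not None
        pairs, y, _ = homo_dataset.pairs_in("test")
        s = scorer.score_pairs(pairs, homo_dataset.task)
        assert np.all((s >= 0) & (s <= 1))
        assert auc_score(s, y) > 0.8  # shift must not destroy the signal

    def test_knn_prediction_stable_under_duplicated_training_pairs(self, homo_bench):
        from seqsimrank.data import PairLabelSet

        corpus, labels, _ = homo_bench
        task = TaskSpec("homogeneous", corpus)
        ds = build_ranking_dataset(task, labels, seed=1)
        scorer = train_distribution_model("knn", ds, seed=1)
        # duplicating training data leaves 1-NN predictions on training points fixed
        pairs, y, _ = ds.pairs_in("train")
        import sklearn.neighbors

        X = scorer._features(pairs, task)
        knn1 = sklearn.neighbors.KNeighborsClassifier(n_neighbors=1).fit(X, y)
        knn2 = sklearn.neighbors.KNeighborsClassifier(n_neighbors=1).fit(
            np.vstack([X, X]), np.concatenate([y, y])
        )
        np.testing.assert_array_equal(knn1.predict(X), knn2.predict(X))

    def test_gs_mode_grids_stay_bounded_and_select_on_validation(self, homo_dataset):
        scorer = train_distribution_model("knn", homo_dataset, gs_mode=1, seed=1)
        assert scorer.metadata["grid_point"]  # a concrete grid point was chosen
        from seqsimrank.distribution import _grid_points

        for name in DISTRIBUTION_MODELS:
            assert len(_grid_points(name, 2)) <= 64
            assert all(len(p) <= 3 for p in _grid_points(name, 2))

    def test_persistence_round_trip_bit_identical(self, homo_dataset, tmp_path):
        scorer = train_distribution_model("gbdt", homo_dataset, seed=1)
        pairs, _, _ = homo_dataset.pairs_in("test")
        before = scorer.score_pairs(pairs, homo_dataset.task)
        scorer.save(tmp_path / "gbdt.scorer")
        loaded = load_scorer(tmp_path / "gbdt.scorer")
        np.testing.assert_array_equal(
            before, loaded.score_pairs(pairs, homo_dataset.task)
        )

    @pytest.mark.parametrize("name", ["goss", "dart"])
    def test_boosting_variants_train_and_score(self, homo_dataset, name):
        scorer = train_distribution_model(name, homo_dataset, seed=1)
        pairs, y, _ = homo_dataset.pairs_in("test")
        assert auc_score(scorer.score_pairs(pairs, homo_dataset.task), y) > 0.9
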