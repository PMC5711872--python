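import itertools

import numpy as np
import pytest

from scarvss import build_ovo_coding, loo_cross_validate, predict, train
from scarvss.ecoc_classifier import EcocModel, LEARNER_SPECS, decode_losses


def two_clouds(rng, n=12, d=3, gap=10.0):
    X = np.vstack(
        [rng.normal(0, 1, size=(n, d)), rng.normal(gap, 1, size=(n, d))]
    )
    y = np.array([0] * n + [1] * n)
    return X, y


class TestCoding:
    def test_pair_columns(self):
        cm = build_ovo_coding([1, 2])
        assert cm.matrix.shape == (2, 1)
        cm3 = build_ovo_coding([3, 1, 2])
        assert cm3.matrix.shape == (3, 3)
        # lexicographic pairs: (1,2), (1,3), (2,3)
        assert cm3.matrix.tolist() == [[1, 1, 0], [-1, 0, 1], [0, -1, -1]]

    def test_eight_classes_give_28_columns(self):
        cm = build_ovo_coding([0, 1, 2, 4, 5, 7, 8, 9])
        assert cm.matrix.shape == (8, 28)
        # every column: exactly one +1, one -1, K-2 zeros; no duplicates
        assert ((cm.matrix == 1).sum(axis=0) == 1).all()
        assert ((cm.matrix == -1).sum(axis=0) == 1).all()
        assert len({tuple(col) for col in cm.matrix.T}) == 28

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            build_ovo_coding([5])


class TestTrainPredict:
    def test_knn1_memorizes_training_set(self, rng):
        X, y = two_clouds(rng)
        model = train((X, y), "knn1")
        assert (predict(model, X) == y).all()

    def test_eight_class_model_holds_28_learners(self, rng):
        X = rng.normal(0, 1, size=(16, 4))
        y = np.repeat([0, 1, 2, 4, 5, 7, 8, 9], 2)
        model = train((X, y), "knn1")
        assert len(model.learners) == 28

    @pytest.mark.parametrize("spec", LEARNER_SPECS)
    def test_each_learner_separates_clean_clouds(self, spec, rng):
        X, y = two_clouds(rng, n=15)
        model = train((X, y), spec, seed=0)
        assert (predict(model, X) == y).all()

    def test_unknown_spec_rejected(self, rng):
        X, y = two_clouds(rng)
        with pytest.raises(ValueError, match="unknown learner"):
            train((X, y), "random_forest")

    def test_dimension_mismatch_rejected(self, rng):
        X, y = two_clouds(rng)
        model = train((X, y), "knn1")
        with pytest.raises(ValueError, match="dimension"):
            predict(model, np.zeros((1, 5)))

    def test_k2_prediction_equals_single_binary_learner(self, rng):
        X, y = two_clouds(rng, n=8, gap=2.0)
        model = train((X, y), "knn1")
        assert len(model.learners) == 1
        votes = model.learners[0].score(X)
        expected = np.where(votes > 0, 0, 1)  # +1 codes class 0, -1 class 1
        assert (predict(model, X) == expected).all()


def _hamming_model(K):
    coding = build_ovo_coding(list(range(K)))
    return EcocModel(
        coding=coding, learners=[], learner_spec="knn1",
        decoding_loss="hamming", n_features=0,
    )


class TestDecoding:
    def test_three_class_hand_example(self):
        # votes (+1, +1, -1) on columns (1v2), (1v3), (2v3): class 1 has
        # zero loss on both of its columns
        model = _hamming_model(3)
        losses = decode_losses(model, np.array([[1.0, 1.0, -1.0]]))
        assert losses[0].argmin() == 0
        assert losses[0][0] == 0.0

    def test_all_zero_scores_tie_break_to_smallest_label(self):
        model = _hamming_model(4)
        losses = decode_losses(model, np.zeros((1, 6)))
        assert np.unique(losses).size == 1  # perfect tie
        assert model.coding.class_order[losses[0].argmin()] == 0

    def test_losses_nonnegative_and_prediction_attains_minimum(self, rng):
        model = _hamming_model(4)
        scores = rng.choice([-1.0, 1.0], size=(20, 6))
        losses = decode_losses(model, scores)
        assert (losses >= 0).all()

    @pytest.mark.parametrize("K", [2, 3, 4])
    def test_hamming_decoding_equals_pairwise_majority_vote(self, K):
        """One-vs-one ECOC with Hamming decoding on hard votes is pairwise
        majority voting with ties to the smallest class label, for every
        possible vote pattern."""
        model = _hamming_model(K)
        pairs = list(itertools.combinations(range(K), 2))
        for votes in itertools.product([1.0, -1.0], repeat=len(pairs)):
            losses = decode_losses(model, np.array([votes]))
            ecoc_pick = int(model.coding.class_order[losses[0].argmin()])
            wins = [0] * K
            for (a, b), v in zip(pairs, votes):
                wins[a if v > 0 else b] += 1
            majority_pick = int(np.argmax(wins))  # first max = smallest label
            assert ecoc_pick == majority_pick


class TestLOO:
    def test_perfectly_separated_clouds_100_percent(self, rng):
        X, y = two_clouds(rng, n=10)
        true, pred = loo_cross_validate((X, y), "knn1")
        assert (true == y).all()
        assert (pred == y).all()

    def test_returns_one_prediction_per_sample_in_input_order(self, rng):
        X = rng.normal(0, 1, size=(12, 3))
        y = np.array([0, 1, 2] * 4)
        true, pred = loo_cross_validate((X, y), "knn1")
        assert len(pred) == 12
        assert (true == y).all()

    def test_invariant_to_sample_order_for_deterministic_learner(self, rng):
        X, y = two_clouds(rng, n=8, gap=3.0)
        _, pred = loo_cross_validate((X, y), "knn1")
        perm = rng.permutation(len(y))
        _, pred_perm = loo_cross_validate((X[perm], y[perm]), "knn1")
        assert (pred_perm == pred[perm]).all()

    def test_permuted_labels_fall_to_chance(self, rng):
        # separable 4-class problem, labels shuffled: accuracy should drop
        # to roughly 1/K; bound at 2/K over repetitions
        accs = []
        for rep in range(3):
            X = np.vstack([rng.normal(5 * k, 1, size=(12, 3)) for k in range(4)])
            y = rng.permutation(np.repeat(np.arange(4), 12))
            true, pred = loo_cross_validate((X, y), "knn1")
            accs.append((true == pred).mean())
        assert np.mean(accs) <= 2 / 4

    def test_fold_standardize_runs_and_stays_accurate(self, rng):
        X, y = two_clouds(rng, n=8)
        _, pred = loo_cross_validate((X, y), "knn1", fold_standardize=True)
        assert (pred == y).all()

    def test_too_few_samples_rejected(self, rng):
        X = rng.normal(0, 1, size=(3, 2))
        y = np.array([0, 1, 2])
        with pytest.raises(ValueError, match="LOO"):
            loo_cross_validate((X, y), "knn1")
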