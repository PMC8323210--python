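"""Personalized kNN prediction, training-subset selection, and the
evaluation metrics (AUC checked against a concordant-pair oracle)."""

import itertools

import numpy as np
import pytest

from emrsim import (CombinationSpec, ce_loss, f1_score, knn_predict,
                    loo_evaluate, micro_auc, run_combination_grid,
                    select_training)


@pytest.fixture
def clustered():
    """Four well-separated clusters of 8 points each in 2-D, with a similarity
    matrix derived from distances."""
    rng = np.random.default_rng(7)
    centers = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], dtype=float)
    X, labels = [], []
    for c, name in zip(centers, ("a", "b", "c", "d")):
        X.append(c + 0.3 * rng.standard_normal((8, 2)))
        labels += [name] * 8
    X = np.vstack(X)
    D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    S = 1.0 / (1.0 + D)
    return X, np.array(labels), S


class TestSelectTraining:
    def test_full_pool_at_M_100_any_mode(self, clustered):
        X, labels, S = clustered
        pool = np.arange(1, 32)
        for mode in ("random", "learned", "euclidean"):
            spec = CombinationSpec(training_selection=mode, M_percent=100, k=5)
            assert np.array_equal(select_training(pool, 0, spec, S=S, X=X), pool)

    def test_learned_mode_takes_highest_similarity(self, clustered):
        X, labels, S = clustered
        pool = np.arange(1, 11)
        spec = CombinationSpec(training_selection="learned", M_percent=50, k=5)
        chosen = select_training(pool, 0, spec, S=S)
        top5 = pool[np.argsort(-S[0, pool], kind="stable")[:5]]
        assert set(chosen) == set(top5)

    def test_random_mode_seed_determinism(self, clustered):
        X, labels, S = clustered
        pool = np.arange(1, 21)
        spec = CombinationSpec(training_selection="random", M_percent=50, k=5, seed=3)
        c1 = select_training(pool, 0, spec)
        c2 = select_training(pool, 0, spec)
        assert np.array_equal(c1, c2)
        assert len(c1) == 10

    def test_small_M_floors_at_k_with_warning(self, clustered):
        X, labels, S = clustered
        pool = np.arange(1, 21)
        spec = CombinationSpec(training_selection="random", M_percent=2, k=5)
        with pytest.warns(UserWarning, match="flooring"):
            chosen = select_training(pool, 0, spec)
        assert len(chosen) == 5

    def test_pool_smaller_than_k_rejected(self):
        spec = CombinationSpec(k=10)
        with pytest.raises(ValueError, match="smaller than k"):
            select_training(np.arange(5), 99, spec)


class TestKnnPredict:
    def test_majority_vote_fractions(self, clustered):
        X, labels, S = clustered
        spec = CombinationSpec(neighbor_metric="euclidean", k=3)
        training = np.array([8, 9, 24])  # two 'b', one 'd'
        probs, label = knn_predict(0, training, spec, labels, X=X,
                                   classes=("a", "b", "c", "d"))
        assert label == "b"
        assert probs.tolist() == [0.0, 2 / 3, 0.0, 1 / 3]

    def test_exact_duplicate_dominates_k1(self, clustered):
        X, labels, S = clustered
        Xdup = np.vstack([X, X[0]])
        labdup = np.append(labels, labels[0])
        spec = CombinationSpec(neighbor_metric="euclidean", k=1)
        probs, label = knn_predict(32, np.arange(32), spec, labdup, X=Xdup)
        assert label == labels[0]
        assert probs.max() == 1.0

    def test_learned_metric_uses_similarity_row(self, clustered):
        X, labels, S = clustered
        spec = CombinationSpec(neighbor_metric="learned", k=8)
        probs, label = knn_predict(0, np.arange(1, 32), spec, labels, S=S)
        assert label == "a"  # cluster mates are the most similar

    def test_probabilities_sum_to_one(self, clustered):
        X, labels, S = clustered
        spec = CombinationSpec(neighbor_metric="euclidean", k=10)
        probs, _ = knn_predict(0, np.arange(1, 32), spec, labels, X=X)
        assert probs.sum() == pytest.approx(1.0)


def auc_concordant_pairs(scores, labels):
    """Exhaustive Mann-Whitney count: concordant pairs + half ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p, q in itertools.product(pos, neg):
        total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestMetrics:
    def test_binary_auc_hand_example(self):
        scores = np.array([0.9, 0.8, 0.4, 0.3])
        labels = np.array([1, 0, 1, 0])
        assert micro_auc(scores, labels) == pytest.approx(0.75)
        assert micro_auc(scores, labels) == pytest.approx(
            auc_concordant_pairs(scores, labels))

    def test_all_ties_gives_half(self):
        assert micro_auc(np.full(6, 0.5), np.array([1, 0, 1, 0, 1, 0])) == \
            pytest.approx(0.5)

    def test_perfect_one_hot_multiclass(self):
        labels = np.array(["a", "b", "c", "a"])
        proba = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
        assert micro_auc(proba, labels, classes=("a", "b", "c")) == 1.0

    def test_micro_auc_matches_pooled_pair_oracle(self, rng):
        """Micro AUC == concordant-pair count over the pooled one-vs-rest
        (label, score) pairs, on random inputs of <= 50 samples."""
        classes = ("a", "b", "c")
        labels = rng.choice(classes, size=40)
        proba = rng.random((40, 3))
        proba /= proba.sum(axis=1, keepdims=True)
        pooled_scores, pooled_labels = [], []
        for j, c in enumerate(classes):
            pooled_scores += proba[:, j].tolist()
            pooled_labels += [1 if l == c else 0 for l in labels]
        assert micro_auc(proba, labels, classes=classes) == pytest.approx(
            auc_concordant_pairs(pooled_scores, pooled_labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            micro_auc(np.array([0.1, 0.9]), np.array([1, 1]))

    @pytest.mark.parametrize("pred,true,expected", [
        (["a", "b", "c", "d"], ["a", "b", "c", "d"], 1.0),
        (["a", "b", "c", "a"], ["a", "b", "c", "d"], 0.75),
        (["b", "a", "a", "a"], ["a", "b", "c", "d"], 0.0),
    ])
    def test_micro_f1_equals_accuracy(self, pred, true, expected):
        assert f1_score(pred, true) == pytest.approx(expected)

    def test_f1_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            f1_score(["a"], ["a", "b"])

    def test_ce_loss_values(self):
        proba = np.array([[1.0, 0.0], [0.5, 0.5]])
        labels = np.array(["x", "x"])
        assert ce_loss(proba, labels, classes=("x", "y")) == \
            pytest.approx(-np.log(0.5) / 2)
        assert ce_loss(np.array([[1.0, 0.0]]), np.array(["x"]),
                       classes=("x", "y")) == 0.0
        zero = ce_loss(np.array([[0.0, 1.0]]), np.array(["x"]), classes=("x", "y"))
        assert zero == pytest.approx(-np.log(1e-15))


class TestLooEvaluate:
    def test_round_count_and_shapes(self, clustered):
        X, labels, S = clustered
        spec = CombinationSpec.from_name("R+E", M_percent=100, k=5)
        run = loo_evaluate(labels, spec, S=S, X=X)
        assert run.proba.shape == (32, 4)
        assert np.allclose(run.proba.sum(axis=1), 1.0)

    def test_perfectly_separable_clusters(self, clustered):
        X, labels, S = clustered
        for name in ("R+E", "R+L"):
            spec = CombinationSpec.from_name(name, M_percent=100, k=5)
            run = loo_evaluate(labels, spec, S=S, X=X)
            assert run.auc == 1.0
            assert run.f1 == 1.0

    def test_determinism(self, clustered):
        X, labels, S = clustered
        spec = CombinationSpec.from_name("R+L", M_percent=40, k=5, seed=2)
        r1 = loo_evaluate(labels, spec, S=S, X=X)
        r2 = loo_evaluate(labels, spec, S=S, X=X)
        assert np.array_equal(r1.proba, r2.proba)
        assert np.array_equal(r1.pred_labels, r2.pred_labels)

    def test_cohort_too_small_rejected(self, clustered):
        X, labels, S = clustered
        spec = CombinationSpec(k=10)
        with pytest.raises(ValueError):
            loo_evaluate(labels[:8], spec, S=S[:8, :8], X=X[:8])


class TestCombinationGrid:
    def test_grid_shape(self, clustered):
        X, labels, S = clustered
        results, runs = run_combination_grid(labels, ["R+L", "R+E"], [50, 100],
                                             k=5, S=S, X=X)
        assert len(results) == 4
        assert set(results["combination"]) == {"R+L", "R+E"}

    def test_full_pool_equivalences(self, clustered):
        """At M = 100% training selection is vacuous: R+L == E+L and
        R+E == L+E prediction-for-prediction."""
        X, labels, S = clustered
        _, runs = run_combination_grid(labels, ["R+L", "E+L", "R+E", "L+E"],
                                       [100], k=5, S=S, X=X)
        assert np.array_equal(runs[("R+L", 100)].proba, runs[("E+L", 100)].proba)
        assert np.array_equal(runs[("R+L", 100)].pred_labels,
                              runs[("E+L", 100)].pred_labels)
        assert np.array_equal(runs[("R+E", 100)].proba, runs[("L+E", 100)].proba)
        assert np.array_equal(runs[("R+E", 100)].pred_labels,
                              runs[("L+E", 100)].pred_labels)

    def test_preset_names(self):
        spec = CombinationSpec.from_name("E+L")
        assert spec.training_selection == "euclidean"
        assert spec.neighbor_metric == "learned"
        assert spec.name == "E+L"
        with pytest.raises(ValueError):
            CombinationSpec.from_name("X+Y")

    def test_default_k_is_ten(self):
        assert CombinationSpec().k == 10
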