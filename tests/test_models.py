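"""Classifier families: contracts, closed forms, brute-force oracles."""

import random

import numpy as np
import pytest

from carestrat.models import (
    LogisticConfig,
    nb_log_joint,
    nb_predict,
    train_linear_svm,
    train_logistic,
    train_majority,
    train_naive_bayes,
)

from .oracles import nb_log_joint_brute, svm_grid_search, svm_primal_objective


class TestMajority:
    def test_predicts_modal_label(self):
        model = train_majority(["A", "A", "B"])
        assert model.predict([1, 2, 3]) == ["A", "A", "A"]

    def test_tie_breaks_lexicographically(self):
        assert train_majority(["B", "A"]).stored_label == "A"

    def test_empty_labels_raise(self):
        with pytest.raises(ValueError):
            train_majority([])


class TestNaiveBayes:
    def test_hand_enumerated_example(self):
        # A: "fun fun", "fun good"; B: "bad bad"; test "fun" -> A
        docs = [["fun", "fun"], ["fun", "good"], ["bad", "bad"]]
        labels = ["A", "A", "B"]
        model = train_naive_bayes(docs, labels)
        assert nb_predict(model, ["fun"]) == "A"
        # smoothed likelihood check: P(fun|A) = (3+1)/(4+3)
        i = model.vocabulary["fun"]
        k = model.classes.index("A")
        assert np.exp(model.log_likelihoods[k, i]) == pytest.approx(4 / 7)

    def test_all_unknown_tokens_fall_back_to_prior(self):
        docs = [["x"], ["x"], ["y"]]
        model = train_naive_bayes(docs, ["A", "A", "B"])
        assert nb_predict(model, ["unseen", "words"]) == "A"

    def test_likelihoods_normalize_per_class(self):
        rng = random.Random(0)
        docs = [[rng.choice("abcd") for _ in range(5)] for _ in range(20)]
        labels = [rng.choice("XY") for _ in range(20)]
        if len(set(labels)) < 2:
            labels[0] = "X" if labels[0] == "Y" else "Y"
        model = train_naive_bayes(docs, labels)
        sums = np.exp(model.log_likelihoods).sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_posteriors_match_brute_force_on_random_corpora(self):
        rng = random.Random(1)
        for _ in range(50):
            n_docs = rng.randint(3, 6)
            docs = [
                [rng.choice(["w1", "w2", "w3", "w4"]) for _ in range(rng.randint(1, 4))]
                for _ in range(n_docs)
            ]
            labels = [rng.choice(["A", "B", "C"][: rng.randint(2, 3)]) for _ in range(n_docs)]
            if len(set(labels)) < 2:
                labels[0] = "A" if labels[0] != "A" else "B"
            test = [rng.choice(["w1", "w2", "w9"]) for _ in range(3)]
            model = train_naive_bayes(docs, labels)
            classes, expected = nb_log_joint_brute(docs, labels, test)
            assert classes == model.classes
            assert np.allclose(nb_log_joint(model, test), expected, atol=1e-9)

    def test_single_class_training_raises(self):
        with pytest.raises(ValueError):
            train_naive_bayes([["a"], ["b"]], ["A", "A"])


class TestLogistic:
    def test_separable_clusters_reach_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal((-3, -3), 0.3, (20, 2)), rng.normal((3, 3), 0.3, (20, 2))])
        y = ["neg"] * 20 + ["pos"] * 20
        model = train_logistic(X, y, LogisticConfig(l2_strength=0.0, seed=0))
        assert model.predict(X) == y

    def test_symmetric_data_puts_threshold_at_zero(self):
        X = np.array([[-1.0], [1.0]])
        model = train_logistic(X, ["a", "b"], LogisticConfig(l2_strength=0.0, seed=0))
        dw = model.weights[1, 0] - model.weights[0, 0]
        db = model.bias[1] - model.bias[0]
        threshold = -db / dw
        assert abs(threshold) < 0.05
        assert dw > 0  # class "b" on the positive side

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 4))
        y = [str(i % 3) for i in range(30)]
        model = train_logistic(X, y, LogisticConfig(max_epochs=5))
        proba = model.predict_proba(rng.normal(size=(10, 4)))
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_non_finite_features_raise(self):
        with pytest.raises(ValueError):
            train_logistic(np.array([[np.nan], [1.0]]), ["a", "b"])

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 3))
        y = [str(i % 2) for i in range(40)]
        m1 = train_logistic(X, y, LogisticConfig(seed=5))
        m2 = train_logistic(X, y, LogisticConfig(seed=5))
        assert np.array_equal(m1.weights, m2.weights)


class TestLinearSvm:
    def test_symmetric_pair_threshold_zero_margin_two(self):
        X = np.array([[-1.0], [1.0]])
        model = train_linear_svm(X, ["neg", "pos"], C=1e4)
        w = model.weights[0, 0]
        b = model.bias[0]
        assert abs(b / w) < 1e-2  # threshold at 0
        assert 2.0 / abs(w) == pytest.approx(2.0, abs=1e-2)  # geometric margin

    def test_separable_data_zero_training_errors(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(-2, 0.2, (15, 2)), rng.normal(2, 0.2, (15, 2))])
        y = ["a"] * 15 + ["b"] * 15
        model = train_linear_svm(X, y, C=100.0)
        assert model.predict(X) == y

    def test_objective_close_to_grid_search_optimum(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0])
        y = np.array([-1.0, -1.0, 1.0, 1.0])
        labels = ["n", "n", "p", "p"]
        model = train_linear_svm(x[:, None], labels, C=1.0)
        ours = svm_primal_objective(model.weights[0, 0], model.bias[0], x, y, C=1.0)
        grid_obj, _, _ = svm_grid_search(x, y, C=1.0)
        assert ours <= grid_obj + 1e-3

    def test_multiclass_predicts_only_training_labels(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 2)) + np.repeat(np.eye(3) * 4, 10, axis=0)[:, :2]
        y = [lab for lab in ("a", "b", "c") for _ in range(10)]
        model = train_linear_svm(X, y)
        assert set(model.predict(rng.normal(size=(50, 2)))) <= {"a", "b", "c"}

    def test_deterministic_predictions_across_refits(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 3))
        y = [str(i % 2) for i in range(40)]
        p1 = train_linear_svm(X, y).predict(X)
        p2 = train_linear_svm(X, y).predict(X)
        assert p1 == p2

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            train_linear_svm(np.zeros((3, 1)), ["a", "a", "a"])
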