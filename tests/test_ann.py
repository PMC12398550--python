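"""Binarized feature space, network forward/backward, folds, votes, metrics."""

import numpy as np
import pytest

from oligomap import ann
from oligomap.ann import (
    ANNConfig,
    ANNModel,
    TrainingConfig,
    balanced_batches,
    binarize,
    build_feature_space,
    ensemble_predict,
    evaluate,
    forward,
    gradients,
    init_model,
    loss,
    one_hot,
    stratified_folds,
    train_ann,
    train_ensemble,
)
from oligomap.errors import ValidationError

from .conftest import make_count_matrix


class TestFeatureSpace:
    def test_union(self):
        assert build_feature_space(["A", "B", "C"], ["B", "C", "D"]) == ["A", "B", "C", "D"]

    def test_identical_lists_keep_length(self):
        assert len(build_feature_space(["X", "Y"], ["Y", "X"])) == 2

    def test_empty_union_rejected(self):
        with pytest.raises(ValidationError):
            build_feature_space([], [])

    def test_binarize_detection_rule(self):
        m = make_count_matrix(np.array([[0], [1], [57]]), gene_ids=["A", "B", "C"])
        X = binarize(m, ["A", "B", "C"])
        assert X.tolist() == [[0.0, 1.0, 1.0]]

    def test_missing_feature_gives_zero_column(self):
        m = make_count_matrix(np.array([[3]]), gene_ids=["A"])
        X = binarize(m, ["A", "Z"])
        assert X.tolist() == [[1.0, 0.0]]

    def test_binarize_idempotent(self, reference):
        m, _, _ = reference
        fs = list(m.gene_ids[:50])
        X = binarize(m, fs)
        rebin = (X > 0).astype(float)
        assert np.array_equal(X, rebin)


class TestFolds:
    def test_even_split(self):
        folds = stratified_folds(["a"] * 10, 5, seed=0)
        assert np.bincount(folds).tolist() == [2, 2, 2, 2, 2]

    def test_class_proportions_within_one(self):
        labels = ["a"] * 25 + ["b"] * 13
        folds = stratified_folds(labels, 5, seed=1)
        labels = np.asarray(labels, dtype=object)
        for c, total in (("a", 25), ("b", 13)):
            per_fold = [np.sum((labels == c) & (folds == i)) for i in range(5)]
            assert max(per_fold) - min(per_fold) <= 1

    def test_deterministic(self):
        labels = ["a", "b"] * 20
        assert np.array_equal(
            stratified_folds(labels, 4, seed=9), stratified_folds(labels, 4, seed=9)
        )

    def test_small_class_named_in_error(self):
        with pytest.raises(ValidationError, match="tiny"):
            stratified_folds(["big"] * 10 + ["tiny"] * 2, 5)


class TestBalancedBatches:
    def test_exact_composition(self):
        X = np.arange(40, dtype=float).reshape(40, 1)
        labels = ["a"] * 30 + ["b"] * 6 + ["c"] * 2 + ["d"] * 2  # heavily imbalanced
        gen = balanced_batches(X, labels, ["a", "b", "c", "d"], 16, np.random.default_rng(0))
        Xb, Yb = next(gen)
        assert Xb.shape == (64, 1)
        assert Yb.sum(axis=0).tolist() == [16.0, 16.0, 16.0, 16.0]

    def test_per_class_one(self):
        X = np.zeros((4, 1))
        gen = balanced_batches(X, ["a", "a", "b", "b"], ["a", "b"], 1, np.random.default_rng(0))
        Xb, Yb = next(gen)
        assert Xb.shape[0] == 2 and Yb.sum(axis=0).tolist() == [1.0, 1.0]

    def test_equalises_imbalanced_frequencies(self):
        """90:10 imbalance in the data still yields 50:50 sampled label frequency."""
        X = np.zeros((100, 1))
        labels = ["a"] * 90 + ["b"] * 10
        gen = balanced_batches(X, labels, ["a", "b"], 8, np.random.default_rng(2))
        freq_b = np.mean([next(gen)[1].sum(axis=0)[1] / 16 for _ in range(500)])
        assert freq_b == pytest.approx(0.5, abs=0.01)

    def test_absent_class_rejected(self):
        with pytest.raises(ValidationError):
            next(balanced_batches(np.zeros((2, 1)), ["a", "a"], ["a", "b"], 2,
                                  np.random.default_rng(0)))


def random_model(F=50, K=4, seed=0):
    rng = np.random.default_rng(seed)
    model = init_model(F, ANNConfig(hidden1=8, hidden2=6, l1_lambda=0.001), list(range(K)), rng)
    # perturb biases so ReLU kinks are off the gradient-check points
    model.b1 = rng.normal(0, 0.3, size=model.b1.shape)
    model.b2 = rng.normal(0, 0.3, size=model.b2.shape)
    model.b3 = rng.normal(0, 0.3, size=model.b3.shape)
    return model


class TestForwardAndLoss:
    def test_zero_network_gives_uniform_probabilities(self):
        model = ANNModel(
            W1=np.zeros((10, 4)), b1=np.zeros(4), W2=np.zeros((4, 3)), b2=np.zeros(3),
            W3=np.zeros((3, 5)), b3=np.zeros(5), classes=list("abcde"), l1_lambda=0.0,
        )
        P = forward(model, np.ones((7, 10)))
        assert np.allclose(P, 0.2)

    def test_rows_sum_to_one(self):
        model = random_model()
        X = (np.random.default_rng(1).random((20, 50)) > 0.5).astype(float)
        P = forward(model, X)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_uniform_prediction_loss_is_log_k(self):
        model = ANNModel(
            W1=np.zeros((6, 4)), b1=np.zeros(4), W2=np.zeros((4, 3)), b2=np.zeros(3),
            W3=np.zeros((3, 4)), b3=np.zeros(4), classes=list("abcd"), l1_lambda=0.0,
        )
        Y = one_hot(["a", "b"], list("abcd"))
        assert loss(model, np.ones((2, 6)), Y) == pytest.approx(np.log(4))

    def test_l1_penalty_scales_linearly(self):
        model = random_model()
        X = (np.random.default_rng(2).random((10, 50)) > 0.5).astype(float)
        Y = one_hot([0] * 10, list(range(4)))
        base = loss(model, X, Y)
        model2 = random_model()
        model2.l1_lambda *= 2
        penalty = np.abs(model.W1).sum() + np.abs(model.W2).sum()
        assert loss(model2, X, Y) - base == pytest.approx(model.l1_lambda * penalty, rel=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            forward(random_model(), np.zeros((2, 49)))

    def test_gradient_matches_finite_differences(self):
        """Analytic backprop equals central finite differences at F=50, K=4."""
        model = random_model(seed=3)
        rng = np.random.default_rng(4)
        X = (rng.random((12, 50)) > 0.5).astype(float)
        Y = one_hot(rng.integers(0, 4, size=12).tolist(), list(range(4)))
        grads = gradients(model, X, Y)
        eps = 1e-6
        rng2 = np.random.default_rng(5)
        for p, g in zip(model.params(), grads):
            flat = p.ravel()
            for idx in rng2.choice(flat.size, size=min(20, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss(model, X, Y)
                flat[idx] = orig - eps
                dn = loss(model, X, Y)
                flat[idx] = orig
                assert g.ravel()[idx] == pytest.approx((up - dn) / (2 * eps), abs=1e-5)


class TestTraining:
    @staticmethod
    def separable_data(n=120, F=20, seed=0):
        """Two classes with disjoint deterministic detection blocks."""
        rng = np.random.default_rng(seed)
        y = np.array(["a", "b"] * (n // 2), dtype=object)
        X = (rng.random((n, F)) > 0.9).astype(float)
        X[y == "a", :5] = 1.0
        X[y == "b", 5:10] = 1.0
        X[y == "a", 5:10] = 0.0
        X[y == "b", :5] = 0.0
        return X, y

    def test_loss_decreases_early(self):
        X, y = self.separable_data()
        cfg = TrainingConfig(epochs=5, steps_per_epoch=16, seed=0)
        model = train_ann(X[:100], y[:100], X[100:], y[100:], ANNConfig(), cfg)
        losses = model.history["train_loss"]
        drops = sum(b < a for a, b in zip(losses, losses[1:]))
        assert drops >= len(losses) - 2

    def test_separable_problem_learned(self):
        X, y = self.separable_data()
        cfg = TrainingConfig(epochs=30, steps_per_epoch=16, seed=1)
        model = train_ann(X[:100], y[:100], X[100:], y[100:], ANNConfig(), cfg)
        assert model.history["val_balanced_accuracy"][-1] >= 0.99

    def test_training_is_deterministic(self):
        X, y = self.separable_data()
        cfg = TrainingConfig(epochs=3, steps_per_epoch=8, seed=5)
        m1 = train_ann(X[:100], y[:100], X[100:], y[100:], ANNConfig(), cfg)
        m2 = train_ann(X[:100], y[:100], X[100:], y[100:], ANNConfig(), cfg)
        for a, b in zip(m1.params(), m2.params()):
            assert np.array_equal(a, b)

    def test_ensemble_validates_each_fold_once(self):
        X, y = self.separable_data(n=150)
        cfg = TrainingConfig(n_folds=5, epochs=3, steps_per_epoch=8, seed=2)
        models, metrics = train_ensemble(X, y, ANNConfig(), cfg)
        assert len(models) == 5
        assert sorted(metrics["fold"]) == [0, 1, 2, 3, 4]

    def test_three_fold_variant_supported(self):
        X, y = self.separable_data(n=90)
        cfg = TrainingConfig(n_folds=3, epochs=2, steps_per_epoch=8, seed=2)
        models, metrics = train_ensemble(X, y, ANNConfig(), cfg)
        assert len(models) == 3 and len(metrics) == 3


class TestEnsemblePredict:
    @staticmethod
    def fixed_model(logits_row, classes):
        """A model whose output logits are constant: zero weights, b3 = logits."""
        F = 4
        return ANNModel(
            W1=np.zeros((F, 3)), b1=np.zeros(3), W2=np.zeros((3, 2)), b2=np.zeros(2),
            W3=np.zeros((2, len(classes))), b3=np.array(logits_row, dtype=float),
            classes=list(classes), l1_lambda=0.0,
        )

    def test_plurality_vote(self):
        classes = ["A", "B"]
        models = [self.fixed_model([1, 0], classes)] * 3 + [self.fixed_model([0, 1], classes)] * 2
        out = ensemble_predict(models, np.zeros((2, 4)))
        assert list(out["final_label"]) == ["A", "A"]
        assert not out["tie_broken"].any()
        assert (out["votes_A"] + out["votes_B"]).tolist() == [5, 5]

    def test_tie_broken_by_mean_probability(self):
        classes = ["A", "B", "C"]
        models = [
            self.fixed_model([2.0, 0.0, 1.0], classes),  # votes A
            self.fixed_model([0.0, 1.5, 1.0], classes),  # votes B
        ]
        out = ensemble_predict(models, np.zeros((1, 4)))
        assert out.loc[0, "tie_broken"]
        # mean softmax favours A (2.0 logit) over B (1.5 logit)
        assert out.loc[0, "final_label"] == "A"

    def test_single_model_equals_argmax(self):
        classes = ["A", "B"]
        model = self.fixed_model([0.0, 3.0], classes)
        out = ensemble_predict([model], np.zeros((3, 4)))
        assert list(out["final_label"]) == ["B"] * 3

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValidationError):
            ensemble_predict([], np.zeros((1, 4)))

    def test_confidence_threshold_off_by_default_but_can_reject(self):
        classes = ["A", "B"]
        model = self.fixed_model([0.1, 0.0], classes)  # low-confidence output
        default = ensemble_predict([model], np.zeros((2, 4)))
        assert "unassigned" not in set(default["final_label"])
        strict = ensemble_predict([model], np.zeros((2, 4)), confidence_threshold=0.9)
        assert set(strict["final_label"]) == {"unassigned"}


class TestEvaluate:
    def test_perfect_predictions(self):
        m = evaluate(["a", "b", "a"], ["a", "b", "a"])
        assert m["balanced_accuracy"] == 1.0
        assert m["macro_precision"] == 1.0 and m["macro_recall"] == 1.0

    def test_balanced_accuracy_is_mean_recall(self):
        true = ["a"] * 4 + ["b"] * 4
        pred = ["a"] * 4 + ["b", "b", "a", "a"]  # recalls 1.0 and 0.5
        assert evaluate(pred, true)["balanced_accuracy"] == pytest.approx(0.75)

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(8)
        classes = ["x", "y", "z"]
        true = rng.choice(classes, size=30)
        pred = rng.choice(classes, size=30)
        m = evaluate(pred, true, classes=classes)
        cm = np.zeros((3, 3), dtype=int)
        for t, p in zip(true, pred):
            cm[classes.index(t), classes.index(p)] += 1
        assert np.array_equal(m["confusion_matrix"].to_numpy(), cm)
        recalls = [cm[i, i] / cm[i].sum() for i in range(3) if cm[i].sum()]
        assert m["balanced_accuracy"] == pytest.approx(np.mean(recalls))
        precs = [cm[j, j] / cm[:, j].sum() if cm[:, j].sum() else 0.0 for j in range(3)]
        assert m["macro_precision"] == pytest.approx(np.mean(precs))

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            evaluate([], [])


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path):
        X, y = TestTraining.separable_data(n=60)
        cfg = TrainingConfig(n_folds=3, epochs=2, steps_per_epoch=4, seed=0)
        models, _ = train_ensemble(X, y, ANNConfig(), cfg)
        fs = [f"G{i}" for i in range(X.shape[1])]
        path = tmp_path / "ens.npz"
        ann.save_ensemble(models, fs, path)
        loaded, fs2 = ann.load_ensemble(path)
        assert fs2 == fs
        a = ensemble_predict(models, X)
        b = ensemble_predict(loaded, X)
        assert list(a["final_label"]) == list(b["final_label"])
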