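"""Feedforward gesture classifier: splits, training, evaluation, persistence."""

from dataclasses import replace

import numpy as np
import pytest

from semgband import (
    ConfusionReport,
    GestureClassifier,
    NetConfig,
    evaluate,
    load_network,
    run_experiment_grid,
    split_dataset,
)


@pytest.fixture(scope="module")
def blobs():
    """Two well-separated Gaussian blobs: a linearly separable toy problem."""
    rng = np.random.default_rng(7)
    X = np.vstack([rng.normal(-5, 1, size=(10, 2)), rng.normal(5, 1, size=(10, 2))])
    y = np.repeat([0, 1], 10)
    return X, y


class TestSplit:
    def test_balanced_540_split(self):
        y = np.repeat(np.arange(6), 90)
        parts = split_dataset(y, NetConfig(seed=0))
        assert len(parts["train"]) == 378
        assert len(parts["validation"]) == 81
        assert len(parts["test"]) == 81
        joined = np.concatenate([parts["train"], parts["validation"], parts["test"]])
        assert np.array_equal(np.sort(joined), np.arange(540))
        for name in ("validation", "test"):
            counts = np.bincount(y[parts[name]], minlength=6)
            assert counts.min() >= 13 and counts.max() <= 14  # stratified

    def test_seed_reproducibility(self):
        y = np.repeat(np.arange(6), 90)
        a = split_dataset(y, NetConfig(seed=3))
        b = split_dataset(y, NetConfig(seed=3))
        for name in a:
            assert np.array_equal(a[name], b[name])

    def test_class_too_small_to_stratify(self):
        y = np.array([0, 0, 0, 0, 1])  # one instance of class 1
        with pytest.raises(ValueError, match="stratify"):
            split_dataset(y, NetConfig(seed=0))

    def test_train_only_split_rejects_patience_stopping(self, blobs):
        X, y = blobs
        cfg = NetConfig(split_fractions=(1.0, 0.0, 0.0), seed=0)
        with pytest.raises(ValueError, match="validation"):
            GestureClassifier(X, y, cfg).fit()

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            NetConfig(split_fractions=(0.7, 0.2, 0.2))


class TestTraining:
    def test_separable_toy_reaches_full_training_accuracy(self, blobs):
        X, y = blobs
        cfg = NetConfig(hidden_size=8, max_epochs=200, patience=50, batch_size=4,
                        learning_rate=0.01, seed=0)
        res = GestureClassifier(X, y, cfg).fit()
        assert res.accuracy("train") == 1.0
        assert res.epochs_run <= 200

    def test_softmax_probabilities_sum_to_one(self, small_avg_dataset):
        cfg = NetConfig(hidden_size=13, max_epochs=20, seed=0)
        res = GestureClassifier.from_dataset(small_avg_dataset, cfg).fit()
        proba = res.predict_proba(small_avg_dataset.X[:25])
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_fit_deterministic_given_seed(self, small_avg_dataset):
        cfg = NetConfig(hidden_size=13, max_epochs=40, seed=1)
        r1 = GestureClassifier.from_dataset(small_avg_dataset, cfg).fit()
        r2 = GestureClassifier.from_dataset(small_avg_dataset, cfg).fit()
        assert r1.epochs_run == r2.epochs_run
        assert all(np.array_equal(a, b) for a, b in zip(r1._clf.coefs_, r2._clf.coefs_))
        for name in r1.reports:
            assert np.array_equal(r1.reports[name].confusion, r2.reports[name].confusion)

    def test_summary_mentions_partitions(self, small_avg_dataset):
        cfg = NetConfig(hidden_size=13, max_epochs=20, seed=0)
        res = GestureClassifier.from_dataset(small_avg_dataset, cfg).fit()
        text = res.summary()
        for word in ("train", "validation", "test", "accuracy"):
            assert word in text

    def test_save_load_round_trip(self, tmp_path, small_avg_dataset):
        cfg = NetConfig(hidden_size=13, max_epochs=30, seed=0)
        res = GestureClassifier.from_dataset(small_avg_dataset, cfg).fit()
        path = res.save(tmp_path / "net.json")
        net = load_network(path)
        X = small_avg_dataset.X[:20]
        assert np.array_equal(net.predict(X), res.predict(X))
        assert np.allclose(net.predict_proba(X), res.predict_proba(X), atol=1e-9)


class TestEvaluation:
    def test_constant_predictor_closed_form(self):
        y = np.repeat(np.arange(6), 90)
        parts = {"train": np.arange(540), "validation": np.array([], dtype=int),
                 "test": np.array([], dtype=int)}
        reports = evaluate(lambda X: np.ones(len(X), dtype=int), np.zeros((540, 1)), y,
                           parts, 6)
        rep = reports["train"]
        assert rep.accuracy == pytest.approx(1 / 6)
        assert rep.sensitivity[1] == 1.0
        assert np.all(rep.sensitivity[[0, 2, 3, 4, 5]] == 0.0)
        assert rep.precision[1] == pytest.approx(1 / 6)

    def test_hand_computed_three_class_confusion(self):
        y_true = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        y_pred = np.array([0, 1, 0, 1, 1, 2, 2, 2, 0])
        rep = ConfusionReport.from_predictions(y_true, y_pred, 3, "test")
        assert rep.confusion.tolist() == [[2, 1, 0], [0, 2, 1], [1, 0, 2]]
        assert rep.accuracy == pytest.approx(6 / 9)
        assert np.allclose(rep.sensitivity, [2 / 3, 2 / 3, 2 / 3])
        assert np.allclose(rep.precision, [2 / 3, 2 / 3, 2 / 3])

    def test_report_internal_consistency_random(self, rng):
        y_true = rng.integers(0, 6, size=300)
        y_pred = rng.integers(0, 6, size=300)
        rep = ConfusionReport.from_predictions(y_true, y_pred, 6, "x")
        cm = rep.confusion
        assert cm.sum() == 300
        assert rep.accuracy == pytest.approx(np.trace(cm) / cm.sum())
        row, col = cm.sum(axis=1), cm.sum(axis=0)
        for c in range(6):
            if row[c]:
                assert rep.sensitivity[c] == pytest.approx(cm[c, c] / row[c])
            if col[c]:
                assert rep.precision[c] == pytest.approx(cm[c, c] / col[c])


class TestGrid:
    def test_grid_structure_and_determinism(self, small_segments):
        cfg = NetConfig(max_epochs=30, seed=2)
        table, results = run_experiment_grid(small_segments, modes=("average",),
                                             hidden_sizes=(13, 17), config=cfg)
        assert len(table) == 2
        assert set(table["hidden"]) == {13, 17}
        for colname in ("train %", "validation %", "test %", "overall %", "epochs", "time_s"):
            assert table[colname].notna().all()
        table2, _ = run_experiment_grid(small_segments, modes=("average",),
                                        hidden_sizes=(13, 17), config=cfg)
        acc_cols = ["train %", "validation %", "test %", "overall %", "epochs"]
        assert table[acc_cols].equals(table2[acc_cols])
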