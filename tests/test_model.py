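"""Classifier construction, training, prediction and evaluation protocols."""

import dataclasses

import numpy as np
import pytest

from tripmine.encoder import build_table, encode_batch, encode_pair
from tripmine.model import (
    ARCHITECTURES,
    Metrics,
    ModelConfig,
    RelationClassifier,
    cross_validate,
    evaluate_predictions,
    imbalance_experiment,
    load_checkpoint,
    predict,
    save_checkpoint,
    stratified_folds,
    train,
)
from tripmine.pipeline import pair_vocabulary

SMALL = dict(hidden_units=12, fc_size=24, batch_size=16, epochs=25,
             learning_rate=0.5)


@pytest.fixture(scope="module")
def data(small_corpus):
    pairs = small_corpus["pairs"]
    table = build_table(pair_vocabulary(pairs), d_word=24, d_ent=6, seed=2)
    batch = encode_batch(pairs, table)
    labels = np.asarray([1 if p.label == "positive" else 0 for p in pairs])
    return pairs, table, batch, labels


class TestBuildClassifier:
    def test_bilstm_step_width_is_twice_hidden(self, data):
        _, table, _, _ = data
        clf = RelationClassifier(ModelConfig(hidden_units=100), table)
        assert clf.step_width == 200

    def test_fc_width_matches_config(self, data):
        _, table, _, _ = data
        clf = RelationClassifier(ModelConfig(fc_size=1000), table)
        assert clf.fc.params["W"].shape[1] == 1000

    def test_equal_seed_gives_identical_parameters(self, data):
        _, table, _, _ = data
        cfg = ModelConfig(seed=5, **SMALL)
        a, b = RelationClassifier(cfg, table), RelationClassifier(cfg, table)
        for la, lb in zip(a.layers, b.layers):
            for k in la.params:
                assert np.array_equal(la.params[k], lb.params[k]), k

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(architecture="transformer")
        with pytest.raises(ValueError):
            ModelConfig(threshold=1.0)
        with pytest.raises(ValueError):
            ModelConfig(batch_size=0)

    def test_architecture_swap_contract(self, data):
        """All five architectures consume the same input, same output shape."""
        _, table, batch, _ = data
        sub = dataclasses.replace
        from tripmine.model import _trim

        small = _trim(batch, np.arange(6))
        for arch in ARCHITECTURES:
            cfg = ModelConfig(architecture=arch, hidden_units=8, fc_size=12)
            clf = RelationClassifier(cfg, table)
            probs = clf.predict_batch(small)
            assert probs.shape == (6, 2)
            assert np.abs(probs.sum(axis=1) - 1).max() < 1e-6


class TestTrain:
    def test_memorizes_two_repeated_pairs(self, data):
        pairs, table, batch, labels = data
        pos = next(i for i, y in enumerate(labels) if y == 1)
        neg = next(i for i, y in enumerate(labels) if y == 0)
        rows = np.array([pos, neg] * 10)
        from tripmine.model import _trim

        sub = _trim(batch, rows)
        cfg = ModelConfig(seed=3, **SMALL)
        import copy

        clf = RelationClassifier(cfg, copy.deepcopy(table))
        train(clf, sub, labels[rows], cfg)
        probs = clf.predict_batch(sub)
        acc = ((probs[:, 1] >= 0.5).astype(int) == labels[rows]).mean()
        assert acc == 1.0

    def test_single_class_training_is_error(self, data):
        pairs, table, batch, labels = data
        from tripmine.model import _trim

        rows = np.nonzero(labels == 1)[0][:8]
        clf = RelationClassifier(ModelConfig(**SMALL), table)
        with pytest.raises(ValueError, match="both classes"):
            train(clf, _trim(batch, rows), labels[rows])

    def test_training_is_deterministic(self, data):
        import copy

        pairs, table, batch, labels = data
        from tripmine.model import _trim

        rows = np.concatenate([np.nonzero(labels == 1)[0][:20],
                               np.nonzero(labels == 0)[0][:20]])
        cfg = ModelConfig(seed=11, hidden_units=8, fc_size=12, batch_size=16,
                          epochs=3, learning_rate=0.3)
        hists = []
        for _ in range(2):
            clf = RelationClassifier(cfg, copy.deepcopy(table))
            hists.append(train(clf, _trim(batch, rows), labels[rows], cfg))
        assert hists[0] == hists[1]

    def test_loss_decreases_on_separable_data(self, data):
        import copy

        pairs, table, batch, labels = data
        cfg = ModelConfig(seed=1, **SMALL)
        clf = RelationClassifier(cfg, copy.deepcopy(table))
        hist = train(clf, batch, labels, cfg)
        assert hist[-1] < hist[0]


class TestPredict:
    def test_probabilities_sum_to_one(self, data):
        pairs, table, batch, _ = data
        clf = RelationClassifier(ModelConfig(hidden_units=8, fc_size=12), table)
        probs = clf.predict_batch(batch)
        assert np.abs(probs.sum(axis=1) - 1).max() < 1e-6

    def test_threshold_semantics(self):
        m = evaluate_predictions(np.array([1, 1]), np.array([0.49, 0.50]), 0.5)
        assert (m.tp, m.fn) == (1, 1)  # 0.49 is negative, 0.50 positive

    def test_single_matrix_matches_batch_prediction(self, data):
        pairs, table, batch, _ = data
        clf = RelationClassifier(ModelConfig(hidden_units=8, fc_size=12), table)
        probs = clf.predict_batch(batch)
        for i in (0, 5, 17):
            fm = encode_pair(pairs[i], table)
            p_neg, p_pos = predict(clf, fm)
            assert p_pos == pytest.approx(float(probs[i, 1]), abs=1e-5)

    def test_shape_mismatch_is_error(self, data):
        pairs, table, _, _ = data
        clf = RelationClassifier(ModelConfig(hidden_units=8, fc_size=12), table)
        fm = encode_pair(pairs[0], table, strategy="sequential")
        with pytest.raises(ValueError, match="rows"):
            predict(clf, fm)


class TestMetricsAndFolds:
    def test_f_measure_identity(self):
        m = Metrics.from_counts(tp=30, fp=10, fn=20, tn=40)
        p, r = 30 / 40, 30 / 50
        assert m.precision == pytest.approx(p)
        assert m.recall == pytest.approx(r)
        assert m.f_measure == pytest.approx(2 * p * r / (p + r))
        assert Metrics.from_counts(0, 0, 0, 5).f_measure == 0.0

    def test_confusion_counts_sum_to_n(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 57)
        s = rng.random(57)
        m = evaluate_predictions(y, s, 0.5)
        assert m.tp + m.fp + m.fn + m.tn == 57

    def test_stratified_folds_balanced_sizes(self):
        labels = np.array([0] * 500 + [1] * 500)
        folds = stratified_folds(labels, 10, seed=1)
        assert len(folds) == 10
        for f in folds:
            assert len(f) == 100
            assert (labels[f] == 1).sum() == 50

    def test_folds_disjoint_and_cover(self):
        labels = np.array([0] * 41 + [1] * 30)
        folds = stratified_folds(labels, 5, seed=2)
        per_class = [np.bincount(labels[f], minlength=2) for f in folds]
        for c in (0, 1):
            sizes = [pc[c] for pc in per_class]
            assert max(sizes) - min(sizes) <= 1
        all_idx = np.concatenate(folds)
        assert len(all_idx) == len(set(all_idx)) == 71

    def test_k_larger_than_class_count_is_error(self):
        labels = np.array([0] * 20 + [1] * 3)
        with pytest.raises(ValueError, match="class count"):
            stratified_folds(labels, 5, seed=0)

    def test_perfect_scores_give_mean_f_one(self):
        y = np.array([0, 1] * 20)
        m = evaluate_predictions(y, y.astype(float), 0.5)
        assert m.f_measure == 1.0


class TestProtocols:
    def test_cross_validate_reports_k_folds(self, data):
        pairs, table, _, _ = data
        cfg = ModelConfig(seed=0, hidden_units=8, fc_size=12, batch_size=32,
                          epochs=4, learning_rate=0.3)
        labels = np.asarray([1 if p.label == "positive" else 0 for p in pairs])
        subset = [pairs[i] for i in
                  np.concatenate([np.nonzero(labels == 1)[0][:30],
                                  np.nonzero(labels == 0)[0][:30]])]
        per_fold, mean = cross_validate(subset, cfg, table, k=3, seed=1)
        assert len(per_fold) == 3
        fs = [m.f_measure for m in per_fold]
        assert mean.f_measure == pytest.approx(float(np.mean(fs)))

    def test_imbalance_rejects_empty_class_and_oversize(self, data):
        pairs, table, _, labels = data
        pos = [p for p in pairs if p.label == "positive"]
        neg = [p for p in pairs if p.label == "negative"]
        cfg = ModelConfig(hidden_units=8, fc_size=12, epochs=1)
        with pytest.raises(ValueError, match="both classes"):
            imbalance_experiment(pos, neg, [(10, 0)], cfg, table, k=2)
        with pytest.raises(ValueError, match="exceeds"):
            imbalance_experiment(pos, neg, [(10 ** 6, 10)], cfg, table, k=2)


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, data, tmp_path):
        import copy

        pairs, table, batch, labels = data
        cfg = ModelConfig(seed=3, hidden_units=8, fc_size=12, batch_size=32,
                          epochs=2, learning_rate=0.3)
        clf = RelationClassifier(cfg, copy.deepcopy(table))
        train(clf, batch, labels, cfg)
        before = clf.predict_batch(batch)
        path = str(tmp_path / "model.npz")
        save_checkpoint(clf, path)
        loaded = load_checkpoint(path, expect_fingerprint=clf.table.fingerprint())
        assert np.allclose(loaded.predict_batch(batch), before)

    def test_refuses_mismatched_fingerprint(self, data, tmp_path):
        pairs, table, batch, labels = data
        cfg = ModelConfig(seed=3, hidden_units=8, fc_size=12, epochs=1)
        clf = RelationClassifier(cfg, table)
        path = str(tmp_path / "model.npz")
        save_checkpoint(clf, path)
        with pytest.raises(ValueError, match="encoder"):
            load_checkpoint(path, expect_fingerprint="deadbeef")
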