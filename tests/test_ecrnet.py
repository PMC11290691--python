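"""Contrastive classifier: momentum, memory bank, losses, training."""

import warnings

import numpy as np
import pytest

import cytoscreen as cs
from cytoscreen.ecrnet import (
    ContrastConfig,
    LabeledKey,
    MemoryBank,
    NoPositiveKeyError,
    classifier_loss,
    label_contrastive_loss,
    momentum_update,
    total_cls_loss,
)


def unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


class TestMomentumUpdate:
    def test_zero_momentum_copies_query(self):
        tq = np.array([1.0, 2.0, 3.0])
        assert np.array_equal(momentum_update(np.zeros(3), tq, 0.0), tq)

    def test_direct_substitution(self):
        assert momentum_update(np.array([1.0]), np.array([2.0]), 0.9)[0] == pytest.approx(1.1)

    def test_geometric_convergence_at_rate_m(self):
        m = 0.9
        tk = np.array([0.0])
        tq = np.array([1.0])
        for t in range(1, 40):
            tk = momentum_update(tk, tq, m)
            assert tk[0] == pytest.approx(1.0 - m**t, abs=1e-12)

    def test_shape_mismatch_and_bad_momentum_raise(self):
        with pytest.raises(ValueError):
            momentum_update(np.zeros(2), np.zeros(3), 0.5)
        with pytest.raises(ValueError):
            momentum_update(np.zeros(2), np.zeros(2), 1.0)


class TestMemoryBank:
    def test_fifo_eviction_keeps_last_in_order(self):
        bank = MemoryBank(capacity=4)
        keys = [LabeledKey(unit(np.eye(6)[i % 6] + 0.01), i % 2) for i in range(6)]
        bank.enqueue(keys)
        assert len(bank) == 4
        assert np.array_equal(bank.labels, [k.label for k in keys[2:]])
        assert np.allclose(bank.embeddings, np.stack([k.embedding for k in keys[2:]]))

    def test_empty_enqueue_is_noop(self):
        bank = MemoryBank(4)
        bank.enqueue([])
        assert len(bank) == 0

    def test_labels_stay_aligned_after_eviction(self):
        rng = np.random.default_rng(0)
        bank = MemoryBank(capacity=5)
        record = []
        for i in range(12):
            emb = unit(rng.normal(size=4))
            record.append((emb, i % 3))
            bank.enqueue([LabeledKey(emb, i % 3)])
        for slot, (emb, lab) in enumerate(record[-5:]):
            assert bank.labels[slot] == lab
            assert np.allclose(bank.embeddings[slot], emb)

    def test_non_normalized_key_warned_and_normalized(self):
        bank = MemoryBank(2)
        with pytest.warns(UserWarning):
            bank.enqueue([LabeledKey(np.array([3.0, 4.0]), 1)])
        assert np.linalg.norm(bank.embeddings[0]) == pytest.approx(1.0, abs=1e-9)


class TestLabelContrastiveLoss:
    def test_all_positive_bank_gives_zero(self):
        rng = np.random.default_rng(1)
        bank = MemoryBank(8).enqueue(
            [LabeledKey(unit(rng.normal(size=5)), 1) for _ in range(8)]
        )
        q = unit(rng.normal(size=5))
        assert label_contrastive_loss(q, 1, bank) == pytest.approx(0.0, abs=1e-12)

    def test_equal_similarities_give_log_ratio(self):
        # 4 keys equidistant from q, 2 sharing its label -> -log(2/4) = log 2
        q = np.array([1.0, 0.0, 0.0])
        embs = [unit([0.5, np.cos(a), np.sin(a)]) for a in (0, np.pi / 2, np.pi, -np.pi / 2)]
        bank = MemoryBank(4).enqueue(
            [LabeledKey(e, lab) for e, lab in zip(embs, [1, 1, 0, 0])]
        )
        got = label_contrastive_loss(unit(q), 1, bank)
        assert got == pytest.approx(np.log(2), abs=1e-9)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(2)
        cfg = ContrastConfig(tau=0.07)
        for _ in range(100):
            n = 16
            embs = [unit(rng.normal(size=8)) for _ in range(n)]
            labs = rng.integers(0, 2, size=n)
            labs[0] = 1  # guarantee a positive
            bank = MemoryBank(n).enqueue(
                [LabeledKey(e, l) for e, l in zip(embs, labs)]
            )
            q = unit(rng.normal(size=8))
            num = den = 0.0
            for e, l in zip(embs, labs):
                term = np.exp(np.dot(q, e) / cfg.tau)
                den += term
                if l == 1:
                    num += term
            assert label_contrastive_loss(q, 1, bank, cfg) == pytest.approx(
                -np.log(num / den), abs=1e-6
            )

    def test_no_positive_key_raises_skip_signal(self):
        bank = MemoryBank(2).enqueue([LabeledKey(unit([1.0, 1.0]), 0)])
        with pytest.raises(NoPositiveKeyError):
            label_contrastive_loss(unit([1.0, 0.0]), 1, bank)
        with pytest.raises(NoPositiveKeyError):
            label_contrastive_loss(unit([1.0, 0.0]), 1, MemoryBank(2))

    def test_loss_is_nonnegative(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            bank = MemoryBank(8).enqueue(
                [LabeledKey(unit(rng.normal(size=4)), int(l))
                 for l in rng.integers(0, 2, size=8)]
            )
            if not (bank.labels == 0).any():
                continue
            assert label_contrastive_loss(unit(rng.normal(size=4)), 0, bank) >= 0


class TestClassifierLoss:
    def test_perfect_one_hot_is_zero(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert classifier_loss(probs, [0, 1]) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_binary_is_log_two(self):
        probs = np.full((4, 2), 0.5)
        assert classifier_loss(probs, [0, 1, 0, 1]) == pytest.approx(np.log(2))

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            p = rng.random((8, 2))
            p /= p.sum(axis=1, keepdims=True)
            y = rng.integers(0, 2, size=8)
            want = -np.mean([np.log(p[i, y[i]]) for i in range(8)])
            assert classifier_loss(p, y) == pytest.approx(want, abs=1e-6)

    def test_zero_probability_clamped(self):
        assert np.isfinite(classifier_loss(np.array([[0.0, 1.0]]), [0]))


class TestTotalLoss:
    def test_combinations(self):
        assert total_cls_loss(0.3, 0.8, 0.5) == pytest.approx(0.7)
        assert total_cls_loss(0.3, 0.8, 0.0) == pytest.approx(0.3)

    def test_shipped_defaults(self):
        cfg = ContrastConfig()
        assert cfg.beta_loss == 0.5
        assert cfg.tau == 0.07
        assert cfg.m == 0.9


def tiny_rois(n=16, seed=0, size=32):
    rng = np.random.default_rng(seed)
    rois, labels = [], []
    for i in range(n):
        img = np.zeros((size, size, 3), np.uint8)
        r = 8 + int(rng.integers(0, 4))
        yy, xx = np.mgrid[:size, :size]
        blob = (yy - size // 2) ** 2 + (xx - size // 2) ** 2 < r * r
        img[blob] = 100 + int(rng.integers(0, 100))
        rois.append(img)
        labels.append("malignant" if i % 2 else "benign")
    return rois, labels


class TestTraining:
    def test_smoke_epoch_bookkeeping(self):
        rois, labels = tiny_rois()
        model = cs.ClumpClassifier(input_size=32, base_channels=4, embed_dim=8,
                                   n_stages=3, batch_size=4, bank_capacity=64, seed=0)
        res = model.fit(rois, labels, epochs=1, seed=0)
        assert np.isfinite(res.final_loss)
        assert len(model.bank) == min(len(rois), 64)
        assert "memory bank" in res.summary()

    def test_single_class_dataset_rejected(self):
        rois, _ = tiny_rois(8)
        model = cs.ClumpClassifier(input_size=32, n_stages=3)
        with pytest.raises(ValueError):
            model.fit(rois, ["benign"] * 8)

    def test_momentum_encoder_receives_no_gradient(self):
        rois, labels = tiny_rois(8)
        model = cs.ClumpClassifier(input_size=32, base_channels=4, embed_dim=8,
                                   n_stages=3, batch_size=4, bank_capacity=32, seed=1)
        model.fit(rois, labels, epochs=2, seed=1)
        assert all(p.grad is None for p in model.key_encoder.parameters())
        # and the key encoder lags the query encoder (EMA, not a copy)
        diffs = [np.abs(pk.data - pq.data).max()
                 for pk, pq in zip(model.key_encoder.parameters(),
                                   model.encoder.parameters())]
        assert max(diffs) > 0

    def test_bank_embeddings_stay_unit_norm(self):
        rois, labels = tiny_rois(12)
        model = cs.ClumpClassifier(input_size=32, base_channels=4, embed_dim=8,
                                   n_stages=3, batch_size=4, bank_capacity=16, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # any normalize warning would fail
            model.fit(rois, labels, epochs=2, seed=2)
        norms = np.linalg.norm(model.bank.embeddings, axis=1)
        assert np.abs(norms - 1.0).max() < 1e-6

    def test_same_seed_reproduces_final_loss(self):
        rois, labels = tiny_rois(8)
        losses = []
        for _ in range(2):
            model = cs.ClumpClassifier(input_size=32, base_channels=4, embed_dim=8,
                                       n_stages=3, batch_size=4, bank_capacity=16, seed=7)
            losses.append(model.fit(rois, labels, epochs=2, seed=7).final_loss)
        assert losses[0] == losses[1]


@pytest.fixture(scope="module")
def fitted():
    rois, labels = tiny_rois(8)
    model = cs.ClumpClassifier(input_size=32, base_channels=4, embed_dim=8,
                               n_stages=3, batch_size=4, bank_capacity=16, seed=3)
    model.fit(rois, labels, epochs=1, seed=3)
    return model


class TestClassify:

    def test_probabilities_sum_to_one(self, fitted):
        out = fitted.classify(np.zeros((32, 32, 3), np.uint8))
        assert out.probabilities.sum() == pytest.approx(1.0, abs=1e-6)

    def test_all_zero_canvas_is_valid_input(self, fitted):
        out = fitted.classify(np.zeros((32, 32, 3), np.uint8))
        assert out.label in ("benign", "malignant")

    def test_deterministic_given_fixed_weights(self, fitted):
        roi = tiny_rois(1, seed=9)[0][0]
        a = fitted.classify(roi)
        b = fitted.classify(roi)
        assert np.array_equal(a.probabilities, b.probabilities)
        assert a.label == b.label

    def test_tie_breaks_toward_malignant(self, fitted):
        fitted_clone = fitted
        orig = fitted_clone.predict_proba
        try:
            fitted_clone.predict_proba = lambda rois: np.array([[0.5, 0.5]])
            out = fitted_clone.classify(np.zeros((32, 32, 3), np.uint8))
            assert out.label == "malignant"
        finally:
            fitted_clone.predict_proba = orig

    def test_mismatched_canvas_warns_and_resizes(self, fitted):
        with pytest.warns(UserWarning):
            out = fitted.classify(np.zeros((48, 48, 3), np.uint8))
        assert out.probabilities.shape == (2,)

    def test_save_load_roundtrip(self, fitted, tmp_path):
        path = str(tmp_path / "cls")
        fitted.save(path)
        loaded = cs.ClumpClassifier.load(path)
        roi = tiny_rois(1, seed=11)[0][0]
        assert np.allclose(loaded.predict_proba([roi]),
                           fitted.predict_proba([roi]))
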