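import numpy as np
import pytest

from ststp.model import (ConfigError, Encoder, EncoderConfig, Hyperparams,
                         SequenceModel, conv_out_size, cross_entropy,
                         resnet152_encoder_config, softmax, threshold_gate,
                         train_model)


class TestConvArithmetic:
    def test_one_by_one_conv_preserves_geometry(self):
        assert conv_out_size(224, kernel=1, stride=1, padding=0) == 224

    def test_same_padding_preserves_size_for_odd_kernels(self):
        for u in (3, 5, 7):
            assert conv_out_size(64, kernel=u, stride=1, padding="same") == 64
        with pytest.raises(ConfigError):
            conv_out_size(64, kernel=4, stride=1, padding="same")

    def test_reduced_encoder_shape_table_matches_hand_computation(self):
        cfg = EncoderConfig(input_size=(32, 32, 3), layers=[
            ("conv", 6, 3, 2, "same"),   # (32+2-3)//2+1 = 16
            ("pool", 2, 2),              # (16-2)//2+1 = 8
            ("conv", 12, 3, 2, "same"),  # (8+2-3)//2+1 = 4
            ("conv", 12, 3, 1, 0),       # (4-3)//1+1 = 2
            ("conv", 16, 1, 1, 0),       # 2
            ("fc", 8), ("fc", 2)])
        assert cfg.shape_table() == [
            (16, 16, 6), (8, 8, 6), (4, 4, 12), (2, 2, 12), (2, 2, 16),
            (1, 1, 8), (1, 1, 2)]
        assert cfg.embedding_dim == 8

    def test_degenerate_layer_named_in_error(self):
        cfg = EncoderConfig(input_size=(8, 8, 3), layers=[
            ("conv", 4, 3, 2, 0), ("pool", 5, 2), ("fc", 4), ("fc", 2)])
        with pytest.raises(ConfigError, match="layer 1"):
            cfg.shape_table()

    def test_residual_schedule_parses(self):
        cfg = resnet152_encoder_config()
        assert sum(1 for l in cfg.layers if l[0] == "conv") == 151
        cfg.shape_table()  # must be geometrically consistent


class TestEncoderForward:
    def test_embedding_shape_and_determinism(self):
        enc = Encoder(seed=3)
        rng = np.random.default_rng(0)
        frames = rng.integers(0, 256, (5, 32, 32, 3), dtype=np.uint8)
        emb = enc.forward(frames)
        assert emb.shape == (5, 8)
        assert np.array_equal(emb, Encoder(seed=3).forward(frames))

    def test_input_size_mismatch_rejected(self):
        enc = Encoder(seed=0)
        with pytest.raises(ConfigError, match="resize"):
            enc.forward(np.zeros((2, 48, 48, 3)))


class TestSoftmaxAndLoss:
    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(1)
        p = softmax(rng.normal(0, 10, size=(40, 2)))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_cross_entropy_closed_forms(self):
        one_hot = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert cross_entropy(one_hot, [0, 1]) == pytest.approx(0.0)
        uniform = np.full((6, 2), 0.5)
        assert cross_entropy(uniform, [0, 1, 0, 1, 1, 0]) == pytest.approx(
            np.log(2.0))


class TestSequenceModel:
    def _model_and_data(self, seed=0, hidden=4, dropout=0.0):
        rng = np.random.default_rng(seed)
        hyper = Hyperparams(hidden=hidden, dropout=dropout, standardize=False)
        m = SequenceModel(3, hyper, seed=seed)
        seqs = [rng.normal(size=(rng.integers(3, 8), 3)) for _ in range(4)]
        return m, seqs, rng

    def test_zero_weight_head_gives_uniform_probabilities(self):
        m, seqs, _ = self._model_and_data()
        probs = m.predict_proba(seqs)
        assert np.allclose(probs, 0.5, atol=1e-12)

    def test_probabilities_normalised_for_any_input(self):
        m, seqs, rng = self._model_and_data(seed=2)
        m.params["head_W"] = rng.normal(0, 5, m.params["head_W"].shape)
        probs = m.predict_proba(seqs)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_bidirectional_output_is_order_sensitive(self):
        m, seqs, rng = self._model_and_data(seed=3)
        m.params["head_W"] = rng.normal(0, 1, m.params["head_W"].shape)
        seq = seqs[0]
        fwd = m.predict_proba([seq])
        rev = m.predict_proba([seq[::-1]])
        assert not np.allclose(fwd, rev, atol=1e-9)

    def test_feature_dimension_mismatch_rejected(self):
        m, _, rng = self._model_and_data()
        with pytest.raises(ConfigError, match="dimension"):
            m.predict_proba([rng.normal(size=(5, 7))])

    def test_bptt_gradients_match_finite_differences(self):
        m, seqs, rng = self._model_and_data(seed=4)
        m.params["head_W"] = rng.normal(0, 0.3, m.params["head_W"].shape)
        labels = np.array([0, 1, 1, 0])
        _, grads = m.loss_and_grads(seqs, labels)
        eps = 1e-6
        worst = 0.0
        for key, sub in m.params.items():
            arrays = sub.items() if isinstance(sub, dict) else [(None, sub)]
            for kk, arr in arrays:
                g = grads[key][kk] if kk else grads[key]
                flat_idx = np.linspace(0, arr.size - 1, 8).astype(int)
                for fi in flat_idx:
                    idx = np.unravel_index(fi, arr.shape)
                    orig = arr[idx]
                    arr[idx] = orig + eps
                    lp, _ = m.loss_and_grads(seqs, labels)
                    arr[idx] = orig - eps
                    lm, _ = m.loss_and_grads(seqs, labels)
                    arr[idx] = orig
                    num = (lp - lm) / (2 * eps)
                    worst = max(worst, abs(num - g[idx])
                                / max(1e-6, abs(num) + abs(g[idx])))
        assert worst < 1e-3

    def test_threshold_gate_zeroes_weak_features(self):
        X = np.zeros((1, 4, 3))
        X[0, :, 0] = 10.0
        X[0, :, 1] = 0.01
        X[0, :, 2] = 8.0
        mask = np.ones((1, 4))
        gated = threshold_gate(X, mask, factor=0.5)
        assert np.all(gated[0, :, 1] == 0.0)
        assert np.array_equal(gated[0, :, 0], X[0, :, 0])


class TestTraining:
    def _separable(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        seqs, labels = [], []
        for i in range(n):
            lab = i % 2
            s = rng.normal(size=(int(rng.integers(15, 30)), 6))
            s[:, 0] += 1.5 * lab
            seqs.append(s)
            labels.append(lab)
        return seqs, labels

    def test_overfits_separable_set_within_max_epochs(self):
        seqs, labels = self._separable()
        hyper = Hyperparams(hidden=16, max_epochs=64)
        model, trace = train_model(seqs, labels, hyper, seed=0)
        assert len(trace) == 64
        assert trace[-1] <= trace[0]
        assert (model.predict(seqs) == np.array(labels)).all()

    def test_loss_trace_non_increasing_with_small_lr(self):
        seqs, labels = self._separable(n=8, seed=1)
        hyper = Hyperparams(hidden=6, max_epochs=15, lr=0.005, dropout=0.0,
                            batch_size=8)
        _, trace = train_model(seqs, labels, hyper, seed=1)
        ratios = np.array(trace[1:]) / np.array(trace[:-1])
        assert np.all(ratios <= 1.05)

    def test_seed_determinism(self):
        seqs, labels = self._separable(n=10, seed=2)
        hyper = Hyperparams(hidden=8, max_epochs=5)
        _, t1 = train_model(seqs, labels, hyper, seed=7)
        _, t2 = train_model(seqs, labels, hyper, seed=7)
        assert np.array_equal(t1, t2)

    def test_single_class_dataset_rejected(self):
        seqs, _ = self._separable(n=4)
        with pytest.raises(ValueError, match="both classes"):
            train_model(seqs, [0, 0, 0, 0], Hyperparams(hidden=4), seed=0)

    def test_string_labels_accepted(self):
        seqs, labels = self._separable(n=6, seed=3)
        names = ["LIE" if l else "TRUTH" for l in labels]
        model, _ = train_model(seqs, names,
                               Hyperparams(hidden=4, max_epochs=2), seed=0)
        assert model.predict_proba(seqs).shape == (6, 2)
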