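"""Network core: convolution against a brute-force oracle, pooling, forward
contracts, loss values, gradient correctness, state round-trips."""

import dataclasses

import numpy as np
import pytest

from convdti import DTIModel, ModelConfig, bce_loss, elu, encode_sequence
from convdti.encoding import DEFAULT_VOCABULARY
from convdti.nn.layers import MaskedGlobalMaxPool, WindowConv1D


def brute_force_conv(x, w3):
    """Direct evaluation of (x*w)_j = sum_a sum_t w[a,t] x[a, j+t].

    x: (L, ES) input, w3: (ES, WS) single filter; returns length L-WS+1.
    """
    L, es = x.shape
    _, ws = w3.shape
    out = np.zeros(L - ws + 1)
    for j in range(L - ws + 1):
        for a in range(es):
            for t in range(ws):
                out[j] += w3[a, t] * x[j + t, a]
    return out


class TestELU:
    @pytest.mark.parametrize("x,alpha,expected", [
        (0.0, 1.0, 0.0),
        (2.0, 1.0, 2.0),
        (-1.0, 1.0, np.expm1(-1.0)),   # ~ -0.6321
        (-2.0, 0.5, 0.5 * np.expm1(-2.0)),
    ])
    def test_values(self, x, alpha, expected):
        assert elu(x, alpha) == pytest.approx(expected, abs=1e-12)

    def test_continuous_at_zero(self):
        eps = 1e-9
        assert abs(elu(eps) - elu(-eps)) < 1e-8


class TestConvolution:
    def test_toy_double_sum(self):
        # ES=2, WS=2: E rows are channels, w[a,t]; expected [2, 2] by hand
        x = np.array([[1.0, 0.0], [2.0, 1.0], [3.0, 0.0]])  # (L=3, ES=2)
        w3 = np.array([[1.0, 0.0], [0.0, 1.0]])  # (ES=2, WS=2)
        np.testing.assert_allclose(brute_force_conv(x, w3), [2.0, 2.0])
        rng = np.random.default_rng(0)
        conv = WindowConv1D(2, 2, 1, rng, "c", bias=False)
        conv.W.value[:, 0] = w3.reshape(-1)
        out = conv.forward(x[None])
        np.testing.assert_allclose(out[0, :, 0], [2.0, 2.0], atol=1e-12)

    def test_zero_filter(self, rng):
        conv = WindowConv1D(3, 4, 2, rng, "c", bias=False)
        conv.W.value[:] = 0.0
        out = conv.forward(rng.normal(size=(2, 10, 3)))
        assert np.all(out == 0)

    def test_identity_filter(self, rng):
        conv = WindowConv1D(1, 1, 1, rng, "c", bias=False)
        conv.W.value[:] = 1.0
        x = rng.normal(size=(1, 7, 1))
        np.testing.assert_allclose(conv.forward(x)[0, :, 0], x[0, :, 0])

    def test_oracle_equivalence_100_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            es = int(rng.integers(1, 9))
            ws = int(rng.integers(1, 7))
            L = int(rng.integers(ws, 51))
            x = rng.normal(size=(L, es))
            conv = WindowConv1D(es, ws, 1, rng, "c", bias=False)
            w3 = conv.W.value[:, 0].reshape(es, ws)
            got = conv.forward(x[None])[0, :, 0]
            np.testing.assert_allclose(got, brute_force_conv(x, w3), atol=1e-6)

    def test_window_exceeding_length_rejected(self, rng):
        conv = WindowConv1D(2, 8, 1, rng, "c")
        with pytest.raises(ValueError):
            conv.forward(rng.normal(size=(1, 5, 2)))


class TestGlobalMaxPool:
    def test_first_occurrence_tie_break(self):
        pool = MaskedGlobalMaxPool()
        conv = np.array([3.0, 7.0, 7.0, 1.0])[None, :, None]
        pooled, arg = pool.forward(conv, np.array([4]))
        assert pooled[0, 0] == 7.0
        assert arg[0, 0] == 1  # 0-based position of the first 7

    def test_masking_excludes_invalid_positions(self):
        pool = MaskedGlobalMaxPool()
        conv = np.array([5.0, 9.0])[None, :, None]
        pooled, arg = pool.forward(conv, np.array([1]))
        assert (pooled[0, 0], arg[0, 0]) == (5.0, 0)

    def test_empty_valid_set_flagged(self):
        pool = MaskedGlobalMaxPool()
        pooled, arg = pool.forward(np.ones((1, 3, 2)), np.array([0]))
        assert np.all(pooled == 0.0)
        assert np.all(arg == -1)

    def test_matches_brute_force_on_random_instances(self, rng):
        pool = MaskedGlobalMaxPool()
        for _ in range(50):
            L = int(rng.integers(1, 30))
            nv = int(rng.integers(1, L + 1))
            conv = rng.normal(size=(1, L, 1))
            pooled, arg = pool.forward(conv, np.array([nv]))
            assert pooled[0, 0] == conv[0, :nv, 0].max()
            assert arg[0, 0] == conv[0, :nv, 0].argmax()


class TestForward:
    def test_pooled_dimension_is_filters_times_windows(self):
        cfg = ModelConfig(window_sizes=(8, 16), filters_per_window=128,
                          embedding_size=8, mpl=60, fingerprint_bits=32,
                          protein_dense_sizes=(16,), drug_dense_sizes=(16,),
                          joint_dense_sizes=(8,), seed=0)
        model = DTIModel(cfg)
        enc = encode_sequence("MKVLAWTTYHHGGAARNDCQEGHILKMFPSTW", mpl=60)
        trace = model.forward(enc, np.zeros(32))
        total = sum(v.size for v in trace.pooled.values())
        assert total == 256 == cfg.n_pooled_features

    def test_probability_in_open_unit_interval(self, tiny_model, make_sequence):
        enc = encode_sequence(make_sequence(12), mpl=20)
        tr = tiny_model.forward(enc, np.ones(10))
        assert 0.0 < tr.probability < 1.0

    def test_argmax_positions_are_valid_window_starts(self, tiny_model, make_sequence):
        enc = encode_sequence(make_sequence(11), mpl=20)
        tr = tiny_model.forward(enc, np.zeros(10))
        for ws, starts in tr.argmax_start.items():
            valid = enc.window_mask(ws)
            assert all(int(s) in valid for s in starts)

    def test_padding_invariance_across_mpl(self, tiny_config, make_sequence):
        seq = make_sequence(12)
        fp = np.ones(10)
        probs = []
        for mpl in (12, 15, 20):
            model = DTIModel(dataclasses.replace(tiny_config, mpl=mpl))
            tr = model.forward(encode_sequence(seq, mpl=mpl), fp)
            probs.append(tr.probability)
        assert probs[0] == pytest.approx(probs[1], abs=1e-12)
        assert probs[0] == pytest.approx(probs[2], abs=1e-12)

    def test_translation_invariance_of_matched_filter(self, rng):
        # a filter equal to the motif's embedding pattern pools the same max
        # wherever the motif sits among valid positions
        cfg = ModelConfig(window_sizes=(4,), filters_per_window=1,
                          embedding_size=6, mpl=30, fingerprint_bits=4,
                          protein_dense_sizes=(4,), drug_dense_sizes=(4,),
                          joint_dense_sizes=(4,), conv_bias=False, seed=1)
        motif = "WYKD"
        vocab = DEFAULT_VOCABULARY
        pooled_values = []
        for offset in (0, 5, 16):
            model = DTIModel(cfg)
            w = np.zeros((6, 4))
            for t, ch in enumerate(motif):
                w[:, t] = model.embedding.table.value[vocab.index(ch)]
            # make the filter response at the motif dominate
            model.convs[4].W.value[:, 0] = 10.0 * w.reshape(-1)
            seq = list("A" * 20)
            seq[offset:offset + 4] = motif
            enc = encode_sequence("".join(seq), mpl=30)
            trace = model.protein_conv_trace(enc)
            pooled, arg = trace[4]
            assert arg[0] == offset + 1
            pooled_values.append(pooled[0])
        np.testing.assert_allclose(pooled_values, pooled_values[0], atol=1e-10)


class TestLoss:
    def test_uninformative_prediction_gives_log2(self):
        assert bce_loss([0.5, 0.5], [1, 0]) == pytest.approx(np.log(2), abs=1e-12)

    def test_confident_correct_approaches_zero(self):
        assert bce_loss([1.0, 0.0], [1, 0]) < 1e-5

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bce_loss([0.5], [1, 0])

    def test_l2_penalty_zero_for_zero_weights(self, tiny_config):
        model = DTIModel(dataclasses.replace(tiny_config, l2_lambda=0.1))
        for p in model.params():
            if p.weight_decay:
                p.value[:] = 0.0
        assert model.l2_penalty() == 0.0

    def test_l2_penalty_excludes_embedding_and_biases(self, tiny_config):
        model = DTIModel(dataclasses.replace(tiny_config, l2_lambda=1.0))
        base = model.l2_penalty()
        model.embedding.table.value += 10.0
        model.output.b.value += 10.0
        model.pool_bn.gamma.value += 10.0
        assert model.l2_penalty() == pytest.approx(base)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients of the penalised loss agree with central
        finite differences to 1e-4 relative error on a tiny model."""
        cfg = ModelConfig(window_sizes=(3, 4), filters_per_window=3,
                          embedding_size=4, mpl=15, protein_dense_sizes=(5,),
                          drug_dense_sizes=(4,), joint_dense_sizes=(4,),
                          fingerprint_bits=10, spatial_dropout_rate=0.0,
                          dense_dropout_rate=0.0, l2_lambda=1e-3, seed=7)
        model = DTIModel(cfg)
        rng = np.random.default_rng(0)
        B = 5
        labels = rng.integers(1, 21, size=(B, 15))
        lengths = np.array([15, 10, 8, 12, 6])
        for i, l in enumerate(lengths):
            labels[i, l:] = 0
        fps = rng.integers(0, 2, size=(B, 10)).astype(float)
        y = rng.integers(0, 2, size=B)

        def loss():
            out = model.forward_batch(labels, lengths, fps, training=True)
            return model.penalized_loss(out["probability"], y)

        out = model.forward_batch(labels, lengths, fps, training=True)
        for p in model.params():
            p.zero_grad()
        model.backward_batch((out["probability"] - y) / B)
        model.add_l2_gradients()

        eps = 1e-6
        pick = np.random.default_rng(1)
        for p in model.params():
            flat_idx = pick.choice(p.value.size, size=min(5, p.value.size),
                                   replace=False)
            for i in flat_idx:
                idx = np.unravel_index(i, p.value.shape)
                old = p.value[idx]
                p.value[idx] = old + eps
                lp = loss()
                p.value[idx] = old - eps
                lm = loss()
                p.value[idx] = old
                fd = (lp - lm) / (2 * eps)
                g = p.grad[idx]
                # absolute floor absorbs FD noise on true-zero gradients
                # (e.g. biases feeding straight into batch-norm)
                if abs(fd - g) < 1e-7:
                    continue
                assert abs(fd - g) / max(abs(fd), abs(g)) < 1e-4, p.name


class TestStateRoundtrip:
    def test_save_load_preserves_predictions(self, tiny_model, tmp_path, rng):
        labels = rng.integers(1, 21, size=(3, 20))
        lengths = np.array([20, 9, 14])
        fps = rng.integers(0, 2, size=(3, 10)).astype(float)
        before = tiny_model.predict(labels, lengths, fps)
        state = tiny_model.get_state()
        state.threshold = 0.42
        path = tmp_path / "model.npz"
        state.save(path)
        from convdti.nn.model import ModelState
        restored = DTIModel.from_state(ModelState.load(path))
        np.testing.assert_allclose(restored.predict(labels, lengths, fps),
                                   before, atol=1e-12)
        assert restored.threshold == 0.42

    def test_inference_is_deterministic(self, tiny_model, rng):
        labels = rng.integers(1, 21, size=(4, 20))
        lengths = np.full(4, 20)
        fps = rng.integers(0, 2, size=(4, 10)).astype(float)
        a = tiny_model.predict(labels, lengths, fps)
        b = tiny_model.predict(labels, lengths, fps)
        np.testing.assert_array_equal(a, b)
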