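import numpy as np
import pytest
from scipy import special

from cltnet.autodiff import Tensor
from cltnet.model import (CLTNet, EncoderLayer, LSTMLayer, ModelConfig,
                          MultiHeadAttention, count_parameters,
                          feature_sequence_length, load_checkpoint,
                          save_checkpoint, temporal_receptive_field_ms)


def small_cfg(**kw):
    base = dict(C=3, T=128, F1=4, D=2, KC1=8, KC2=8, pool1=4, P2=4,
                lstm_hidden=8, ffn_hidden=16, d_k=8, h=2, N=2)
    base.update(kw)
    return ModelConfig(**base)


# ---------------------------------------------------------------- CNN stage

class TestCNNStage:
    def test_default_config_emits_16_by_15_feature_sequence(self):
        """22-channel, 1000-sample trials with the default configuration give
        a 15-step sequence of 16 features (the canonical (16, 1, 15) feature map)."""
        cfg = ModelConfig()
        model = CLTNet(cfg, rng=0)
        x = Tensor(np.random.default_rng(0).standard_normal((2, 22, 1000)))
        feats = model.cnn_forward(x)
        assert feats.shape == (2, 15, 16)

    def test_sequence_length_formula(self):
        assert feature_sequence_length(1000, 8, 8) == 15

    def test_shape_law_over_random_configs(self):
        """Output dims are (batch, TC, F2) with TC by floor division at both
        pooling stages, against an independent repeated-subtraction counter."""
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 50:
            C = int(rng.integers(1, 8))
            T = int(rng.integers(32, 300))
            pool1 = int(rng.integers(2, 6))
            P2 = int(rng.integers(2, 6))
            # independent: peel off pool1-sized blocks, then P2-sized blocks
            L = 0
            t = T
            while t >= pool1:
                t -= pool1
                L += 1
            tc, L2 = 0, L
            while L2 >= P2:
                L2 -= P2
                tc += 1
            if tc < 1:
                continue
            assert feature_sequence_length(T, pool1, P2) == tc
            checked += 1

    @pytest.mark.parametrize("C,T,pool1,P2", [(3, 128, 4, 4), (5, 96, 2, 6), (2, 200, 8, 3)])
    def test_forward_shape_matches_formula(self, C, T, pool1, P2):
        cfg = small_cfg(C=C, T=T, pool1=pool1, P2=P2)
        model = CLTNet(cfg, rng=1)
        x = Tensor(np.random.default_rng(1).standard_normal((3, C, T)))
        assert model.cnn_forward(x).shape == (3, cfg.TC, cfg.F2)

    def test_mismatched_input_raises(self):
        model = CLTNet(small_cfg(), rng=0)
        with pytest.raises(ValueError, match="does not match config"):
            model.cnn_forward(Tensor(np.zeros((1, 5, 128))))

    def test_too_aggressive_pooling_rejected(self):
        with pytest.raises(ValueError, match="TC"):
            small_cfg(T=32, pool1=8, P2=8)

    def test_receptive_field_of_16_at_32hz_is_500ms(self):
        """A 16-sample temporal kernel at the 32 Hz post-pooling rate covers
        half a second of signal."""
        assert temporal_receptive_field_ms(16, 32.0) == 500.0


# ---------------------------------------------------------------- LSTM stage

def lstm_oracle(layer: LSTMLayer, x: np.ndarray) -> np.ndarray:
    """Straight-loop evaluation of the gate equations on plain arrays."""
    sig = special.expit
    W = {k: getattr(layer, k).data for k in
         ("W_xi", "W_hi", "b_i", "W_xf", "W_hf", "b_f",
          "W_xo", "W_ho", "b_o", "W_xc", "W_hc", "b_c")}
    B, L, _ = x.shape
    H = W["W_hi"].shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    out = np.zeros((B, L, H))
    for t in range(L):
        xt = x[:, t]
        i = sig(xt @ W["W_xi"] + h @ W["W_hi"] + W["b_i"])
        f = sig(xt @ W["W_xf"] + h @ W["W_hf"] + W["b_f"])
        o = sig(xt @ W["W_xo"] + h @ W["W_ho"] + W["b_o"])
        cand = np.tanh(xt @ W["W_xc"] + h @ W["W_hc"] + W["b_c"])
        c = f * c + i * cand
        h = o * np.tanh(c)
        out[:, t] = h
    return out


class TestLSTM:
    def test_matches_straight_loop_oracle(self):
        rng = np.random.default_rng(3)
        layer = LSTMLayer(3, 4, rng)
        x = rng.standard_normal((2, 5, 3))
        got = layer(Tensor(x)).data
        np.testing.assert_allclose(got, lstm_oracle(layer, x), atol=1e-5)

    def test_zero_weights_give_zero_hidden_states(self):
        rng = np.random.default_rng(0)
        layer = LSTMLayer(3, 4, rng)
        for _, p in layer.named_parameters():
            p.data[...] = 0.0
        out = layer(Tensor(np.random.default_rng(1).standard_normal((2, 6, 3)))).data
        # gates are 0.5, candidate is 0 => c_t = 0 and h_t = 0 throughout
        np.testing.assert_array_equal(out, np.zeros_like(out))

    def test_output_length_equals_input_length(self):
        rng = np.random.default_rng(4)
        model = CLTNet(small_cfg(), rng=rng)
        seq = Tensor(rng.standard_normal((2, small_cfg().TC, small_cfg().d)))
        assert model.lstm_forward(seq).shape == seq.shape


# ------------------------------------------------------------- attention

def mha_oracle(mha: MultiHeadAttention, S: np.ndarray) -> np.ndarray:
    """Brute-force per-head attention with explicit dot products and softmax."""
    Wq, Wk, Wv, Wo = mha.W_q.data, mha.W_k.data, mha.W_v.data, mha.W_o.data
    h, d, d_k = Wq.shape
    L = S.shape[0]
    heads = []
    for i in range(h):
        Q, K, V = S @ Wq[i], S @ Wk[i], S @ Wv[i]
        Z = np.zeros((L, d_k))
        for a in range(L):
            logits = np.array([np.dot(Q[a], K[b]) / np.sqrt(d_k) for b in range(L)])
            w = np.exp(logits - logits.max())
            w = w / w.sum()
            for b in range(L):
                Z[a] += w[b] * V[b]
        heads.append(Z)
    return np.concatenate(heads, axis=1) @ Wo


class TestAttention:
    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        mha = MultiHeadAttention(d=16, h=2, d_k=16, rng=rng)
        S = rng.standard_normal((3, 16))
        got = mha(Tensor(S[None]))
        np.testing.assert_allclose(got.data[0], mha_oracle(mha, S), atol=1e-5)

    def test_softmax_rows_sum_to_one(self):
        rng = np.random.default_rng(6)
        mha = MultiHeadAttention(d=8, h=3, d_k=4, rng=rng)
        A = mha.attention_weights(Tensor(rng.standard_normal((2, 5, 8))))
        np.testing.assert_allclose(A.sum(axis=-1), np.ones(A.shape[:-1]), atol=1e-6)

    def test_single_token_passes_value_through(self):
        """With one sequence position the softmax weight is 1, so each head
        outputs exactly its value vector."""
        rng = np.random.default_rng(7)
        mha = MultiHeadAttention(d=6, h=2, d_k=5, rng=rng)
        S = rng.standard_normal((1, 1, 6))
        got = mha(Tensor(S)).data
        V = np.concatenate([S[0] @ mha.W_v.data[i] for i in range(2)], axis=1)
        np.testing.assert_allclose(got[0], V @ mha.W_o.data, atol=1e-12)

    def test_nonfinite_input_surfaces(self):
        rng = np.random.default_rng(8)
        mha = MultiHeadAttention(d=4, h=1, d_k=4, rng=rng)
        bad = np.full((1, 2, 4), np.nan)
        out = mha(Tensor(bad)).data
        assert np.isnan(out).any()    # propagated, not silently masked


# ------------------------------------------------------------- GELU / encoder

class TestGELUAndEncoder:
    def test_gelu_is_x_times_normal_cdf(self):
        x = np.linspace(-10, 10, 2001)
        got = Tensor(x).gelu().data
        expected = x * 0.5 * (1 + special.erf(x / np.sqrt(2)))
        np.testing.assert_allclose(got, expected, atol=1e-9)
        assert Tensor(np.array(0.0)).gelu().data == 0.0
        np.testing.assert_allclose(Tensor(np.array(1.0)).gelu().data,
                                   special.ndtr(1.0), atol=1e-9)

    def test_gelu_odd_part_identity(self):
        """gelu(x) - gelu(-x) = x, since Phi(-x) = 1 - Phi(x)."""
        x = np.random.default_rng(9).standard_normal(1000) * 3
        diff = Tensor(x).gelu().data - Tensor(-x).gelu().data
        np.testing.assert_allclose(diff, x, atol=1e-9)

    def test_layernorm_rows_standardized(self):
        rng = np.random.default_rng(10)
        enc = EncoderLayer(d=8, h=2, d_k=4, ffn_hidden=16, dropout_ffn=0.0, rng=rng)
        out = enc(Tensor(rng.standard_normal((2, 5, 8))), train=False, rng=None)
        # affine is at identity after init, so rows are standardized
        np.testing.assert_allclose(out.data.mean(-1), 0.0, atol=1e-5)
        np.testing.assert_allclose(out.data.std(-1), 1.0, atol=1e-4)

    def test_degenerate_weights_reduce_to_double_layernorm(self):
        rng = np.random.default_rng(11)
        enc = EncoderLayer(d=6, h=2, d_k=3, ffn_hidden=8, dropout_ffn=0.0, rng=rng)
        for _, p in enc.named_parameters():
            if p is not enc.ln1.gamma and p is not enc.ln2.gamma:
                p.data[...] = 0.0
        enc.ln1.gamma.data[...] = 1.0
        enc.ln2.gamma.data[...] = 1.0
        S = rng.standard_normal((1, 4, 6))

        def ln(v):
            mu = v.mean(-1, keepdims=True)
            sd = np.sqrt(((v - mu) ** 2).mean(-1, keepdims=True) + 1e-5)
            return (v - mu) / sd

        got = enc(Tensor(S), train=False, rng=None).data
        np.testing.assert_allclose(got, ln(ln(S)), atol=1e-10)

    def test_permutation_equivariance_without_positional_encoding(self):
        rng = np.random.default_rng(12)
        enc = EncoderLayer(d=8, h=2, d_k=8, ffn_hidden=16, dropout_ffn=0.0, rng=rng)
        S = rng.standard_normal((1, 6, 8))
        perm = rng.permutation(6)
        out_then_perm = enc(Tensor(S), False, None).data[:, perm]
        perm_then_out = enc(Tensor(S[:, perm]), False, None).data
        np.testing.assert_allclose(out_then_perm, perm_then_out, atol=1e-10)


# ------------------------------------------------------------- classifier / full model

class TestClassifierAndForward:
    def test_probabilities_on_simplex(self):
        model = CLTNet(small_cfg(), rng=0)
        x = np.random.default_rng(0).standard_normal((5, 3, 128))
        probs = model.predict_proba(x)
        np.testing.assert_allclose(probs.sum(1), 1.0, atol=1e-6)
        assert probs.min() >= 0

    def test_zero_classifier_weights_give_uniform_probabilities(self):
        model = CLTNet(small_cfg(N=4, lstm_hidden=8), rng=0)
        model.fc.W.data[...] = 0.0
        model.fc.b.data[...] = 0.0
        probs = model.predict_proba(np.random.default_rng(1).standard_normal((3, 3, 128)))
        np.testing.assert_allclose(probs, 0.25, atol=1e-12)

    def test_argmax_invariant_under_logit_shift(self):
        rng = np.random.default_rng(13)
        logits = rng.standard_normal((10, 4))
        p1 = Tensor(logits).softmax(-1).data
        p2 = Tensor(logits + 7.3).softmax(-1).data
        np.testing.assert_array_equal(p1.argmax(1), p2.argmax(1))

    def test_evaluation_forward_is_bit_reproducible(self):
        model = CLTNet(small_cfg(), rng=0)
        x = np.random.default_rng(2).standard_normal((4, 3, 128))
        a = model.predict_proba(x)
        b = model.predict_proba(x)
        np.testing.assert_array_equal(a, b)

    def test_training_mode_differs_only_through_dropout(self):
        cfg = small_cfg(dropout_cnn=0.0, dropout_lstm=0.0, dropout_ffn=0.0,
                        dropout_cls=0.0)
        model = CLTNet(cfg, rng=0)
        x = Tensor(np.random.default_rng(3).standard_normal((2, 3, 128)))
        eval_out = model(x).data
        train_out = model(x, train=True, rng=np.random.default_rng(0)).data
        # with all dropout at 0 the only train/eval difference is batch-norm
        # statistics; feeding the same batch keeps them equal up to the
        # running-stat update tolerance
        assert np.abs(eval_out - train_out).max() < 0.2

    def test_every_parameter_receives_gradient(self):
        from cltnet.autodiff import cross_entropy_logits
        model = CLTNet(small_cfg(), rng=0)
        x = Tensor(np.random.default_rng(4).standard_normal((6, 3, 128)))
        loss = cross_entropy_logits(
            model.forward_logits(x, train=True, rng=np.random.default_rng(1)),
            np.array([0, 1, 0, 1, 0, 1]))
        loss.backward()
        for name, p in model.named_parameters():
            assert p.grad is not None and np.abs(p.grad).sum() > 0, name

    def test_gradient_matches_finite_differences_spot_check(self):
        from cltnet.autodiff import cross_entropy_logits
        cfg = small_cfg(dropout_cnn=0.0, dropout_lstm=0.0, dropout_ffn=0.0,
                        dropout_cls=0.0)
        model = CLTNet(cfg, rng=0)
        x = np.random.default_rng(5).standard_normal((3, 3, 128))
        y = np.array([0, 1, 0])

        def loss_value():
            return cross_entropy_logits(
                model.forward_logits(Tensor(x)), y).item()

        loss = cross_entropy_logits(model.forward_logits(Tensor(x)), y)
        loss.backward()
        rng = np.random.default_rng(6)
        params = list(model.named_parameters())
        for idx in rng.choice(len(params), size=5, replace=False):
            name, p = params[idx]
            flat = rng.integers(p.data.size)
            eps = 1e-5
            orig = p.data.flat[flat]
            p.data.flat[flat] = orig + eps
            up = loss_value()
            p.data.flat[flat] = orig - eps
            down = loss_value()
            p.data.flat[flat] = orig
            num = (up - down) / (2 * eps)
            assert abs(num - p.grad.flat[flat]) < 1e-4 * max(1, abs(num)), name


class TestParameterCount:
    def test_matches_closed_form_for_default_config(self):
        cfg = ModelConfig()
        conv = cfg.F1 * cfg.KC1 + cfg.F1 + cfg.F1 * cfg.D * cfg.C \
            + cfg.KC2 * cfg.F2 * cfg.F2
        bn = 2 * (2 * cfg.F2)
        lstm = 0
        n_in = cfg.d
        for _ in range(cfg.lstm_layers):
            lstm += 4 * (n_in * cfg.lstm_hidden + cfg.lstm_hidden ** 2 + cfg.lstm_hidden)
            n_in = cfg.lstm_hidden
        attn = 3 * cfg.h * cfg.d * cfg.d_k + cfg.h * cfg.d_k * cfg.d
        ffn = cfg.d * cfg.ffn_hidden + cfg.ffn_hidden + cfg.ffn_hidden * cfg.d + cfg.d
        ln = 2 * (2 * cfg.d)
        fusion_width = cfg.TC * cfg.d + cfg.TC * cfg.lstm_hidden
        fc = fusion_width * cfg.N + cfg.N
        expected = conv + bn + lstm * 1 + (attn + ffn + ln) * cfg.encoder_layers + fc
        assert count_parameters(cfg) == expected

    def test_lstm_contribution_formula(self):
        rng = np.random.default_rng(0)
        layer = LSTMLayer(16, 16, rng)
        n = sum(p.size for p in layer.parameters())
        assert n == 4 * (16 * 16 + 16 ** 2 + 16)

    def test_doubling_f1_increases_count(self):
        assert count_parameters(small_cfg(F1=8, lstm_hidden=16, d_k=16)) > \
            count_parameters(small_cfg(F1=4, lstm_hidden=8, d_k=8))

    def test_count_increases_with_heads(self):
        counts = [count_parameters(small_cfg(h=h)) for h in (1, 2, 4)]
        assert counts[0] < counts[1] < counts[2]


class TestCheckpoint:
    def test_roundtrip_preserves_forward(self, tmp_path):
        model = CLTNet(small_cfg(), rng=0)
        x = np.random.default_rng(7).standard_normal((2, 3, 128))
        before = model.predict_proba(x)
        path = tmp_path / "model.h5"
        save_checkpoint(model, path)
        after = load_checkpoint(path).predict_proba(x)
        np.testing.assert_array_equal(before, after)
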