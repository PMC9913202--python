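"""Attention primitives, distillation, encoder–decoder and training."""

import numpy as np
import pandas as pd
import pytest

import stlcast as sc
from stlcast.autodiff import Tensor
from stlcast.data_io import N_TIME_FEATURES
from stlcast.residual_model import (
    DistillBlock,
    Embedding,
    InformerConfig,
    InformerModel,
    distill_block,
    encoder_output_length,
    full_attention,
    positional_encoding,
    prob_sparse_attention,
    train_residual,
)


class TestEmbedding:
    def test_zero_input_embeds_to_positional_encoding(self, rng):
        emb = Embedding(3, 16, np.random.default_rng(0))
        out = emb(np.zeros((1, 10, 3)), np.zeros((1, 10, N_TIME_FEATURES)))
        np.testing.assert_allclose(out.data[0], positional_encoding(10, 16), atol=1e-12)

    def test_output_width_is_d_model(self, rng):
        for c_in in (1, 2, 3):
            emb = Embedding(c_in, 24, np.random.default_rng(0))
            out = emb(rng.normal(size=(2, 5, c_in)), rng.normal(size=(2, 5, N_TIME_FEATURES)))
            assert out.shape == (2, 5, 24)

    def test_value_projection_is_linear(self, rng):
        emb = Embedding(3, 16, np.random.default_rng(0))
        t = np.zeros((1, 6, N_TIME_FEATURES))
        x = rng.normal(size=(1, 6, 3))
        pe = positional_encoding(6, 16)
        single = emb(x, t).data - pe
        double = emb(2 * x, t).data - pe
        np.testing.assert_allclose(double, 2 * single, atol=1e-12)


class TestFullAttention:
    def test_single_key_returns_that_value(self, rng):
        Q = rng.normal(size=(4, 8))
        K = rng.normal(size=(1, 8))
        V = rng.normal(size=(1, 8))
        out = full_attention(Q, K, V)
        np.testing.assert_allclose(out, np.repeat(V, 4, axis=0), atol=1e-12)

    def test_zero_query_averages_values(self, rng):
        K = rng.normal(size=(6, 8))
        V = rng.normal(size=(6, 8))
        out = full_attention(np.zeros((2, 8)), K, V)
        np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (2, 1)), atol=1e-12)

    def test_causal_first_position_sees_only_first_value(self, rng):
        Q = rng.normal(size=(5, 8))
        K = rng.normal(size=(5, 8))
        V = rng.normal(size=(5, 8))
        out = full_attention(Q, K, V, causal_mask=True)
        np.testing.assert_allclose(out[0], V[0], atol=1e-12)

    def test_softmax_rows_sum_to_one(self, rng):
        # checked through the value-of-ones trick
        Q, K = rng.normal(size=(6, 8)), rng.normal(size=(6, 8))
        out = full_attention(Q, K, np.ones((6, 1)))
        np.testing.assert_allclose(out, 1.0, atol=1e-12)

    def test_dim_mismatch_errors(self, rng):
        with pytest.raises(ValueError):
            full_attention(rng.normal(size=(3, 4)), rng.normal(size=(3, 5)),
                           rng.normal(size=(3, 5)))


class TestProbSparseAttention:
    @pytest.mark.parametrize("causal", [False, True])
    def test_equals_full_attention_when_u_covers_all(self, causal):
        rng = np.random.default_rng(42)
        for _ in range(60):
            L = int(rng.integers(1, 16))
            d = int(rng.integers(2, 8))
            Q, K, V = (rng.normal(size=(L, d)) for _ in range(3))
            a = full_attention(Q, K, V, causal_mask=causal)
            b = prob_sparse_attention(Q, K, V, factor_c=100, causal=causal)
            np.testing.assert_allclose(a, b, atol=1e-10)

    def test_identical_queries_tie_break_and_finiteness(self, rng):
        Q = np.tile(rng.normal(size=(1, 6)), (8, 1))
        K, V = rng.normal(size=(8, 6)), rng.normal(size=(8, 6))
        out = prob_sparse_attention(Q, K, V, factor_c=1)
        assert np.isfinite(out).all()
        # selected queries (lowest indices on ties) match full attention
        u = min(8, 1 * int(np.ceil(np.log(8))))
        full = full_attention(Q, K, V)
        np.testing.assert_allclose(out[:u], full[:u], atol=1e-12)
        # the rest fall back to the value mean
        np.testing.assert_allclose(out[u:], np.tile(V.mean(axis=0), (8 - u, 1)), atol=1e-12)

    def test_single_query_always_selected(self, rng):
        Q = rng.normal(size=(1, 4))
        K, V = rng.normal(size=(5, 4)), rng.normal(size=(5, 4))
        np.testing.assert_allclose(
            prob_sparse_attention(Q, K, V, factor_c=1),
            full_attention(Q, K, V), atol=1e-12,
        )

    def test_causal_fallback_is_cumulative_mean(self, rng):
        # force u = 1 so later queries use the running mean of values
        L = 40
        Q = np.zeros((L, 4))
        Q[0] = 10.0  # only this query scores high
        K, V = rng.normal(size=(L, 4)), rng.normal(size=(L, 4))
        out = prob_sparse_attention(Q, K, V, factor_c=1, causal=True)
        cm = np.cumsum(V, axis=0) / np.arange(1, L + 1)[:, None]
        np.testing.assert_allclose(out[-1], cm[-1], atol=1e-12)


class TestDistill:
    @pytest.mark.parametrize("L, expect", [(24, 12), (25, 13), (2, 1)])
    def test_halving_lengths(self, L, expect, rng):
        block = DistillBlock(8, np.random.default_rng(0))
        out = block(Tensor(rng.normal(size=(1, L, 8))))
        assert out.shape[1] == expect

    def test_identity_conv_on_constants(self):
        x = np.full((1, 10, 4), 3.0)
        out = distill_block(x)
        np.testing.assert_allclose(out, 3.0, atol=1e-12)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            distill_block(np.ones((1, 1, 4)))

    def test_encoder_length_recursion(self):
        # closed-form ⌈·/2⌉ pyramid arithmetic for all L in 4..128
        cfg = InformerConfig.reduced(input_size=2, d_model=8, n_heads=2, dropout=0.0)
        model = InformerModel(cfg, seed=0)
        rng = np.random.default_rng(0)
        for L in range(4, 129, 31):
            enc_x = rng.normal(size=(1, L, 2))
            enc_t = rng.normal(size=(1, L, N_TIME_FEATURES))
            Ve = model.encode(enc_x, enc_t)
            assert Ve.shape[1] == encoder_output_length(L, cfg.stack_levels)


class TestEncoderDecoder:
    def _model(self, **kw):
        kw.setdefault("input_size", 3)
        kw.setdefault("pred_len", 7)
        kw.setdefault("d_model", 16)
        kw.setdefault("n_heads", 2)
        kw.setdefault("dropout", 0.0)
        return InformerModel(InformerConfig.reduced(**kw), seed=3)

    def _batch(self, rng, B=2, s=24, l=12, p=7, C=3):
        return (rng.normal(size=(B, s, C)), rng.normal(size=(B, s, N_TIME_FEATURES)),
                rng.normal(size=(B, l + p, C)), rng.normal(size=(B, l + p, N_TIME_FEATURES)))

    def test_output_horizon_and_determinism(self, rng):
        m = self._model()
        enc_x, enc_t, dec_x, dec_t = self._batch(rng)
        a = m.forward(enc_x, enc_t, dec_x, dec_t).data
        b = m.forward(enc_x, enc_t, dec_x, dec_t).data
        assert a.shape == (2, 7)
        np.testing.assert_array_equal(a, b)

    def test_single_stack_no_distill_collapses_to_one_attention_layer(self, rng):
        m = self._model(stack_levels=(1,), distill=False)
        enc_x, enc_t, *_ = self._batch(rng)
        Ve = m.encode(enc_x, enc_t)
        emb = m.enc_embed(enc_x, enc_t)
        direct = m.stacks[0]["layers"][0](emb)
        np.testing.assert_allclose(Ve.data, direct.data, atol=1e-12)

    def test_decoder_masked_self_attention_is_causal(self, rng):
        # perturbing a later decoder row never changes earlier positions of
        # the masked self-attention sublayer.  factor_c is set high enough
        # that every query receives exact attention: with u < L the global
        # top-u ranking itself may shift, which is inherent to sparse scoring
        m = self._model(factor_c=100)
        enc_x, enc_t, dec_x, dec_t = self._batch(rng, B=1)
        emb = m.dec_embed(dec_x, dec_t)
        base = m.decoder.self_attn(emb, emb, emb).data
        dec_x2 = dec_x.copy()
        dec_x2[0, 15] += 5.0  # a placeholder-region row
        emb2 = m.dec_embed(dec_x2, dec_t)
        pert = m.decoder.self_attn(emb2, emb2, emb2).data
        np.testing.assert_allclose(pert[0, :15], base[0, :15], atol=1e-10)

    def test_shape_mismatch_errors(self, rng):
        m = self._model()
        enc_x, enc_t, dec_x, dec_t = self._batch(rng)
        with pytest.raises(ValueError):
            m.forward(enc_x[:, :, :2], enc_t, dec_x, dec_t)


class TestTraining:
    def _ar_windows(self, rng, n=400, C=3, phi=0.9):
        x = np.zeros((n, C))
        innov = rng.normal(size=(n, C)) * 0.1
        shared = rng.normal(size=(n, 1)) * 0.2
        for t in range(1, n):
            x[t] = phi * x[t - 1] + innov[t] + shared[t]
        ts = pd.date_range("2024-01-01", periods=n, freq="10min")
        s = sc.RegularSeries(ts, x, [f"c{i}" for i in range(C)])
        return sc.make_windows(s, 24, 12, 7, "c0")

    def test_lr_schedule(self, rng):
        wb = self._ar_windows(rng, n=100)
        cfg = InformerConfig.reduced(input_size=3, epochs=3, steps_per_epoch=2, dropout=0.0)
        model = train_residual(wb, cfg, seed=0)
        np.testing.assert_allclose(model.lr_history, [1e-3, 5e-4, 2.5e-4])

    def test_same_seed_identical_loss_trace(self, rng):
        wb = self._ar_windows(rng, n=120)
        cfg = InformerConfig.reduced(input_size=3, epochs=2, steps_per_epoch=3)
        a = train_residual(wb, cfg, seed=9)
        b = train_residual(wb, cfg, seed=9)
        assert a.loss_history == b.loss_history

    def test_fits_autocorrelated_noise_below_target_variance(self, rng):
        wb = self._ar_windows(rng)
        cfg = InformerConfig.reduced(input_size=3, epochs=6, steps_per_epoch=40)
        model = train_residual(wb, cfg, seed=0)
        target_var = wb.target.var()
        assert model.loss_history[-1] < target_var
        assert model.loss_history[-1] < model.loss_history[0]

    def test_empty_batch_errors(self, rng):
        wb = self._ar_windows(rng, n=100)
        with pytest.raises(ValueError):
            train_residual(wb.subset(np.array([], dtype=int)),
                           InformerConfig.reduced(input_size=3), seed=0)
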