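"""Model mathematics: GRU cell, bidirectional encoding, attention, classifier."""

import numpy as np
import pytest

from hanscribe import han_core, synthgen, textprep, training
from hanscribe.errors import DimensionError, EmptyDocumentError
from hanscribe.han_core import (
    AttentionParams,
    GruParams,
    attention_pool,
    bigru_encode,
    classify,
    forward_document,
    gru_step,
    nll_loss,
)
from conftest import encode_one


def zero_gru(d, u, dtype=np.float64):
    return GruParams(W=np.zeros((d, 3 * u), dtype=dtype),
                     U=np.zeros((u, 3 * u), dtype=dtype),
                     b=np.zeros(3 * u, dtype=dtype))


def rand_gru(d, u, seed=0):
    rng = np.random.default_rng(seed)
    return GruParams(W=rng.normal(0, 0.3, (d, 3 * u)),
                     U=rng.normal(0, 0.3, (u, 3 * u)),
                     b=rng.normal(0, 0.3, 3 * u))


class TestGruStep:
    def test_zero_parameters_halve_previous_state(self):
        # z = sigma(0) = 1/2 and candidate tanh(0) = 0, so h' = h/2
        v = np.array([0.4, -1.2, 2.0])
        out = gru_step(np.zeros(2), v, zero_gru(2, 3))
        np.testing.assert_allclose(out, 0.5 * v)

    def test_zero_state_is_fixed_point_of_zero_parameters(self):
        out = gru_step(np.ones(2), np.zeros(3), zero_gru(2, 3))
        np.testing.assert_array_equal(out, np.zeros(3))

    def test_saturated_update_gate_returns_candidate(self):
        # with b_z -> +inf the update gate saturates and h' -> tanh(W_c x)
        p = zero_gru(1, 1)
        p.W[0, 2] = 0.7     # candidate input weight
        p.b[0] = 50.0       # update-gate bias, far into saturation
        out = gru_step(np.array([1.0]), np.array([0.3]), p)
        np.testing.assert_allclose(out, np.tanh(0.7), atol=1e-12)

    def test_output_bounded_by_gate_ranges(self):
        rng = np.random.default_rng(1)
        p = rand_gru(4, 5, seed=2)
        h = np.zeros(5)
        for _ in range(7):
            h = gru_step(rng.normal(size=4), h, p)
            assert np.all(np.abs(h) < 1.0)

    def test_shape_mismatch_raises(self):
        with pytest.raises(DimensionError):
            gru_step(np.zeros(3), np.zeros(3), zero_gru(2, 3))

    def test_gate_views_cover_parameter_arrays(self):
        p = rand_gru(2, 3, seed=0)
        Wz, Uz, bz = p.gate("z")
        assert Wz.shape == (2, 3) and Uz.shape == (3, 3) and bz.shape == (3,)
        np.testing.assert_array_equal(Wz, p.W[:, :3])


class TestBigruEncode:
    def test_length_one_sequence_is_single_step_both_directions(self):
        fwd, bwd = rand_gru(2, 3, 1), rand_gru(2, 3, 2)
        x = np.array([[0.5, -0.2]])
        out = bigru_encode(x, fwd, bwd)
        np.testing.assert_allclose(out[0, :3], gru_step(x[0], np.zeros(3), fwd))
        np.testing.assert_allclose(out[0, 3:], gru_step(x[0], np.zeros(3), bwd))

    def test_backward_direction_equals_reversed_forward(self):
        fwd, bwd = rand_gru(2, 3, 1), rand_gru(2, 3, 2)
        X = np.random.default_rng(0).normal(size=(4, 2))
        out = bigru_encode(X, fwd, bwd)
        flipped = bigru_encode(X[::-1], bwd, fwd)
        np.testing.assert_allclose(out[:, 3:], flipped[::-1, :3], atol=1e-12)

    def test_appending_masked_position_leaves_outputs_unchanged(self):
        fwd, bwd = rand_gru(2, 3, 1), rand_gru(2, 3, 2)
        X = np.random.default_rng(1).normal(size=(3, 2))
        out = bigru_encode(X, fwd, bwd)
        padded = np.vstack([X, np.zeros((2, 2))])
        mask = np.array([1.0, 1, 1, 0, 0])
        out_padded = bigru_encode(padded, fwd, bwd, mask)
        np.testing.assert_allclose(out_padded[:3], out, atol=1e-12)
        assert not out_padded[3:].any()

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyDocumentError):
            bigru_encode(np.zeros((2, 2)), rand_gru(2, 3), rand_gru(2, 3),
                         mask=np.zeros(2))


class TestAttentionPool:
    def attn(self, h_dim=4, a=3, seed=0):
        rng = np.random.default_rng(seed)
        return AttentionParams(W=rng.normal(0, 0.5, (h_dim, a)),
                               b=rng.normal(0, 0.5, a),
                               u_ctx=rng.normal(0, 0.5, a))

    def test_identical_rows_give_uniform_weights(self):
        H = np.tile(np.array([0.3, -0.1, 0.7, 0.2]), (5, 1))
        pooled, w = attention_pool(H, self.attn())
        np.testing.assert_allclose(w, np.full(5, 0.2))
        np.testing.assert_allclose(pooled, H[0])

    def test_single_valid_position(self):
        H = np.random.default_rng(0).normal(size=(3, 4))
        pooled, w = attention_pool(H, self.attn(), mask=np.array([1.0, 0, 0]))
        np.testing.assert_allclose(w, [1.0, 0.0, 0.0])
        np.testing.assert_allclose(pooled, H[0])

    def test_hand_computed_softmax_scores(self):
        # a=1 projection chosen so scores are (ln 2, 0) -> weights (2/3, 1/3)
        p = AttentionParams(W=np.array([[1.0], [0.0]]), b=np.zeros(1),
                            u_ctx=np.ones(1))
        H = np.array([[np.arctanh(np.log(2.0)), 0.0], [0.0, 0.0]])
        pooled, w = attention_pool(H, p)
        np.testing.assert_allclose(w, [2 / 3, 1 / 3], atol=1e-12)
        np.testing.assert_allclose(pooled, (2 / 3) * H[0] + (1 / 3) * H[1])

    def test_all_masked_raises(self):
        with pytest.raises(EmptyDocumentError):
            attention_pool(np.zeros((2, 4)), self.attn(), mask=np.zeros(2))

    def test_uniform_flag_ignores_scores(self):
        H = np.random.default_rng(3).normal(size=(4, 4))
        _, w = attention_pool(H, self.attn(), uniform=True)
        np.testing.assert_allclose(w, np.full(4, 0.25))


class TestClassifyAndLoss:
    def test_zero_weights_give_even_split(self):
        np.testing.assert_allclose(
            classify(np.ones(4), np.zeros((2, 4)), np.zeros(2)), [0.5, 0.5])

    def test_hand_computed_softmax(self):
        # logits (ln 3, 0) -> probabilities (3/4, 1/4)
        w = np.vstack([np.full(2, np.log(3.0) / 2), np.zeros(2)])
        probs = classify(np.ones(2), w, np.zeros(2))
        np.testing.assert_allclose(probs, [0.75, 0.25], atol=1e-12)

    def test_shift_invariance(self):
        w = np.random.default_rng(0).normal(size=(2, 3))
        x = np.random.default_rng(1).normal(size=3)
        a = classify(x, w, np.zeros(2))
        b = classify(x, w, np.array([5.0, 5.0]))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_loss_zero_for_perfect_prediction(self):
        probs = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert nll_loss(probs, np.array([1, 0])) == pytest.approx(0.0)

    def test_loss_of_half_is_ln_two(self):
        assert nll_loss(np.array([[0.5, 0.5]]), np.array([1])) == \
            pytest.approx(np.log(2.0), abs=1e-12)

    def test_loss_additivity_over_documents(self):
        probs = np.array([[0.5, 0.5], [0.5, 0.5]])
        assert nll_loss(probs, np.array([0, 1])) == \
            pytest.approx(2 * np.log(2.0), abs=1e-12)

    def test_zero_probability_clamped_not_infinite(self):
        loss = nll_loss(np.array([[1.0, 0.0]]), np.array([1]))
        assert np.isfinite(loss) and loss == pytest.approx(-np.log(1e-12))


class TestForwardDocument:
    def test_single_word_document_has_unit_attention(self, tiny_config,
                                                     small_vocab):
        from hanscribe.transcripts import CleanTranscript

        params = training.init_params(tiny_config, small_vocab, seed=1)
        doc = CleanTranscript(doc_id="one", sentences=[["water"]], label="AD")
        batch = encode_one(doc, small_vocab)
        (out,) = forward_document(batch, params)
        assert out.attention.sentence_weights[0] == pytest.approx(1.0)
        np.testing.assert_allclose(out.attention.word_weights[0], [1.0])
        assert out.class_probabilities.sum() == pytest.approx(1.0)

    def test_inference_is_deterministic(self, tiny_params, small_vocab,
                                        two_sentence_doc):
        batch = encode_one(two_sentence_doc, small_vocab)
        a = forward_document(batch, tiny_params)
        b = forward_document(batch, tiny_params)
        np.testing.assert_array_equal(a[0].class_probabilities,
                                      b[0].class_probabilities)

    def test_padding_invariance(self, tiny_params, small_vocab,
                                two_sentence_doc):
        tight = encode_one(two_sentence_doc, small_vocab)
        loose = encode_one(two_sentence_doc, small_vocab, l_max=6, t_max=9)
        a = forward_document(tight, tiny_params)[0]
        b = forward_document(loose, tiny_params)[0]
        np.testing.assert_allclose(a.class_probabilities,
                                   b.class_probabilities, atol=1e-6)
        np.testing.assert_allclose(a.document_vector, b.document_vector,
                                   atol=1e-6)

    def test_attention_conservation_on_random_documents(self, tiny_config):
        corpus = synthgen.generate_corpus(
            synthgen.SynthConfig(n_docs_per_class=10, seed=3)).transcripts
        vocab = textprep.build_vocab(corpus)
        params = training.init_params(tiny_config, vocab, seed=5)
        batch = textprep.encode_batch(corpus, vocab, 10, 11)
        for out in forward_document(batch, params):
            rec = out.attention
            assert rec.sentence_weights.sum() == pytest.approx(1.0, abs=1e-9)
            for w in rec.word_weights:
                assert w.sum() == pytest.approx(1.0, abs=1e-9)
            total = sum(w.sum() for w in rec.normalized_word_weights)
            assert total == pytest.approx(1.0, abs=1e-9)
            # convexity: pooled vectors are convex combinations
            for w in rec.word_weights:
                assert (w >= 0).all() and w.sum() <= 1 + 1e-9

    def test_dropout_only_active_in_training_mode(self, tiny_params,
                                                  small_vocab,
                                                  two_sentence_doc):
        batch = encode_one(two_sentence_doc, small_vocab)
        eval_out = forward_document(batch, tiny_params, dropout_rate=0.5,
                                    training=False, seed=0)
        ref = forward_document(batch, tiny_params)
        np.testing.assert_array_equal(eval_out[0].class_probabilities,
                                      ref[0].class_probabilities)
        train_a = forward_document(batch, tiny_params, dropout_rate=0.5,
                                   training=True, seed=1)
        train_b = forward_document(batch, tiny_params, dropout_rate=0.5,
                                   training=True, seed=2)
        assert not np.array_equal(train_a[0].class_probabilities,
                                  train_b[0].class_probabilities)


class TestCheckpoint:
    def test_save_load_round_trip(self, tiny_params, tmp_path):
        path = tmp_path / "ckpt.npz"
        tiny_params.save(path, header={"note": "test"})
        loaded, header = han_core.HanParams.load(path)
        assert header["note"] == "test"
        for (name, a), (_, b) in zip(tiny_params.flat(), loaded.flat()):
            np.testing.assert_array_equal(a, b, err_msg=name)
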