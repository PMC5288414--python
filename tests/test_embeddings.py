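"""Tests for the CBoW / PV-DM embedding model and its softmax core."""

import numpy as np
import pytest

from asdscreen.embeddings import (Doc2Vec, softmax_loss_and_grads,
                                  softmax_prob, train_cbow, train_doc2vec)
from asdscreen.text import Corpus, Document


def make_corpus(token_lists):
    return Corpus([Document(f"d{i}", toks) for i, toks in
                   enumerate(token_lists)])


def cosine(a, b):
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


class TestSoftmax:
    def test_equal_scores_give_uniform(self):
        p = [softmax_prob(np.zeros(7), i) for i in range(7)]
        np.testing.assert_allclose(p, 1 / 7)

    def test_log_ratio_example(self):
        assert softmax_prob(np.array([0.0, np.log(3.0)]), 1) == \
            pytest.approx(0.75)

    def test_matches_unshifted_formula(self, rng):
        s = rng.normal(size=10)
        direct = np.exp(s) / np.exp(s).sum()
        for i in range(10):
            assert softmax_prob(s, i) == pytest.approx(direct[i], abs=1e-12)

    def test_probabilities_sum_to_one_even_for_large_scores(self, rng):
        s = rng.normal(size=20) * 300
        total = sum(softmax_prob(s, i) for i in range(20))
        assert total == pytest.approx(1.0, abs=1e-9)


class TestGradients:
    def test_analytic_gradient_matches_finite_differences(self, rng):
        """Central finite differences on a 5-word toy model agree with the
        analytic gradients to < 1e-4 relative error."""
        V, K = 5, 6
        W = rng.normal(size=(V, K)) * 0.4
        h = rng.normal(size=K) * 0.4
        target = 3
        _, gW, gh = softmax_loss_and_grads(W, h, target)
        eps = 1e-6

        def loss(Wm, hm):
            return softmax_loss_and_grads(Wm, hm, target)[0]

        for i in range(V):
            for j in range(K):
                Wp, Wm = W.copy(), W.copy()
                Wp[i, j] += eps
                Wm[i, j] -= eps
                fd = (loss(Wp, h) - loss(Wm, h)) / (2 * eps)
                assert abs(fd - gW[i, j]) <= 1e-4 * max(1.0, abs(fd))
        for j in range(K):
            hp, hm = h.copy(), h.copy()
            hp[j] += eps
            hm[j] -= eps
            fd = (loss(W, hp) - loss(W, hm)) / (2 * eps)
            assert abs(fd - gh[j]) <= 1e-4 * max(1.0, abs(fd))


@pytest.fixture(scope="module")
def context_model():
    return Doc2Vec(dim=4, window=2, mode="pvdm", n_epochs=1,
                   seed=0).fit(make_corpus([list("abcde")]))


@pytest.fixture(scope="module")
def inference_model():
    corpus = make_corpus([list("ababab") * 3, list("cdcdcd") * 3])
    return train_doc2vec(corpus, dim=8, window=1, lr=0.05, n_epochs=150,
                         seed=5)


class TestContextRepresentation:

    def test_pvdm_width_includes_paragraph_block(self, context_model):
        h = context_model.context_representation(0, 2)
        assert h.shape == (5 * 4,)  # 2c blocks + paragraph block

    def test_cbow_width_excludes_paragraph_block(self):
        m = Doc2Vec(dim=4, window=2, mode="cbow", n_epochs=1,
                    seed=0).fit(make_corpus([list("abcde")]))
        assert m.context_representation(0, 2).shape == (4 * 4,)

    def test_edge_positions_use_zero_pads(self, context_model):
        h = context_model.context_representation(0, 0)
        assert (h[:8] == 0).all()          # the two left-context blocks
        assert (h[8:] != 0).any()

    def test_repeated_neighbour_duplicates_its_block(self):
        m = Doc2Vec(dim=4, window=1, mode="cbow", n_epochs=1,
                    seed=0).fit(make_corpus([list("aba")]))
        h = m.context_representation(0, 1)  # both neighbours are "a"
        np.testing.assert_array_equal(h[:4], h[4:])


class TestTraining:
    def test_deterministic_alternation_learned(self):
        corpus = make_corpus([list("ababab")])
        m = train_cbow(corpus, dim=8, window=1, lr=0.1, n_epochs=200, seed=0)
        h = m.context_representation(0, 1)  # context (a, a), target b
        scores = m.word_out_ @ h
        assert softmax_prob(scores, m.index_["b"]) > \
            softmax_prob(scores, m.index_["a"])

    def test_objective_improves_on_toy_corpus(self):
        corpus = make_corpus([list("ababab"), list("cdcdcd")])
        m = train_cbow(corpus, dim=6, window=1, lr=0.05, n_epochs=60, seed=1)
        assert m.trace_[-1] > m.trace_[0]
        assert len(m.trace_) == 60
        assert np.isfinite(m.trace_).all()

    def test_same_seed_identical_vectors(self):
        corpus = make_corpus([list("abcabc"), list("defdef")])
        m1 = train_doc2vec(corpus, dim=6, window=1, n_epochs=10, seed=3)
        m2 = train_doc2vec(corpus, dim=6, window=1, n_epochs=10, seed=3)
        np.testing.assert_array_equal(m1.para_, m2.para_)
        np.testing.assert_array_equal(m1.word_in_, m2.word_in_)

    def test_disjoint_documents_less_similar_than_duplicates(self):
        corpus = make_corpus([list("ababab"), list("cdcdcd"),
                              list("ababab")])
        m = train_doc2vec(corpus, dim=8, window=1, lr=0.05, n_epochs=100,
                          seed=4)
        p = m.para_
        assert cosine(p[0], p[1]) < cosine(p[0], p[2])

    def test_paragraph_matrix_width_is_dim(self):
        corpus = make_corpus([list("abcd"), list("bcda")])
        m = train_doc2vec(corpus, dim=150, window=1, n_epochs=1, seed=0)
        assert m.para_.shape == (2, 150)


class TestInference:
    def test_reinference_matches_trained_vector(self, inference_model):
        vec = inference_model.infer(list("ababab") * 3, n_steps=150, seed=6)
        assert cosine(vec, inference_model.para_[0]) >= 0.8

    def test_word_matrices_frozen_during_inference(self, inference_model):
        before_in = inference_model.word_in_.copy()
        before_out = inference_model.word_out_.copy()
        inference_model.infer(list("abab"), n_steps=20, seed=7)
        np.testing.assert_array_equal(inference_model.word_in_, before_in)
        np.testing.assert_array_equal(inference_model.word_out_, before_out)

    def test_all_oov_document_yields_zero_vector(self, inference_model):
        with pytest.warns(UserWarning):
            vec = inference_model.infer(["zzz"], n_steps=5)
        assert (vec == 0).all()

    def test_empty_document_yields_zero_vector(self, inference_model):
        with pytest.warns(UserWarning):
            assert (inference_model.infer([], n_steps=5) == 0).all()
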