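"""Tests for tokenization and the lexical feature families."""

import numpy as np
import pytest
import scipy.sparse as sp

from asdscreen.stopwords import DEFAULT_STOPWORDS
from asdscreen.text import (BagOfWordsVectorizer, Corpus, Document,
                            FeatureMatrix, TfidfVectorizer, bow_matrix,
                            combine_features, extract_ngrams, tf_idf_matrix,
                            tokenize)


def make_corpus(token_lists, labels=None):
    labels = labels or [None] * len(token_lists)
    return Corpus([Document(f"d{i}", toks, lab)
                   for i, (toks, lab) in enumerate(zip(token_lists, labels))])


class TestTokenize:
    def test_stop_words_removed(self):
        assert tokenize("He is a boy", {"he", "is", "a"}) == ["boy"]

    def test_empty_text(self):
        assert tokenize("") == []

    def test_splits_on_non_alphabetic_and_lowercases(self):
        assert tokenize("Dr. Smith-Jones, age 4!", set()) == \
            ["dr", "smith", "jones", "age"]

    def test_default_list_matches_manual_filter(self):
        text = ("The child does not respond to his name and he avoids eye "
                "contact with other children during play, the parents are "
                "concerned about repetitive behaviors and delayed speech "
                "which was first noticed when he was about two years old "
                "at preschool")
        manual = [w.strip(",.!").lower() for w in text.split()]
        manual = [w for w in manual if w not in DEFAULT_STOPWORDS]
        assert tokenize(text) == manual

    def test_default_stop_list_has_174_words(self):
        assert len(DEFAULT_STOPWORDS) == 174


class TestNgrams:
    def test_bigrams(self):
        assert extract_ngrams(["a", "b", "c"], 2) == ["a_b", "b_c"]

    def test_too_short_sequence(self):
        assert extract_ngrams(["a"], 2) == []

    def test_trigram_count_is_length_minus_two(self):
        toks = [f"t{i}" for i in range(50)]
        assert len(extract_ngrams(toks, 3)) == 48


class TestBow:
    def test_counts(self):
        corpus = make_corpus([["x", "x", "y"]])
        fm = bow_matrix(corpus)
        assert fm.values.toarray().tolist() == [[2.0, 1.0]]
        assert fm.feature_names == ["bow:x", "bow:y"]
        assert fm.penalty_hint == "l1"

    def test_out_of_vocabulary_document_is_zero_row(self):
        train = make_corpus([["x", "y"]])
        vec = BagOfWordsVectorizer().fit(train)
        out = vec.transform(make_corpus([["z", "w"]]))
        assert out.nnz == 0

    def test_row_sums_equal_in_vocab_token_counts(self, small_corpus):
        corpus, _ = small_corpus
        fm = bow_matrix(corpus)
        sums = np.asarray(fm.values.sum(axis=1)).ravel()
        expected = [len(d.tokens) for d in corpus]
        np.testing.assert_array_equal(sums, expected)

    def test_empty_vocabulary_rejected(self):
        with pytest.raises(ValueError):
            BagOfWordsVectorizer().fit(make_corpus([[]]))

    def test_vocabulary_is_fit_on_training_only(self):
        train = make_corpus([["alpha", "beta"]])
        test = make_corpus([["alpha", "gamma"]])
        vec = BagOfWordsVectorizer().fit(train)
        out = vec.transform(test)
        assert out.shape[1] == 2  # gamma never becomes a column


class TestTfidf:
    def test_word_in_half_the_docs_of_two_gets_zero(self):
        corpus = make_corpus([["a"], ["b"]])
        fm = tf_idf_matrix(corpus)
        # df = 1 for each, idf = ln(2 / (1 + 1)) = 0
        assert abs(fm.values).max() == 0.0

    def test_hand_computed_value(self):
        # N=4, df("rare")=1, tf=3 -> 3 * ln(4/2) = 3 ln 2
        corpus = make_corpus([["rare", "rare", "rare"], ["x"], ["y"], ["z"]])
        fm = tf_idf_matrix(corpus)
        col = fm.feature_names.index("tfidf:rare")
        assert fm.values[0, col] == pytest.approx(3 * np.log(2), abs=1e-4)
        assert fm.values[0, col] == pytest.approx(2.0794, abs=1e-4)

    def test_ubiquitous_word_gets_negative_idf(self):
        corpus = make_corpus([["w", "a"], ["w", "b"], ["w", "c"]])
        vec = TfidfVectorizer().fit(corpus)
        col = vec.vocabulary_.index("w")
        assert vec.idf_[col] == pytest.approx(np.log(3 / 4))
        assert vec.idf_[col] < 0

    def test_single_document_corpus_entries_share_sign(self):
        # every present word has df=1, idf = ln(1/2) < 0
        corpus = make_corpus([["p", "q", "p"]])
        fm = tf_idf_matrix(corpus)
        vals = fm.values.toarray().ravel()
        assert (vals[vals != 0] < 0).all()

    def test_matches_count_times_idf_recomputation(self, small_corpus):
        corpus, _ = small_corpus
        fm = tf_idf_matrix(corpus)
        counts = bow_matrix(corpus).values.toarray()
        df = (counts > 0).sum(axis=0)
        manual = counts * np.log(len(corpus) / (1.0 + df))
        np.testing.assert_allclose(fm.values.toarray(), manual, atol=1e-12)


class TestCombine:
    def test_study_feature_space_width(self):
        """4839 BoW + 4839 tf-idf + 9284 n-gram columns combine to 18962."""
        mats = [FeatureMatrix(sp.csr_matrix((3, w)),
                              [f"m{w}:{j}" for j in range(w)], "l1")
                for w in (4839, 4839, 9284)]
        assert combine_features(mats).shape == (3, 18962)

    def test_single_matrix_unchanged(self):
        fm = FeatureMatrix(np.ones((2, 3)), ["a", "b", "c"], "l2")
        assert combine_features([fm]) is fm

    def test_columns_traceable_by_prefix(self, rng):
        a = FeatureMatrix(rng.random((4, 2)), ["fa:0", "fa:1"], "l1")
        b = FeatureMatrix(rng.random((4, 3)), ["fb:0", "fb:1", "fb:2"], "l2")
        combined = combine_features([a, b])
        assert combined.penalty_hint == "l1"
        for j, name in enumerate(combined.feature_names):
            src, col = name.split(":")
            source = a if src == "fa" else b
            np.testing.assert_allclose(
                np.asarray(combined.values.todense())[:, j],
                np.asarray(source.values)[:, int(col)])

    def test_row_mismatch_rejected(self):
        a = FeatureMatrix(np.ones((2, 1)), ["x"], "l1")
        b = FeatureMatrix(np.ones((3, 1)), ["y"], "l1")
        with pytest.raises(ValueError):
            combine_features([a, b])

    def test_ngram_columns_count_distinct_bigrams_plus_trigrams(self):
        corpus = make_corpus([["a", "b", "a", "b"], ["b", "c", "d"]])
        fm = bow_matrix(corpus, ngram_sizes=(2, 3))
        bigrams = {"a_b", "b_a", "b_c", "c_d"}
        trigrams = {"a_b_a", "b_a_b", "b_c_d"}
        assert fm.shape[1] == len(bigrams) + len(trigrams)
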