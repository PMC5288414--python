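"""Latent Dirichlet allocation by collapsed Gibbs sampling.

Each document is modeled as a mixture over ``n_topics`` latent topics, each
topic as a multinomial over the vocabulary, with symmetric Dirichlet priors
alpha (document-topic) and beta (topic-word).  Inference integrates the
multinomials out and resamples each token's topic assignment from

    p(z = t | rest)  ∝  (n_dt + alpha) * (n_tw + beta) / (n_t + V*beta),

sweeping all tokens ``n_iterations`` times.  From the final count tables the
model keeps both conditionals:

* ``topic_word_``  — P(w | t), rows are topics (word distribution per topic);
* ``word_topic_``  — P(t | w), rows are words (topic posterior per word).

Documents are embedded as the mean of their tokens' P(t | w) rows
(``doc_vector="word-avg"``) or, alternatively, as the document's own smoothed
topic proportions from the count table (``doc_vector="doc-posterior"``).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .text import Corpus, FeatureMatrix

__all__ = ["GibbsLDA", "topic_feature_matrix"]


class GibbsLDA(BaseEstimator, TransformerMixin):
    """Collapsed Gibbs LDA with deterministic seeded sampling.

    Parameters
    ----------
    n_topics : int
        Pre-defined topic count (the study swept 50..300; synthetic corpora
        use small values).
    alpha : float or None
        Document-topic concentration; ``None`` uses 50 / n_topics.
    beta : float
        Topic-word concentration.
    n_iterations : int
        Full Gibbs sweeps over all tokens.
    doc_vector : {"word-avg", "doc-posterior"}
        Document embedding rule, see module docstring.
    """

    def __init__(self, n_topics: int = 10, alpha: float | None = None,
                 beta: float = 0.01, n_iterations: int = 200,
                 doc_vector: str = "word-avg", seed: int = 0):
        self.n_topics = n_topics
        self.alpha = alpha
        self.beta = beta
        self.n_iterations = n_iterations
        self.doc_vector = doc_vector
        self.seed = seed

    # -- fitting -----------------------------------------------------------

    def fit(self, corpus: Corpus, y=None) -> "GibbsLDA":
        if self.n_topics < 2:
            raise ValueError("n_topics must be >= 2")
        if self.doc_vector not in ("word-avg", "doc-posterior"):
            raise ValueError("doc_vector must be 'word-avg' or 'doc-posterior'")
        docs = corpus.token_lists()
        if not docs:
            raise ValueError("corpus is empty")
        vocab = sorted({t for doc in docs for t in doc})
        if len(vocab) < 2:
            raise ValueError("vocabulary must hold at least 2 terms")
        self.vocabulary_ = vocab
        index = {w: j for j, w in enumerate(vocab)}
        self.index_ = index
        V, T = len(vocab), self.n_topics
        alpha = (50.0 / T) if self.alpha is None else self.alpha
        beta = self.beta

        rng = np.random.default_rng(self.seed)
        word_ids = [np.array([index[t] for t in doc], dtype=np.int64)
                    for doc in docs]
        n_dt = np.zeros((len(docs), T))
        n_tw = np.zeros((T, V))
        n_t = np.zeros(T)
        z = [rng.integers(0, T, size=len(w)) for w in word_ids]
        for d, (w, zd) in enumerate(zip(word_ids, z)):
            for i in range(len(w)):
                n_dt[d, zd[i]] += 1
                n_tw[zd[i], w[i]] += 1
                n_t[zd[i]] += 1

        for _ in range(self.n_iterations):
            for d, (w, zd) in enumerate(zip(word_ids, z)):
                for i in range(len(w)):
                    t_old, wi = zd[i], w[i]
                    n_dt[d, t_old] -= 1
                    n_tw[t_old, wi] -= 1
                    n_t[t_old] -= 1
                    p = (n_dt[d] + alpha) * (n_tw[:, wi] + beta) / (n_t + V * beta)
                    cum = np.cumsum(p)
                    t_new = int(np.searchsorted(cum, rng.random() * cum[-1]))
                    zd[i] = t_new
                    n_dt[d, t_new] += 1
                    n_tw[t_new, wi] += 1
                    n_t[t_new] += 1

        self.alpha_, self.beta_ = alpha, beta
        self.counts_doc_topic_ = n_dt
        self.counts_topic_word_ = n_tw
        self.topic_word_ = (n_tw + beta) / (n_tw + beta).sum(axis=1, keepdims=True)
        wt = (n_tw.T + beta)
        self.word_topic_ = wt / wt.sum(axis=1, keepdims=True)
        return self

    # -- embedding ---------------------------------------------------------

    def doc_topic_vector(self, tokens: Sequence[str]) -> np.ndarray:
        """Topic-simplex embedding of one document.

        word-avg: L1-normalized mean of the in-vocabulary tokens' P(t | w)
        rows; out-of-vocabulary tokens are skipped, and an empty or all-OOV
        document maps to the uniform vector.
        """
        ids = [self.index_[t] for t in tokens if t in self.index_]
        if not ids:
            return np.full(self.n_topics, 1.0 / self.n_topics)
        if self.doc_vector == "word-avg":
            v = self.word_topic_[ids].mean(axis=0)
        else:
            counts = np.zeros(self.n_topics)
            # smoothed proportions from the word-topic posterior mode per token
            for i in ids:
                counts[np.argmax(self.word_topic_[i])] += 1
            v = counts + self.alpha_
        return v / v.sum()

    def transform(self, corpus: Corpus) -> np.ndarray:
        if len(corpus) == 0:
            return np.zeros((0, self.n_topics))
        return np.vstack([self.doc_topic_vector(d.tokens) for d in corpus])


def topic_feature_matrix(model: GibbsLDA, corpus: Corpus) -> FeatureMatrix:
    """Stacked document-topic vectors with the L2 penalty hint."""
    values = model.transform(corpus)
    names = [f"topic:{t}" for t in range(model.n_topics)]
    return FeatureMatrix(values, names, penalty_hint="l2")
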