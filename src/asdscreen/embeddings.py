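"""Distributed document representations: CBoW word vectors and PV-DM
paragraph vectors trained with the full softmax.

The objective is the average log-probability of each target word given its
context window of half-width c,

    (1/N) * sum_i log p(w_i | w_{i-c}, ..., w_{i+c})  ,

with p given by a softmax over the whole vocabulary on scores
``y = W_out @ h``.  The context representation h is the *concatenation* of
the 2c context word input-vectors (order-preserving); in PV-DM mode the
document's paragraph vector is concatenated as a final block, so
K = (2c + 1) * dim.  Positions whose window runs off the document edge are
padded with a zero block.  Training is plain stochastic gradient ascent with
a linearly decaying learning rate, deterministic given the seed.

A full softmax is quadratic in vocabulary size and would not scale to web
corpora, but it is exact and entirely adequate for per-patient form corpora
with vocabularies in the thousands; no hierarchical softmax or negative
sampling approximation is used.

Held-out documents get vectors through :meth:`Doc2Vec.infer`, which runs the
same gradient ascent on a fresh paragraph vector with all word matrices
frozen — test folds therefore never influence the trained words.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .text import Corpus, FeatureMatrix

__all__ = [
    "softmax_prob",
    "softmax_loss_and_grads",
    "Doc2Vec",
    "train_cbow",
    "train_doc2vec",
    "embedding_feature_matrix",
]


def softmax_prob(scores: np.ndarray, target_index: int) -> float:
    """Probability of ``target_index`` under a max-shifted stable softmax."""
    s = np.asarray(scores, dtype=float)
    s = s - s.max()
    e = np.exp(s)
    return float(e[target_index] / e.sum())


def softmax_loss_and_grads(word_out: np.ndarray, h: np.ndarray,
                           target: int) -> tuple[float, np.ndarray, np.ndarray]:
    """Log-probability of the target word and its gradients.

    Returns ``(logp, d logp/d word_out, d logp/d h)`` for scores
    ``y = word_out @ h``.
    """
    y = word_out @ h
    y = y - y.max()
    e = np.exp(y)
    p = e / e.sum()
    logp = float(np.log(p[target]))
    err = -p
    err[target] += 1.0
    return logp, np.outer(err, h), word_out.T @ err


class Doc2Vec(BaseEstimator, TransformerMixin):
    """CBoW / PV-DM embedding model with a full-softmax objective.

    Parameters
    ----------
    dim : int
        Embedding dimensionality (the study found 150 best at its scale;
        synthetic corpora use smaller values).
    window : int
        Context half-width c; the window covers 2c words around the target.
    mode : {"pvdm", "cbow"}
        "pvdm" concatenates a per-document paragraph vector into every
        context (paragraph-vector distributed-memory); "cbow" trains word
        vectors only.
    lr : float
        Initial learning rate, decayed linearly to ~0 over training.
    n_epochs : int
        Passes over the corpus.

    Attributes
    ----------
    word_in_ : (V, dim) input word vectors
    word_out_ : (V, K) output matrix, K = (2c + pvdm) * dim
    para_ : (n_docs, dim) paragraph vectors (pvdm mode)
    trace_ : per-epoch average log-probability of the training objective
    """

    def __init__(self, dim: int = 150, window: int = 5, mode: str = "pvdm",
                 lr: float = 0.025, n_epochs: int = 50, seed: int = 0):
        self.dim = dim
        self.window = window
        self.mode = mode
        self.lr = lr
        self.n_epochs = n_epochs
        self.seed = seed

    # -- construction ------------------------------------------------------

    @property
    def _n_blocks(self) -> int:
        return 2 * self.window + (1 if self.mode == "pvdm" else 0)

    def _context_rep(self, ids: np.ndarray, pos: int,
                     para_vec: np.ndarray | None) -> tuple[np.ndarray, list[int | None]]:
        """Concatenated context vector and the word id feeding each block
        (None for zero pads and the paragraph block)."""
        c, dim = self.window, self.dim
        h = np.zeros(self._n_blocks * dim)
        slots: list[int | None] = [None] * self._n_blocks
        block = 0
        for off in range(-c, c + 1):
            if off == 0:
                continue
            j = pos + off
            if 0 <= j < len(ids):
                h[block * dim:(block + 1) * dim] = self.word_in_[ids[j]]
                slots[block] = int(ids[j])
            block += 1
        if para_vec is not None:
            h[block * dim:(block + 1) * dim] = para_vec
        return h, slots

    def context_representation(self, doc_index: int, position: int) -> np.ndarray:
        """Context vector for a position of a training document."""
        para = self.para_[doc_index] if self.mode == "pvdm" else None
        return self._context_rep(self._train_ids_[doc_index], position, para)[0]

    # -- training ----------------------------------------------------------

    def fit(self, corpus: Corpus, y=None) -> "Doc2Vec":
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.mode not in ("pvdm", "cbow"):
            raise ValueError("mode must be 'pvdm' or 'cbow'")
        docs = corpus.token_lists()
        if not docs or all(len(d) == 0 for d in docs):
            raise ValueError("corpus is empty")
        self.vocabulary_ = sorted({t for d in docs for t in d})
        self.index_ = {w: j for j, w in enumerate(self.vocabulary_)}
        self._train_ids_ = [np.array([self.index_[t] for t in d], dtype=np.int64)
                            for d in docs]
        rng = np.random.default_rng(self.seed)
        V, dim = len(self.vocabulary_), self.dim
        scale = 0.5 / dim
        self.word_in_ = rng.uniform(-scale, scale, size=(V, dim))
        self.word_out_ = rng.uniform(-scale, scale,
                                     size=(V, self._n_blocks * dim))
        self.para_ = (rng.uniform(-scale, scale, size=(len(docs), dim))
                      if self.mode == "pvdm" else None)

        total = self.n_epochs * sum(len(d) for d in self._train_ids_)
        step = 0
        trace = []
        for _ in range(self.n_epochs):
            logp_sum, n_pos = 0.0, 0
            for d, ids in enumerate(self._train_ids_):
                para = self.para_[d] if self.mode == "pvdm" else None
                for i in range(len(ids)):
                    eta = self.lr * max(1e-4, 1.0 - step / total)
                    step += 1
                    h, slots = self._context_rep(ids, i, para)
                    logp, g_out, g_h = softmax_loss_and_grads(
                        self.word_out_, h, int(ids[i]))
                    if not np.isfinite(logp):
                        raise FloatingPointError("objective diverged")
                    self.word_out_ += eta * g_out
                    for b, wid in enumerate(slots):
                        if wid is not None:
                            self.word_in_[wid] += eta * g_h[b * dim:(b + 1) * dim]
                    if para is not None:
                        para += eta * g_h[-dim:]
                    logp_sum += logp
                    n_pos += 1
            trace.append(logp_sum / n_pos)
        self.trace_ = np.array(trace)
        return self

    # -- inference ---------------------------------------------------------

    def infer(self, tokens: Sequence[str], n_steps: int = 50,
              lr: float | None = None, seed: int = 0) -> np.ndarray:
        """Paragraph vector for a new document, word matrices frozen.

        Runs ``n_steps`` passes of gradient ascent on a fresh paragraph
        vector only.  An empty or all-out-of-vocabulary document yields the
        zero vector with a warning.
        """
        if self.mode != "pvdm":
            raise ValueError("inference requires a pvdm model")
        ids = np.array([self.index_[t] for t in tokens if t in self.index_],
                       dtype=np.int64)
        if len(ids) == 0:
            warnings.warn("document has no in-vocabulary tokens; zero vector",
                          stacklevel=2)
            return np.zeros(self.dim)
        rng = np.random.default_rng(seed)
        para = rng.uniform(-0.5 / self.dim, 0.5 / self.dim, size=self.dim)
        eta0 = self.lr if lr is None else lr
        dim = self.dim
        total = n_steps * len(ids)
        step = 0
        for _ in range(n_steps):
            for i in range(len(ids)):
                eta = eta0 * max(1e-4, 1.0 - step / total)
                step += 1
                h, _ = self._context_rep(ids, i, para)
                _, _, g_h = softmax_loss_and_grads(self.word_out_, h, int(ids[i]))
                para += eta * g_h[-dim:]
        return para

    def transform(self, corpus: Corpus, n_steps: int = 50,
                  seed: int = 0) -> np.ndarray:
        """Paragraph vectors for arbitrary documents via :meth:`infer`."""
        return np.vstack([self.infer(d.tokens, n_steps=n_steps, seed=seed)
                          for d in corpus])

    def training_vectors(self) -> np.ndarray:
        """The paragraph vectors learned for the training documents."""
        if self.para_ is None:
            raise ValueError("cbow mode has no paragraph vectors")
        return self.para_.copy()


def train_cbow(corpus: Corpus, dim: int, window: int, lr: float = 0.025,
               n_epochs: int = 50, seed: int = 0) -> Doc2Vec:
    """Fit word vectors with the CBoW objective."""
    return Doc2Vec(dim=dim, window=window, mode="cbow", lr=lr,
                   n_epochs=n_epochs, seed=seed).fit(corpus)


def train_doc2vec(corpus: Corpus, dim: int, window: int, lr: float = 0.025,
                  n_epochs: int = 50, seed: int = 0) -> Doc2Vec:
    """Fit word and paragraph vectors with the PV-DM objective."""
    return Doc2Vec(dim=dim, window=window, mode="pvdm", lr=lr,
                   n_epochs=n_epochs, seed=seed).fit(corpus)


def embedding_feature_matrix(vectors: np.ndarray) -> FeatureMatrix:
    """Paragraph vectors as a FeatureMatrix with the L2 penalty hint."""
    names = [f"d2v:{j}" for j in range(vectors.shape[1])]
    return FeatureMatrix(np.asarray(vectors, dtype=float), names,
                         penalty_hint="l2")
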