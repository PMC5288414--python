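"""Lexical featurization of transcribed form text.

Documents are ordered token lists (lowercased, stop words removed); one
document per patient, all of a patient's forms concatenated.  Three lexical
families are produced: bag-of-words counts, joined bigram+trigram counts, and
tf-idf weights with the smoothed inverse document frequency

    idf(w) = ln( N / (1 + df(w)) ),

where df is the number of documents containing w.  The +1 in the denominator
is kept verbatim, so a term present in every document gets a *negative* idf —
a deliberate property of this weighting, preserved rather than clipped.

Vectorizers follow the scikit-learn estimator protocol: the vocabulary (and
document frequencies) are learned in ``fit`` on training documents only, and
``transform`` projects any documents onto it, so cross-validation folds never
leak test vocabulary into training features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from .stopwords import DEFAULT_STOPWORDS

__all__ = [
    "Document",
    "Corpus",
    "FeatureMatrix",
    "tokenize",
    "extract_ngrams",
    "BagOfWordsVectorizer",
    "TfidfVectorizer",
    "bow_matrix",
    "tf_idf_matrix",
    "combine_features",
]


@dataclass
class Document:
    doc_id: str
    tokens: list[str]
    label: int | None = None


@dataclass
class Corpus:
    documents: list[Document]

    @property
    def n_docs(self) -> int:
        return len(self.documents)

    @property
    def labels(self) -> np.ndarray:
        return np.array([d.label for d in self.documents])

    def token_lists(self) -> list[list[str]]:
        return [d.tokens for d in self.documents]

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __len__(self) -> int:
        return len(self.documents)

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(set(ids)) != len(ids):
            raise ValueError("doc_ids must be unique")

    def subset(self, indices: Sequence[int]) -> "Corpus":
        return Corpus([self.documents[i] for i in indices])


@dataclass
class FeatureMatrix:
    """Documents-by-features matrix plus names and a penalty hint.

    ``penalty_hint`` records which regularizer the classifier should pair
    with this family: L1 for high-dimensional lexical features, L2 for the
    low-dimensional topic/embedding features.
    """

    values: sp.spmatrix | np.ndarray
    feature_names: list[str]
    penalty_hint: str = "l2"

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match column count")
        if self.penalty_hint not in ("l1", "l2"):
            raise ValueError("penalty_hint must be 'l1' or 'l2'")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def tokenize(text: str, stopwords: Iterable[str] | None = None) -> list[str]:
    """Lowercased alphabetic tokens in order, stop words removed.

    Splits on every non-alphabetic character; ``stopwords=None`` uses the
    package's default list of 174 common English words.
    """
    stop = DEFAULT_STOPWORDS if stopwords is None else set(stopwords)
    tokens, current = [], []
    for ch in text.lower():
        if ch.isalpha():
            current.append(ch)
        elif current:
            tokens.append("".join(current))
            current = []
    if current:
        tokens.append("".join(current))
    return [t for t in tokens if t not in stop]


def extract_ngrams(tokens: Sequence[str], n: int, sep: str = "_") -> list[str]:
    """Ordered joined n-grams; length max(0, len(tokens) - n + 1)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [sep.join(tokens[i:i + n]) for i in range(len(tokens) - n + 1)]


def _doc_terms(tokens: Sequence[str], ngram_sizes: tuple[int, ...]) -> list[str]:
    if ngram_sizes == (1,):
        return list(tokens)
    out: list[str] = []
    for n in ngram_sizes:
        out.extend(tokens if n == 1 else extract_ngrams(tokens, n))
    return out


class BagOfWordsVectorizer(BaseEstimator, TransformerMixin):
    """Term-count matrix over a vocabulary learned in ``fit``.

    Parameters
    ----------
    ngram_sizes : tuple of int
        Term units: ``(1,)`` is plain bag-of-words, ``(2, 3)`` the
        bigram+trigram family.
    """

    def __init__(self, ngram_sizes: tuple[int, ...] = (1,)):
        self.ngram_sizes = ngram_sizes

    def fit(self, corpus: Corpus, y=None) -> "BagOfWordsVectorizer":
        terms: set[str] = set()
        for doc in corpus:
            terms.update(_doc_terms(doc.tokens, self.ngram_sizes))
        if not terms:
            raise ValueError("empty vocabulary: no terms in training corpus")
        self.vocabulary_ = sorted(terms)
        self.index_ = {t: j for j, t in enumerate(self.vocabulary_)}
        return self

    def transform(self, corpus: Corpus) -> sp.csr_matrix:
        rows, cols, vals = [], [], []
        for i, doc in enumerate(corpus):
            counts: dict[int, int] = {}
            for term in _doc_terms(doc.tokens, self.ngram_sizes):
                j = self.index_.get(term)
                if j is not None:
                    counts[j] = counts.get(j, 0) + 1
            rows.extend([i] * len(counts))
            cols.extend(counts.keys())
            vals.extend(counts.values())
        return sp.csr_matrix((vals, (rows, cols)),
                             shape=(corpus.n_docs, len(self.vocabulary_)),
                             dtype=float)


class TfidfVectorizer(BaseEstimator, TransformerMixin):
    """tf-idf matrix with idf = ln(N / (1 + df)), fitted on training docs.

    tf is the raw in-document count; no length normalization is applied, and
    negative idf (term present in every training document) is preserved.
    """

    def __init__(self, ngram_sizes: tuple[int, ...] = (1,)):
        self.ngram_sizes = ngram_sizes

    def fit(self, corpus: Corpus, y=None) -> "TfidfVectorizer":
        if corpus.n_docs == 0:
            raise ValueError("cannot fit tf-idf on an empty corpus")
        self.counter_ = BagOfWordsVectorizer(self.ngram_sizes).fit(corpus)
        counts = self.counter_.transform(corpus)
        df = np.asarray((counts > 0).sum(axis=0)).ravel()
        self.idf_ = np.log(corpus.n_docs / (1.0 + df))
        return self

    @property
    def vocabulary_(self) -> list[str]:
        return self.counter_.vocabulary_

    def transform(self, corpus: Corpus) -> sp.csr_matrix:
        counts = self.counter_.transform(corpus)
        return counts.multiply(self.idf_[None, :]).tocsr()


def bow_matrix(corpus: Corpus, vectorizer: BagOfWordsVectorizer | None = None,
               ngram_sizes: tuple[int, ...] = (1,)) -> FeatureMatrix:
    """Bag-of-words (or n-gram) counts as a FeatureMatrix (L1 penalty hint)."""
    if vectorizer is None:
        vectorizer = BagOfWordsVectorizer(ngram_sizes).fit(corpus)
    prefix = "bow" if vectorizer.ngram_sizes == (1,) else "ngram"
    return FeatureMatrix(vectorizer.transform(corpus),
                         [f"{prefix}:{t}" for t in vectorizer.vocabulary_],
                         penalty_hint="l1")


def tf_idf_matrix(corpus: Corpus,
                  vectorizer: TfidfVectorizer | None = None) -> FeatureMatrix:
    """tf-idf weights as a FeatureMatrix (L1 penalty hint)."""
    if vectorizer is None:
        vectorizer = TfidfVectorizer().fit(corpus)
    return FeatureMatrix(vectorizer.transform(corpus),
                         [f"tfidf:{t}" for t in vectorizer.vocabulary_],
                         penalty_hint="l1")


def combine_features(matrices: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Column-wise concatenation of feature families.

    Feature names keep their source prefixes so every column remains
    traceable; the combined family inherits the L1 hint when any member
    carries it (the combined lexical space is high-dimensional).
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    n_rows = {m.shape[0] for m in matrices}
    if len(n_rows) != 1:
        raise ValueError(f"row counts differ: {sorted(n_rows)}")
    if len(matrices) == 1:
        return matrices[0]
    values = sp.hstack([sp.csr_matrix(m.values) for m in matrices]).tocsr()
    names = [name for m in matrices for name in m.feature_names]
    hint = "l1" if any(m.penalty_hint == "l1" for m in matrices) else "l2"
    return FeatureMatrix(values, names, penalty_hint=hint)
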