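"""Synthetic study data with known ground truth.

Two generators stand in for the confidential scanned-form corpus:

* :func:`generate_form_image` renders a page of horizontal text-line bands —
  one of them a full-width separator line below a personal-information
  header — rotates it by a known angle and adds salt-and-pepper noise, so the
  de-skew and de-identification operators can be scored against the exact
  parameters used.

* :func:`generate_corpus` samples labeled two-class documents from
  class-conditional mixtures of topic-word distributions, with a tunable
  divergence between the class vocabularies and the study's 56:143 positive
  to negative imbalance as the default, so featurization, upsampling and the
  classifier have a recoverable statistical structure to be tested on.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .image import rotate_image
from .text import Corpus, Document

__all__ = [
    "FormImageSpec",
    "CorpusSpec",
    "generate_form_image",
    "generate_corpus",
]


@dataclass(frozen=True)
class FormImageSpec:
    """Parameters of one synthetic scanned form."""

    width_px: int = 240
    height_px: int = 320
    n_lines: int = 8
    line_height_px: int = 6
    skew_deg: float = 0.0
    noise_rate: float = 0.0
    marker_row: int = 60
    seed: int = 0

    def validate(self) -> None:
        if abs(self.skew_deg) > 20:
            raise ValueError("|skew_deg| must be <= 20")
        if not 0 <= self.marker_row < self.height_px:
            raise ValueError("marker_row must lie inside the page")
        if not 0.0 <= self.noise_rate < 0.05:
            raise ValueError("noise_rate must lie in [0, 0.05)")
        if self.n_lines < 1:
            raise ValueError("need at least one line")


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of one synthetic labeled two-class corpus.

    ``class_divergence`` controls how far apart the class-conditional word
    distributions sit: 0 makes documents label-independent, large values give
    the classes effectively disjoint vocabularies.  Defaults mirror the study
    conditions: 56 positive and 143 negative patients.
    """

    n_pos: int = 56
    n_neg: int = 143
    vocab_size: int = 60
    doc_length_mean: int = 80
    class_divergence: float = 4.0
    n_topics_true: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_pos + self.n_neg < 2:
            raise ValueError("need at least two documents")
        if self.vocab_size < 10:
            raise ValueError("vocab_size must be >= 10")
        if self.vocab_size < self.n_topics_true:
            raise ValueError("vocab_size must be >= n_topics_true")
        if self.class_divergence < 0:
            raise ValueError("class_divergence must be >= 0")
        if self.doc_length_mean < 1:
            raise ValueError("doc_length_mean must be >= 1")


def generate_form_image(spec: FormImageSpec) -> tuple[np.ndarray, dict]:
    """Render a synthetic form and return it with its ground truth.

    The unrotated page holds ``n_lines`` dark bands: one personal-information
    band above ``marker_row``, the full-width separator line at
    ``marker_row``, and the remaining bands evenly spaced below.  The page is
    then rotated by ``skew_deg`` about its center and each pixel is flipped
    independently with probability ``noise_rate`` (salt and pepper).

    Returns ``(image, ground_truth)`` where ground truth records the skew
    angle, the marker row and the personal-information redaction region.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w, lh = spec.height_px, spec.width_px, spec.line_height_px

    n_above = 1 if spec.marker_row >= 3 * lh else 0
    n_below = spec.n_lines - 1 - n_above
    if n_below < 0:
        raise ValueError("n_lines too small for the layout")
    top = spec.marker_row + 3 * lh
    bottom = h - 2 * lh
    if n_below > 0 and top + n_below * 3 * lh > bottom:
        raise ValueError("lines do not fit on the page")

    page = np.ones((h, w))
    margin = max(2, w // 10)

    def text_band(row: int) -> None:
        # a text line: ~70% of interior columns inked, in word-like runs
        cols = np.arange(margin, w - margin)
        keep = rng.random(cols.size) < 0.85
        run = rng.integers(0, 6, size=cols.size)
        keep &= run > 0  # word gaps
        page[row:row + lh, cols[keep]] = 0.0

    if n_above:
        text_band(max(0, spec.marker_row // 2 - lh // 2))
    page[spec.marker_row:spec.marker_row + lh, :] = 0.0  # separator line
    if n_below > 0:
        rows = np.linspace(top, bottom - lh, n_below).astype(int)
        for r in rows:
            text_band(int(r))

    image = rotate_image(page, spec.skew_deg, binary=True)
    if spec.noise_rate > 0:
        flip = rng.random(image.shape) < spec.noise_rate
        image = np.where(flip, 1.0 - image, image)

    ground_truth = {
        "skew_deg": spec.skew_deg,
        "marker_row": spec.marker_row,
        "redaction_region": {"row_start": 0, "row_end": spec.marker_row,
                             "col_start": 0, "col_end": w},
    }
    return image, ground_truth


def _word_names(n: int) -> list[str]:
    """Purely alphabetic synthetic vocabulary: 'waa', 'wab', ..."""
    letters = string.ascii_lowercase
    width = 1
    while 26 ** width < n:
        width += 1
    names = []
    for i in range(n):
        s, x = [], i
        for _ in range(width):
            s.append(letters[x % 26])
            x //= 26
        names.append("w" + "".join(reversed(s)))
    return names


def _class_topics(base: np.ndarray, half: np.ndarray, gamma: float) -> np.ndarray:
    """Down-weight the opposite class's vocabulary half by exp(-gamma)."""
    tilted = base * np.where(half, 1.0, np.exp(-gamma))
    return tilted / tilted.sum(axis=1, keepdims=True)


def generate_corpus(spec: CorpusSpec) -> tuple[Corpus, dict]:
    """Sample a labeled two-class corpus from class-conditional topic mixtures.

    Shared topic-word distributions are drawn once from a sparse Dirichlet;
    each class then down-weights the other class's half of the vocabulary by
    ``exp(-class_divergence)``.  Every document draws its topic mixture from a
    symmetric Dirichlet(1) and its length from a Poisson, then samples tokens
    i.i.d. topic-then-word.  Positive documents are labeled 1.

    Returns ``(corpus, ground_truth)`` with the per-class marginal word
    distributions and per-class topic-word matrices.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    vocab = _word_names(spec.vocab_size)

    base = rng.dirichlet(np.full(spec.vocab_size, 0.2), size=spec.n_topics_true)
    half_mask = np.arange(spec.vocab_size) < spec.vocab_size // 2
    phi = {0: _class_topics(base, half_mask, spec.class_divergence),
           1: _class_topics(base, ~half_mask, spec.class_divergence)}

    labels = np.array([1] * spec.n_pos + [0] * spec.n_neg)
    docs: list[Document] = []
    for i, label in enumerate(labels):
        theta = rng.dirichlet(np.ones(spec.n_topics_true))
        length = max(1, rng.poisson(spec.doc_length_mean))
        z = rng.choice(spec.n_topics_true, size=length, p=theta)
        tokens = [vocab[rng.choice(spec.vocab_size, p=phi[label][t])] for t in z]
        docs.append(Document(doc_id=f"doc{i:04d}", tokens=tokens, label=int(label)))

    ground_truth = {
        "vocabulary": vocab,
        "topic_word": {c: phi[c] for c in (0, 1)},
        "class_word": {c: phi[c].mean(axis=0) for c in (0, 1)},
    }
    return Corpus(docs), ground_truth
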