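"""Minority-class upsampling by nearest-neighbour interpolation.

The study corpus is imbalanced (56 positive vs 143 negative patients), so
before training the positive class is augmented: for each positive sample,
artificial points are drawn uniformly at random on the segments joining it to
its k nearest positive neighbours (Euclidean distance, self excluded).  Real
rows are never modified and negatives are untouched; augmentation is applied
inside each training fold only, so test folds never contain artificial rows.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator

__all__ = [
    "pairwise_euclidean",
    "nearest_positive_neighbors",
    "synthesize_between",
    "InterpolationUpsampler",
    "upsample",
]


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense() if sp.issparse(X) else X, dtype=float)


def pairwise_euclidean(X: np.ndarray) -> np.ndarray:
    """Symmetric zero-diagonal matrix of Euclidean distances between rows."""
    X = _dense(X)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 points")
    sq = (X * X).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(np.maximum(d2, 0.0))


def nearest_positive_neighbors(X: np.ndarray, k: int) -> np.ndarray:
    """Index table of each row's k nearest other rows.

    Distance ties break toward the smaller index; a row is never its own
    neighbour.
    """
    X = _dense(X)
    m = X.shape[0]
    if k >= m:
        raise ValueError(f"k={k} must be < number of points {m}")
    d = pairwise_euclidean(X)
    np.fill_diagonal(d, np.inf)
    # lexicographic (distance, index) order makes the tie-break explicit
    order = np.lexsort((np.broadcast_to(np.arange(m), (m, m)), d), axis=1)
    return order[:, :k]


def synthesize_between(x: np.ndarray, neighbor: np.ndarray, u: float) -> np.ndarray:
    """Point x + u * (neighbor - x) on the closed segment, u in [0, 1]."""
    if not 0.0 <= u <= 1.0:
        raise ValueError("u must lie in [0, 1]")
    x = np.asarray(x, dtype=float)
    return x + u * (np.asarray(neighbor, dtype=float) - x)


class InterpolationUpsampler(BaseEstimator):
    """Append interpolated artificial positives to a labeled matrix.

    Parameters
    ----------
    n_per_positive : int
        Artificial samples generated per real positive (the study used 2,
        taking 56 positives to 168 against 143 negatives).
    k : int or None
        Neighbour pool size; ``None`` matches ``n_per_positive``.  Each
        artificial sample picks one of the k nearest positive neighbours
        uniformly and a position u ~ Uniform(0, 1) along the segment.
    """

    def __init__(self, n_per_positive: int = 2, k: int | None = None,
                 seed: int = 0):
        self.n_per_positive = n_per_positive
        self.k = k
        self.seed = seed

    def fit_resample(self, X, y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return ``(X_aug, y_aug, provenance)``.

        Real rows come first, bit-identical and in their original order;
        artificial rows (provenance ``"artificial"``, label 1) follow.
        """
        y = np.asarray(y)
        dense = _dense(X)
        if dense.shape[0] != y.shape[0]:
            raise ValueError("X and y row counts differ")
        pos_idx = np.flatnonzero(y == 1)
        if pos_idx.size < 2:
            raise ValueError("need at least 2 positive samples to interpolate")
        k = self.n_per_positive if self.k is None else self.k
        if k < 1:
            raise ValueError("k must be >= 1")
        k = min(k, pos_idx.size - 1)
        Xpos = dense[pos_idx]
        nbrs = nearest_positive_neighbors(Xpos, k)

        rng = np.random.default_rng(self.seed)
        rows = []
        for i in range(Xpos.shape[0]):
            for _ in range(self.n_per_positive):
                j = int(rng.integers(0, k))
                u = float(rng.random())
                rows.append(synthesize_between(Xpos[i], Xpos[nbrs[i, j]], u))
        X_art = np.array(rows) if rows else np.empty((0, dense.shape[1]))
        X_aug = np.vstack([dense, X_art])
        y_aug = np.concatenate([y, np.ones(len(rows), dtype=y.dtype)])
        provenance = np.array(["real"] * len(y) + ["artificial"] * len(rows))
        return X_aug, y_aug, provenance


def upsample(X, y, n_per_positive: int = 2, k: int | None = None,
             seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Functional wrapper over :class:`InterpolationUpsampler`."""
    return InterpolationUpsampler(n_per_positive, k, seed).fit_resample(X, y)
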