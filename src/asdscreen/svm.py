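"""Regularized squared-hinge linear SVMs.

Two objectives over labels y in {-1, +1}:

    L1:  min_w  ||w||_1    + C * sum_i max(0, 1 - y_i w^T x_i)^2
    L2:  min_w  (1/2)w^T w + C * sum_i max(0, 1 - y_i w^T x_i)^2

The L1 form is paired with high-dimensional lexical features (it zeroes
uninformative weights), the L2 form with the low-dimensional topic and
paragraph-vector features.  The solver is monotone proximal gradient descent
(FISTA with a monotone safeguard and backtracking line search): the squared
hinge is convex and differentiable, the L1 term enters through its
soft-threshold proximal map, so every iterate weakly decreases the objective
and the solution matches a generic convex reference optimizer to high
accuracy on small instances.

The decision rule labels a document positive when w^T x >= 0; the tie at
exactly 0 resolves to positive, consistent with the screening goal of
favouring recall.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = ["objective", "SquaredHingeSVM", "top_features"]


def _margins(w, X, y):
    return 1.0 - y * (X @ w)


def objective(w: np.ndarray, X, y: np.ndarray, C: float,
              penalty: str) -> float:
    """Exact value of the selected objective; y must be in {-1, +1}."""
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (-1.0, 1.0)).all():
        raise ValueError("labels must be in {-1, +1}")
    if C <= 0:
        raise ValueError("C must be positive")
    w = np.asarray(w, dtype=float)
    hinge = np.maximum(0.0, _margins(w, X, y))
    loss = C * float(hinge @ hinge)
    if penalty == "l1":
        return float(np.abs(w).sum()) + loss
    if penalty == "l2":
        return 0.5 * float(w @ w) + loss
    raise ValueError("penalty must be 'l1' or 'l2'")


def _soft_threshold(v: np.ndarray, t: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


class SquaredHingeSVM(BaseEstimator, ClassifierMixin):
    """Linear SVM with squared-hinge loss and L1 or L2 regularization.

    Parameters
    ----------
    penalty : {"l1", "l2"}
    C : float
        Loss weight (larger C fits the data harder).
    fit_intercept : bool
        Appends a constant-1 feature, regularized with the rest.
    tol : float
        Relative objective-change stopping threshold.
    max_iter : int
        Proximal-gradient iteration cap.

    Attributes
    ----------
    w_ : weight vector (including the intercept weight when fitted with one)
    objective_path_ : objective value per iteration (non-increasing)
    """

    def __init__(self, penalty: str = "l2", C: float = 1.0,
                 fit_intercept: bool = True, tol: float = 1e-9,
                 max_iter: int = 3000):
        self.penalty = penalty
        self.C = C
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.max_iter = max_iter

    # -- internals ---------------------------------------------------------

    def _augment(self, X):
        if not self.fit_intercept:
            return X
        if sp.issparse(X):
            ones = np.ones((X.shape[0], 1))
            return sp.hstack([sp.csr_matrix(X), sp.csr_matrix(ones)]).tocsr()
        return np.hstack([np.asarray(X, dtype=float),
                          np.ones((X.shape[0], 1))])

    def _smooth(self, w, X, y):
        """Value and gradient of the differentiable part of the objective."""
        m = _margins(w, X, y)
        act = m > 0
        ma = m[act]
        val = self.C * float(ma @ ma)
        r = np.zeros_like(m)
        r[act] = y[act] * ma
        grad = -2.0 * self.C * (X.T @ r)
        grad = np.asarray(grad).ravel()
        if self.penalty == "l2":
            val += 0.5 * float(w @ w)
            grad = grad + w
        return val, grad

    def _pen(self, w):
        return float(np.abs(w).sum()) if self.penalty == "l1" else 0.0

    def _prox(self, v, t):
        return _soft_threshold(v, t) if self.penalty == "l1" else v

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y) -> "SquaredHingeSVM":
        if self.penalty not in ("l1", "l2"):
            raise ValueError("penalty must be 'l1' or 'l2'")
        y01 = np.asarray(y)
        classes = np.unique(y01)
        if classes.size < 2:
            raise ValueError("both classes must be present in training data")
        if not np.isin(classes, (0, 1)).all():
            raise ValueError("labels must be in {0, 1}")
        ypm = np.where(y01 == 1, 1.0, -1.0)
        Xa = self._augment(X)
        d = Xa.shape[1]

        w = np.zeros(d)
        w_prev = w
        v = w.copy()
        F = self._smooth(w, Xa, ypm)[0] + self._pen(w)
        t_mom = 1.0
        step = 1.0
        path = [F]
        stall = 0
        for _ in range(self.max_iter):
            fv, gv = self._smooth(v, Xa, ypm)
            # backtracking on the smooth part
            while True:
                z = self._prox(v - step * gv, step)
                dzv = z - v
                fz = self._smooth(z, Xa, ypm)[0]
                if fz <= fv + gv @ dzv + (dzv @ dzv) / (2 * step) + 1e-12:
                    break
                step *= 0.5
                if step < 1e-18:
                    break
            Fz = fz + self._pen(z)
            # monotone safeguard: keep the better of iterate and candidate
            if Fz <= F:
                w_new, F_new = z, Fz
                t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom * t_mom))
                v = w_new + (t_mom / t_new) * (z - w_new) \
                    + ((t_mom - 1.0) / t_new) * (w_new - w_prev)
                t_mom = t_new
            else:
                # momentum overshot: restart from the incumbent
                w_new, F_new = w, F
                v = w.copy()
                t_mom = 1.0
            w_prev, w = w, w_new
            step *= 1.5  # let the line search re-expand
            path.append(F_new)
            if abs(F - F_new) <= self.tol * max(1.0, abs(F_new)):
                stall += 1
                if stall >= 5:
                    F = F_new
                    break
            else:
                stall = 0
            F = F_new
        self.w_ = w
        self.objective_path_ = np.array(path)
        self.n_features_in_ = Xa.shape[1] - (1 if self.fit_intercept else 0)
        return self

    @property
    def coef_(self) -> np.ndarray:
        return self.w_[:-1] if self.fit_intercept else self.w_

    @property
    def intercept_(self) -> float:
        return float(self.w_[-1]) if self.fit_intercept else 0.0

    def decision_function(self, X) -> np.ndarray:
        Xa = self._augment(X)
        if Xa.shape[1] != self.w_.shape[0]:
            raise ValueError(f"X has {Xa.shape[1]} features, model expects "
                             f"{self.w_.shape[0]}")
        return np.asarray(Xa @ self.w_).ravel()

    def predict(self, X) -> np.ndarray:
        """Label 1 iff w^T x >= 0 (ties resolve positive)."""
        return (self.decision_function(X) >= 0.0).astype(int)


def top_features(weights: np.ndarray, feature_names: list[str],
                 k: int = 10) -> list[tuple[str, float, str]]:
    """Top-k features by absolute weight, with their class association.

    Returns ``(name, weight, sign_class)`` triples sorted by |weight|
    descending, name-ordered on ties; zero weights are omitted (an all-zero
    model yields an empty report) and k larger than the number of nonzero
    weights returns them all.
    """
    w = np.asarray(weights, dtype=float)
    if len(feature_names) != w.shape[0]:
        raise ValueError("feature_names length must match weight vector")
    entries = [(name, float(wt), "positive" if wt > 0 else "negative")
               for name, wt in zip(feature_names, w) if wt != 0.0]
    entries.sort(key=lambda e: (-abs(e[1]), e[0]))
    return entries[:k]
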