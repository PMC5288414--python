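"""Tests for the squared-hinge SVM objective, solver and reports."""

import numpy as np
import pytest
from scipy.optimize import minimize

from asdscreen.svm import SquaredHingeSVM, objective, top_features


def reference_optimum(X, y01, C, penalty):
    """Generic convex reference optimizer (independent of the package's
    proximal-gradient solver): L-BFGS-B, with an exact split-variable
    reformulation w = u - v, u, v >= 0 for the L1 term."""
    ypm = np.where(y01 == 1, 1.0, -1.0)
    d = X.shape[1]
    if penalty == "l2":
        res = minimize(lambda w: objective(w, X, ypm, C, "l2"), np.zeros(d),
                       method="L-BFGS-B",
                       options=dict(maxiter=5000, ftol=1e-15, gtol=1e-12))
        return res.fun

    def f(z):
        w = z[:d] - z[d:]
        m = np.maximum(0.0, 1.0 - ypm * (X @ w))
        return z.sum() + C * (m @ m)

    res = minimize(f, np.zeros(2 * d), method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * d),
                   options=dict(maxiter=10000, ftol=1e-15, gtol=1e-12))
    return res.fun


class TestObjective:
    def test_zero_weights_cost_C_per_sample(self, rng):
        X = rng.normal(size=(7, 3))
        y = np.array([1.0, -1.0, 1.0, 1.0, -1.0, -1.0, 1.0])
        for penalty in ("l1", "l2"):
            assert objective(np.zeros(3), X, y, 2.5, penalty) == \
                pytest.approx(2.5 * 7)

    def test_one_dimensional_margin_example(self):
        X = np.array([[1.0]])
        y = np.array([1.0])
        w = np.array([2.0])
        assert objective(w, X, y, 1.0, "l2") == pytest.approx(2.0)
        assert objective(w, X, y, 1.0, "l1") == pytest.approx(2.0)

    def test_matches_term_by_term_recomputation(self, rng):
        X = rng.normal(size=(9, 4))
        y = np.where(rng.random(9) < 0.5, 1.0, -1.0)
        w = rng.normal(size=4)
        C = 1.7
        hinge = sum(max(0.0, 1.0 - y[i] * (X[i] @ w)) ** 2 for i in range(9))
        assert objective(w, X, y, C, "l1") == \
            pytest.approx(np.abs(w).sum() + C * hinge)
        assert objective(w, X, y, C, "l2") == \
            pytest.approx(0.5 * w @ w + C * hinge)

    def test_bad_labels_rejected(self):
        with pytest.raises(ValueError):
            objective(np.zeros(2), np.ones((2, 2)), np.array([0.0, 1.0]),
                      1.0, "l2")


class TestSolver:
    def test_separable_data_reaches_zero_training_error(self, rng):
        X = np.vstack([rng.normal(loc=+3, size=(20, 2)),
                       rng.normal(loc=-3, size=(20, 2))])
        y = np.array([1] * 20 + [0] * 20)
        clf = SquaredHingeSVM(penalty="l2", C=100.0).fit(X, y)
        assert (clf.predict(X) == y).all()

    def test_objective_path_non_increasing(self, rng):
        X = rng.normal(size=(30, 4))
        y = (rng.random(30) < 0.4).astype(int)
        y[0], y[1] = 0, 1
        for penalty in ("l1", "l2"):
            clf = SquaredHingeSVM(penalty=penalty, C=1.0).fit(X, y)
            assert (np.diff(clf.objective_path_) <= 1e-10).all()

    @pytest.mark.parametrize("penalty", ["l1", "l2"])
    def test_matches_reference_optimizer_on_small_instances(self, penalty):
        """Relative objective gap to an independent convex optimizer stays
        below 1e-3 on 20 random small instances."""
        rng = np.random.default_rng(99)
        for _ in range(20):
            n = int(rng.integers(10, 51))
            d = int(rng.integers(2, 6))
            X = rng.normal(size=(n, d))
            y = (rng.random(n) < 0.5).astype(int)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            C = float(rng.choice([0.1, 1.0, 10.0]))
            clf = SquaredHingeSVM(penalty=penalty, C=C, fit_intercept=False,
                                  tol=1e-12, max_iter=20000).fit(X, y)
            ours = objective(clf.w_, X, np.where(y == 1, 1.0, -1.0), C,
                             penalty)
            ref = reference_optimum(X, y, C, penalty)
            assert ours - ref <= 1e-3 * max(1.0, abs(ref))

    def test_l1_zeroes_noise_features(self, rng):
        """With one informative and many noise features, moderate-C L1
        training drives the noise weights exactly to zero."""
        n = 60
        signal = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        X = np.hstack([signal[:, None] * 2.0, rng.normal(size=(n, 8)) * 0.1])
        y = (signal > 0).astype(int)
        clf = SquaredHingeSVM(penalty="l1", C=1.0, fit_intercept=False,
                              tol=1e-12, max_iter=20000).fit(X, y)
        assert clf.w_[0] != 0.0
        assert np.all(clf.w_[1:] == 0.0)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            SquaredHingeSVM().fit(rng.normal(size=(5, 2)), np.ones(5))


class TestPredict:
    def test_tie_at_zero_resolves_positive(self):
        clf = SquaredHingeSVM(fit_intercept=False)
        clf.w_ = np.array([1.0, 0.0])
        assert clf.predict(np.array([[0.0, 5.0]]))[0] == 1

    def test_negative_margin_predicts_zero(self):
        clf = SquaredHingeSVM(fit_intercept=False)
        clf.w_ = np.array([1.0, 0.0])
        assert clf.predict(np.array([[-3.0, 2.0]]))[0] == 0

    def test_agrees_with_brute_force_sign(self, rng):
        clf = SquaredHingeSVM(fit_intercept=False)
        clf.w_ = rng.normal(size=4)
        X = rng.normal(size=(25, 4))
        expected = [1 if X[i] @ clf.w_ >= 0 else 0 for i in range(25)]
        assert clf.predict(X).tolist() == expected

    def test_dimension_mismatch_rejected(self, rng):
        clf = SquaredHingeSVM(fit_intercept=False)
        clf.w_ = np.zeros(3)
        with pytest.raises(ValueError):
            clf.predict(rng.normal(size=(2, 5)))


class TestTopFeatures:
    def test_ranked_by_absolute_weight_with_sign_class(self):
        report = top_features(np.array([3.0, -5.0, 1.0]),
                              ["fa", "fb", "fc"], k=2)
        assert report == [("fb", -5.0, "negative"), ("fa", 3.0, "positive")]

    def test_all_zero_weights_give_empty_report(self):
        assert top_features(np.zeros(4), list("abcd"), k=10) == []

    def test_matches_exhaustive_sort(self, rng):
        w = rng.normal(size=12)
        names = [f"f{i}" for i in range(12)]
        report = top_features(w, names, k=12)
        expected = sorted(((n, float(v)) for n, v in zip(names, w)),
                          key=lambda e: (-abs(e[1]), e[0]))
        assert [(n, v) for n, v, _ in report] == expected
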