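"""Decoder families against closed-form, brute-force and library oracles."""

import numpy as np
import pytest
from scipy import optimize, stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

import neurogait as ng
from neurogait.classifiers import compare_classifiers, cross_validate
from neurogait.features import FeatureMatrix


def blobs(rng, n=40, sep=6.0, dim=2):
    """Two well-separated isotropic Gaussian clusters."""
    X = np.vstack([rng.normal(0, 1, (n, dim)),
                   rng.normal(sep, 1, (n, dim))])
    y = np.array(["rest"] * n + ["walk"] * n)
    return X, y


class TestFisherLDA:
    def test_symmetric_classes_project_on_separating_axis(self, rng):
        jitter = rng.normal(0, 0.2, (30, 2))
        X = np.vstack([jitter + [-3, 0], jitter + [3, 0]])
        y = np.array(["a"] * 30 + ["b"] * 30)
        v = ng.FisherLDA().fit(X, y).projection_
        assert abs(v[0]) > 0.99 and abs(v[1]) < 0.12

    def test_closed_form_direction_oracle(self):
        """S_w⁻¹(m1−m2) solved directly for two 3-point classes gives a
        direction proportional to (2, 1)."""
        X = np.array([[0, 0], [1, 0], [0, 1], [3, 0], [4, 0], [3, 1]],
                     dtype=float)
        y = np.array(["c1"] * 3 + ["c2"] * 3)
        model = ng.FisherLDA().fit(X, y)
        # oracle: assemble scatter by hand and solve the 2x2 system
        m1, m2 = X[:3].mean(0), X[3:].mean(0)
        sw = sum(np.outer(x - m1, x - m1) for x in X[:3]) \
            + sum(np.outer(x - m2, x - m2) for x in X[3:])
        v_expected = np.linalg.solve(sw, m1 - m2)
        v_expected /= np.linalg.norm(v_expected)
        assert np.allclose(abs(model.projection_), abs(v_expected), atol=1e-12)
        expected_dir = np.array([2.0, 1.0]) / np.sqrt(5.0)
        assert np.allclose(abs(model.projection_), expected_dir, atol=1e-12)

    def test_translation_invariance(self, rng):
        X, y = blobs(rng)
        base = ng.FisherLDA().fit(X, y)
        shifted = ng.FisherLDA().fit(X + [17.0, -4.0], y)
        assert np.allclose(base.projection_, shifted.projection_, atol=1e-9)
        Xq = rng.normal(3, 2, (20, 2))
        assert np.array_equal(base.predict(Xq),
                              shifted.predict(Xq + [17.0, -4.0]))

    def test_agrees_with_sklearn_on_balanced_blobs(self, rng):
        X, y = blobs(rng, n=50, sep=3.0)
        Xq = rng.normal(1.5, 2.5, (200, 2))
        ours = ng.FisherLDA().fit(X, y).predict(Xq)
        theirs = LinearDiscriminantAnalysis().fit(X, y).predict(Xq)
        assert np.mean(ours == theirs) > 0.98

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ng.FisherLDA().fit(np.zeros((4, 2)), np.array(["a"] * 4))


class TestPolynomialSVM:
    def test_separable_training_accuracy(self, rng):
        X, y = blobs(rng)
        model = ng.PolynomialSVM().fit(X, y)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_mirrored_data_mirrors_boundary(self, rng):
        X, y = blobs(rng, sep=4.0)
        Xq = rng.normal(2, 3, (50, 2))
        direct = ng.PolynomialSVM().fit(X, y).predict(Xq)
        flip = {"walk": "rest", "rest": "walk"}
        y_flip = np.array([flip[v] for v in y])
        mirrored = ng.PolynomialSVM().fit(-X, y_flip).predict(-Xq)
        assert np.array_equal(direct, np.array([flip[v] for v in mirrored]))

    def test_duals_match_qp_oracle(self):
        """4-point toy problem: libsvm duals equal an SLSQP solve of the
        dual QP max Σα − ½ Σ α_i α_j y_i y_j K(x_i,x_j) to 1e-4."""
        X = np.array([[0.0, 0.3], [0.4, -0.2], [2.0, 1.1], [2.3, 0.4]])
        y01 = np.array([-1.0, -1.0, 1.0, 1.0])
        y = np.where(y01 > 0, "walk", "rest")
        C = 0.5
        K = (X @ X.T + 1.0) ** 3

        def neg_dual(a):
            return -(a.sum() - 0.5 * a @ (np.outer(y01, y01) * K) @ a)

        cons = {"type": "eq", "fun": lambda a: a @ y01}
        res = optimize.minimize(neg_dual, np.full(4, 0.1), method="SLSQP",
                                bounds=[(0, C)] * 4, constraints=cons,
                                options={"ftol": 1e-14, "maxiter": 500})
        alpha_oracle = res.x
        model = ng.PolynomialSVM(C=C).fit(X, y)
        alpha_fit = np.zeros(4)
        # dual_coef_ holds alpha_i * y_i for the support vectors
        alpha_fit[model.support_] = np.abs(model.dual_coef_[0])
        assert np.allclose(alpha_fit, alpha_oracle, atol=1e-4)


class TestRankKNN:
    def test_training_point_recovers_own_label(self, rng):
        X, y = blobs(rng, n=10)
        model = ng.RankKNN(k=1).fit(X, y)
        assert np.array_equal(model.predict(X), y)

    def test_hand_distances(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0]])
        y = np.array(["A", "B"])
        assert ng.RankKNN(k=1).fit(X, y).predict([[0.2, 0.0]])[0] == "A"

    def test_matches_exhaustive_scan(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.where(rng.random(20) < 0.5, "walk", "rest")
        if len(np.unique(y)) < 2:
            y[0] = "walk" if y[0] == "rest" else "rest"
        queries = rng.normal(size=(5, 3))
        model = ng.RankKNN(k=1).fit(X, y)
        for q in queries:
            best, best_d = None, np.inf
            for xi, yi in zip(X, y):
                d = np.sqrt(((xi - q) ** 2).sum())
                if d < best_d:
                    best, best_d = yi, d
            assert model.predict([q])[0] == best

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            ng.RankKNN(k=1).fit(np.empty((0, 2)), np.array([]))


class TestGaussianQDA:
    def test_equal_covariances_reduce_to_linear_boundary(self, rng):
        cov_jitter = rng.normal(0, 1, (40, 2))
        X = np.vstack([cov_jitter + [0, 0], cov_jitter + [4, 1]])
        y = np.array(["a"] * 40 + ["b"] * 40)
        Xq = rng.normal(2, 2, (300, 2))
        qda = ng.GaussianQDA().fit(X, y).predict(Xq)
        lda = ng.FisherLDA().fit(X, y).predict(Xq)
        assert np.mean(qda == lda) > 0.99

    def test_1d_equal_variance_boundary_at_midpoint(self):
        # empirical moments exactly N(0,1) and N(2,1)
        X = np.array([[-1.0], [1.0], [1.0], [3.0]])
        y = np.array(["a", "a", "b", "b"])
        model = ng.GaussianQDA().fit(X, y)
        assert model.predict([[0.99]])[0] == "a"
        assert model.predict([[1.01]])[0] == "b"

    def test_1d_unequal_variance_analytic_roots(self):
        """N(0,1) vs N(0,4): boundary at x = ±sqrt(8 ln 2 / 3)."""
        X = np.array([[-1.0], [1.0], [-2.0], [2.0]])
        y = np.array(["narrow", "narrow", "wide", "wide"])
        model = ng.GaussianQDA().fit(X, y)
        root = np.sqrt(8.0 * np.log(2.0) / 3.0)
        eps = 1e-3
        for s in (+1, -1):
            assert model.predict([[s * (root - eps)]])[0] == "narrow"
            assert model.predict([[s * (root + eps)]])[0] == "wide"


class TestGaussianNB:
    def test_1d_matches_qda(self):
        X = np.array([[-1.0], [1.0], [-2.0], [2.0]])
        y = np.array(["narrow", "narrow", "wide", "wide"])
        nb = ng.GaussianNB().fit(X, y)
        qda = ng.GaussianQDA().fit(X, y)
        grid = np.linspace(-3, 3, 101)[:, None]
        assert np.array_equal(nb.predict(grid), qda.predict(grid))

    def test_independent_features_add_log_odds(self):
        """Two features, each with a 1-D boundary at 1: the joint log odds
        are the sum of the per-feature log odds."""
        X1 = np.array([[-1.0], [1.0], [1.0], [3.0]])
        y = np.array(["a", "a", "b", "b"])
        one = ng.GaussianNB().fit(X1, y)
        X2 = np.hstack([X1, X1])
        two = ng.GaussianNB().fit(X2, y)
        q = np.array([[0.3]])
        assert two.decision_function(np.hstack([q, q]))[0] == pytest.approx(
            2 * one.decision_function(q)[0], rel=1e-9)

    def test_degenerate_prior_forces_class(self, rng):
        X, y = blobs(rng, n=10)
        model = ng.GaussianNB(priors=(1.0, 0.0)).fit(X, y)
        pred = model.predict(rng.normal(size=(20, 2)))
        assert set(pred) == {model.classes_[0]}


class TestCrossValidation:
    @pytest.mark.parametrize("family", list(ng.classifiers.CLASSIFIER_FAMILIES))
    def test_separable_data_perfect_accuracy(self, family, rng):
        X, y = blobs(rng, n=60, sep=8.0)
        fm = FeatureMatrix(X, y, ("SM", "SS"), np.zeros(len(y)))
        assert cross_validate(family, fm, seed=0).mean_accuracy == 1.0

    def test_permuted_labels_in_null_band(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(200, 2))
            y = np.array(["walk", "rest"] * 100)
            fm = FeatureMatrix(X, y, ("SM", "SS"), np.zeros(200))
            acc = cross_validate("lda", fm, seed=seed).mean_accuracy
            assert 0.35 <= acc <= 0.65

    def test_fold_arithmetic_120_observations(self, hrf_features):
        report = cross_validate("lda", hrf_features, seed=0)
        assert report.fold_accuracies.size == 10
        assert report.confusion.sum() == 120   # ten held-out folds of 12

    def test_bitwise_reproducibility(self, hrf_features):
        a = cross_validate("svm", hrf_features, seed=42)
        b = cross_validate("svm", hrf_features, seed=42)
        assert np.array_equal(a.fold_accuracies, b.fold_accuracies)
        assert a.mean_accuracy == b.mean_accuracy

    def test_too_few_observations_rejected(self):
        fm = FeatureMatrix(np.zeros((5, 1)), np.array(["a"] * 3 + ["b"] * 2),
                           ("SM",), np.zeros(5))
        with pytest.raises(ValueError):
            cross_validate("lda", fm, folds=10)


class TestCompareClassifiers:
    def test_identical_vectors_p_one(self):
        acc = np.full(9, 0.8)
        p = compare_classifiers({"svm": acc, "lda": acc.copy()})
        assert p[("svm", "lda")] == 1.0

    def test_constant_difference_below_resolution(self):
        p = compare_classifiers({"a": np.full(9, 0.9), "b": np.full(9, 0.5)})
        assert p[("a", "b")] == 0.0

    def test_matches_hand_computed_paired_t(self):
        a = np.array([.80, .75, .68, .74, .73, .81, .65, .77, .87])
        b = np.array([.70, .72, .66, .70, .75, .74, .60, .73, .80])
        p = compare_classifiers({"a": a, "b": b})[("a", "b")]
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        expected = 2 * stats.t.sf(abs(t), d.size - 1)
        assert p == pytest.approx(expected, rel=1e-12)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_classifiers({"a": np.ones(9), "b": np.ones(8)})
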