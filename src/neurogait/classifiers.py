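"""Two-class decoders for walk/rest intention, with cross-validation.

Five classifier families are exposed as scikit-learn compatible estimators so
they compose with Pipelines and model selection:

* :class:`FisherLDA` — Fisher discriminant, closed form: projection
  v ∝ S_w⁻¹(m1 − m2) with the pooled within-class scatter, threshold at the
  midpoint of the projected class means.
* :class:`PolynomialSVM` — soft-margin SVM with an inhomogeneous cubic
  kernel (u·v + 1)³ and slack penalty C = 0.5 (libsvm-backed).
* :class:`RankKNN` — k-nearest-neighbour voting by inverse-rank similarity
  of Euclidean distances; k = 1 reduces to nearest neighbour.
* :class:`GaussianQDA` — per-class Gaussian densities with maximum-likelihood
  (1/N) covariances; classify by density ratio against the prior ratio.
* :class:`GaussianNB` — naive Bayes with per-feature class-conditional
  normals and frequency priors.

Degenerate second-moment estimates (singular scatter/covariance, zero
feature variance) fall back to a small logged ridge/floor so the decoders
stay defined on sub-windowed fNIRS features. Distance/posterior ties break
deterministically toward the lowest-index class.

Cross-validation is stratified shuffled 10-fold; min-max rescaling bounds are
recomputed on each training split (scaling inside the CV loop, so held-out
folds never leak into the bounds). ``compare_classifiers`` runs the paired
two-sided tests across subjects used for the multi-classifier comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .features import FeatureMatrix

__all__ = ["FisherLDA", "PolynomialSVM", "RankKNN", "GaussianQDA",
           "GaussianNB", "make_classifier", "CLASSIFIER_FAMILIES",
           "CVReport", "cross_validate", "compare_classifiers"]

logger = logging.getLogger(__name__)

CLASSIFIER_FAMILIES = ("knn", "lda", "qda", "nb", "svm")

_RIDGE_REL = 1e-6


def _ridge_if_singular(m: np.ndarray, context: str) -> np.ndarray:
    """Add eps*trace/dim to the diagonal when ``m`` is (near) singular."""
    d = m.shape[0]
    try:
        np.linalg.cholesky(m + 0.0)
        cond_bad = np.linalg.cond(m) > 1e12
    except np.linalg.LinAlgError:
        cond_bad = True
    if cond_bad:
        eps = _RIDGE_REL * max(np.trace(m) / d, 1e-300)
        logger.warning("singular %s; adding ridge %.3g", context, eps)
        return m + eps * np.eye(d)
    return m


def _encode(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes.size}")
    return classes, np.searchsorted(classes, y)


class FisherLDA(ClassifierMixin, BaseEstimator):
    """Fisher linear discriminant with closed-form projection.

    v = S_w⁻¹(m1 − m2), normalized to unit length; the decision threshold is
    the midpoint of the projected class means, so prediction is
    sign(vᵀx − c). Translation of the whole training set leaves both the
    projection and the predictions unchanged.
    """

    def __init__(self, ridge: bool = True):
        self.ridge = ridge

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, yi = _encode(y)
        X0, X1 = X[yi == 0], X[yi == 1]
        m0, m1 = X0.mean(axis=0), X1.mean(axis=0)
        sw = (X0 - m0).T @ (X0 - m0) + (X1 - m1).T @ (X1 - m1)
        if self.ridge:
            sw = _ridge_if_singular(sw, "within-class scatter")
        elif np.linalg.cond(sw) > 1e12:
            raise np.linalg.LinAlgError("singular within-class scatter")
        v = np.linalg.solve(sw, m0 - m1)
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError("identical class means: no discriminant direction")
        self.projection_ = v / norm
        self.threshold_ = 0.5 * (self.projection_ @ m0 + self.projection_ @ m1)
        self.means_ = np.stack([m0, m1])
        self.scatter_within_ = sw
        return self

    def decision_function(self, X):
        check_is_fitted(self, "projection_")
        X = check_array(X)
        return X @ self.projection_ - self.threshold_

    def predict(self, X):
        # projection points from class 1 toward class 0
        return self.classes_[(self.decision_function(X) < 0).astype(int)]


class PolynomialSVM(ClassifierMixin, BaseEstimator):
    """Soft-margin SVM, cubic inhomogeneous kernel (uᵀv + coef0)³.

    Minimizes ½‖w‖² + C Σ ξ_i in the kernel feature space; C = 0.5 and
    degree 3 by default, gamma = 1 and coef0 = 1 fixed so the kernel is a
    plain inhomogeneous polynomial.
    """

    def __init__(self, C: float = 0.5, degree: int = 3, coef0: float = 1.0,
                 gamma: float = 1.0):
        self.C = C
        self.degree = degree
        self.coef0 = coef0
        self.gamma = gamma

    def _make_svc(self) -> SVC:
        return SVC(C=self.C, kernel="poly", degree=self.degree,
                   coef0=self.coef0, gamma=self.gamma)

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, _ = _encode(y)
        self.svc_ = self._make_svc().fit(X, y)
        self.dual_coef_ = self.svc_.dual_coef_
        self.support_ = self.svc_.support_
        self.intercept_ = self.svc_.intercept_
        return self

    def decision_function(self, X):
        check_is_fitted(self, "svc_")
        return self.svc_.decision_function(check_array(X))

    def predict(self, X):
        check_is_fitted(self, "svc_")
        return self.svc_.predict(check_array(X))


class RankKNN(ClassifierMixin, BaseEstimator):
    """k-nearest-neighbour classification by inverse-rank similarity.

    The k nearest training points (Euclidean) vote with weights equal to the
    inverse of their distance rank (1, 1/2, ..., 1/k); the label with the
    largest summed similarity wins, ties toward the lowest-index class.
    With k = 1 this is plain nearest-neighbour classification.
    """

    def __init__(self, k: int = 1):
        self.k = k

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if self.k > X.shape[0]:
            raise ValueError("k exceeds the training-set size")
        self.classes_, self._yi = _encode(y)
        self.X_ = X
        return self

    def predict(self, X):
        check_is_fitted(self, "X_")
        X = check_array(X)
        out = np.empty(X.shape[0], dtype=int)
        for i, x in enumerate(X):
            d = np.linalg.norm(self.X_ - x, axis=1)
            order = np.argsort(d, kind="stable")[: self.k]
            sim = 1.0 / (1.0 + np.arange(self.k))
            score = np.zeros(2)
            for rank_w, j in zip(sim, order):
                score[self._yi[j]] += rank_w
            out[i] = int(np.argmax(score))   # argmax ties -> lowest index
        return self.classes_[out]


class GaussianQDA(ClassifierMixin, BaseEstimator):
    """Quadratic discriminant: per-class Gaussian densities, ML covariances.

    Classifies by comparing the class-0/class-1 density ratio with the
    inverse prior ratio (equal priors: threshold 1), evaluated in log space.
    """

    def __init__(self, ridge: bool = True, priors: tuple[float, float] | None = None):
        self.ridge = ridge
        self.priors = priors

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, yi = _encode(y)
        d = X.shape[1]
        self.means_, self.covariances_, counts = [], [], []
        for k in (0, 1):
            Xk = X[yi == k]
            if Xk.shape[0] <= d:
                raise ValueError(
                    f"class {self.classes_[k]!r} needs > {d} samples")
            mu = Xk.mean(axis=0)
            cov = (Xk - mu).T @ (Xk - mu) / Xk.shape[0]
            if self.ridge:
                cov = _ridge_if_singular(cov, "class covariance")
            self.means_.append(mu)
            self.covariances_.append(cov)
            counts.append(Xk.shape[0])
        if self.priors is None:
            self.priors_ = np.asarray(counts, dtype=float) / sum(counts)
        else:
            self.priors_ = np.asarray(self.priors, dtype=float)
        return self

    def _log_density(self, X, k):
        mu, cov = self.means_[k], self.covariances_[k]
        diff = X - mu
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            raise np.linalg.LinAlgError("non-positive-definite covariance")
        maha = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(cov), diff)
        return -0.5 * (maha + logdet)

    def decision_function(self, X):
        """Log posterior odds of class 0 over class 1."""
        check_is_fitted(self, "priors_")
        X = check_array(X)
        with np.errstate(divide="ignore"):
            lp = np.log(self.priors_)
        return (self._log_density(X, 0) + lp[0]
                - self._log_density(X, 1) - lp[1])

    def predict(self, X):
        return self.classes_[(self.decision_function(X) < 0).astype(int)]


class GaussianNB(ClassifierMixin, BaseEstimator):
    """Gaussian naive Bayes: independent per-feature class-conditionals.

    Posterior P(class|x) ∝ P(x|class) P(class) with frequency priors (or
    fixed ``priors``); zero-variance features get a relative variance floor.
    """

    def __init__(self, priors: tuple[float, float] | None = None,
                 var_floor: bool = True):
        self.priors = priors
        self.var_floor = var_floor

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, yi = _encode(y)
        self.theta_ = np.stack([X[yi == k].mean(axis=0) for k in (0, 1)])
        self.var_ = np.stack([X[yi == k].var(axis=0) for k in (0, 1)])
        if np.any(self.var_ <= 0):
            if not self.var_floor:
                raise ValueError("zero-variance feature in a class")
            floor = _RIDGE_REL * max(self.var_.max(), 1e-300)
            logger.warning("zero-variance feature; flooring at %.3g", floor)
            self.var_ = np.maximum(self.var_, floor)
        counts = np.array([(yi == 0).sum(), (yi == 1).sum()], dtype=float)
        self.priors_ = (counts / counts.sum() if self.priors is None
                        else np.asarray(self.priors, dtype=float))
        return self

    def _joint_log_likelihood(self, X):
        jll = []
        with np.errstate(divide="ignore"):
            lp = np.log(self.priors_)
        for k in (0, 1):
            ll = -0.5 * (np.log(2 * np.pi * self.var_[k])
                         + (X - self.theta_[k]) ** 2 / self.var_[k]).sum(axis=1)
            jll.append(ll + lp[k])
        return np.stack(jll, axis=1)

    def decision_function(self, X):
        check_is_fitted(self, "priors_")
        X = check_array(X)
        jll = self._joint_log_likelihood(X)
        return jll[:, 0] - jll[:, 1]

    def predict(self, X):
        # >= 0 -> class 0: posterior ties break toward the lowest index
        return self.classes_[(self.decision_function(X) < 0).astype(int)]


def make_classifier(family: str, **kwargs) -> BaseEstimator:
    """Instantiate a classifier family by name."""
    families = {"lda": FisherLDA, "svm": PolynomialSVM, "knn": RankKNN,
                "qda": GaussianQDA, "nb": GaussianNB}
    if family not in families:
        raise ValueError(f"unknown classifier family {family!r}")
    return families[family](**kwargs)


# -------------------------------------------------------------------- CV

@dataclass(frozen=True)
class CVReport:
    """Stratified k-fold cross-validation outcome."""

    family: str
    fold_accuracies: np.ndarray
    confusion: np.ndarray        # 2x2 totals, rows true, cols predicted
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def cross_validate(family: str | BaseEstimator, fm: FeatureMatrix,
                   folds: int = 10, seed: int = 0) -> CVReport:
    """Stratified shuffled k-fold CV with per-training-fold rescaling.

    The min-max bounds are fit on each training split only (clipped on the
    held-out fold), so the rescaling step cannot leak test information.
    """
    if fm.n_observations < folds:
        raise ValueError("fewer observations than folds")
    base = make_classifier(family) if isinstance(family, str) else clone(family)
    name = family if isinstance(family, str) else type(family).__name__
    pipe = Pipeline([("rescale", MinMaxScaler(clip=True)), ("clf", base)])

    classes = np.unique(fm.y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs, conf = [], np.zeros((2, 2), dtype=int)
    for train, test in skf.split(fm.X, fm.y):
        if np.unique(fm.y[train]).size < 2:
            raise ValueError("a class is absent from a training split")
        model = clone(pipe).fit(fm.X[train], fm.y[train])
        pred = model.predict(fm.X[test])
        accs.append(float(np.mean(pred == fm.y[test])))
        for t, p in zip(fm.y[test], pred):
            conf[np.searchsorted(classes, t), np.searchsorted(classes, p)] += 1
    return CVReport(family=str(name), fold_accuracies=np.asarray(accs),
                    confusion=conf, seed=seed)


def compare_classifiers(accuracy_table: dict[str, np.ndarray],
                        test: str = "ttest") -> dict[tuple[str, str], float]:
    """Pairwise two-sided paired tests of per-subject accuracy vectors.

    ``test='ttest'`` uses the paired t-test; ``'wilcoxon'`` the signed-rank
    test. Returns {(family_a, family_b): p_value}. Identical vectors give
    p = 1; zero-variance nonzero differences give p = 0 (degenerate paired
    statistic). Significance is conventionally judged at α = 0.01 after
    Bonferroni correction.
    """
    if test not in ("ttest", "wilcoxon"):
        raise ValueError("test must be 'ttest' or 'wilcoxon'")
    names = list(accuracy_table)
    if len(names) < 2:
        raise ValueError("need at least two classifiers to compare")
    n = {k: np.asarray(v, dtype=float) for k, v in accuracy_table.items()}
    lengths = {v.size for v in n.values()}
    if len(lengths) != 1:
        raise ValueError("accuracy vectors must be aligned by subject")
    if lengths.pop() < 2:
        raise ValueError("need >= 2 subjects")

    out: dict[tuple[str, str], float] = {}
    for a, b in combinations(names, 2):
        diff = n[a] - n[b]
        if np.allclose(diff, 0):
            p = 1.0
        elif np.ptp(diff) == 0:
            p = 0.0          # constant nonzero difference: below resolution
        elif test == "ttest":
            p = float(stats.ttest_rel(n[a], n[b]).pvalue)
        else:
            p = float(stats.wilcoxon(n[a], n[b]).pvalue)
        out[(a, b)] = p
    return out
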