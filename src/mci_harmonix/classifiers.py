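"""The five retained classifier families behind a uniform fit/predict contract.

Families and their tunable hyperparameter spaces:

1. naive Bayes — distribution 'normal' or 'kernel'; kernel smoother 'box',
   'epanechnikov', 'normal' or 'triangle'; positive smoothing window width
   (searched as a log-scaled multiplier of the per-feature Silverman width);
2. k-nearest neighbors — neighbors in [5, 30]; one of 11 distance functions;
3. SVM — kernel 'gaussian'/'rbf' (aliases), 'linear' or 'polynomial'; kernel
   scale and box constraint in [0.1, 10];
4. logistic regression with lasso regularization — lambda in [1e-3, 10];
   a monotone score transformation applied to reported scores only;
5. RUSBoost — boosting with per-cycle random undersampling of the majority
   class: ensemble cycles, shrinkage learning rate in (0, 1], max splits.

Class imbalance is compensated (for every family except RUSBoost) with the
misclassification-cost matrix [[0, 1], [delta, 0]], realized as class weights
w_minority = delta, w_majority = 1: at training time where the backend
supports weighted losses (SVM, logistic), and exactly at decision time via
the weighted-risk Bayes rule for the probabilistic families (NB, KNN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.dummy import DummyClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "kernel_density",
    "KernelNaiveBayes",
    "RUSBoostClassifier",
    "LogisticLasso",
    "KNNClassifier",
    "ClassifierSpec",
    "hyperparameter_space",
    "make_classifier",
    "apply_cost_matrix",
    "predict_scores",
    "CLASSIFIER_FAMILIES",
]

CLASSIFIER_FAMILIES = ("naive_bayes", "knn", "svm", "logistic", "rusboost")

_KERNELS = ("box", "epanechnikov", "normal", "triangle")

KNN_METRICS = (
    "cityblock", "chebychev", "correlation", "cosine", "euclidean",
    "hamming", "jaccard", "mahalanobis", "minkowski", "seuclidean", "spearman",
)

_VARIANCE_FLOOR = 1e-9


# ---------------------------------------------------------------------------
# Kernel density primitives
# ---------------------------------------------------------------------------


def _kernel_fn(u: np.ndarray, kernel: str) -> np.ndarray:
    if kernel == "normal":
        return np.exp(-0.5 * u**2) / math.sqrt(2 * math.pi)
    if kernel == "box":
        return 0.5 * (np.abs(u) <= 1)
    if kernel == "triangle":
        return np.maximum(0.0, 1.0 - np.abs(u))
    if kernel == "epanechnikov":
        return 0.75 * np.maximum(0.0, 1.0 - u**2)
    raise ValueError(f"unknown kernel {kernel!r}; choose from {_KERNELS}")


def kernel_density(train, kernel: str, width: float, query) -> np.ndarray:
    """Univariate KDE: density(x) = (1/(n*w)) * sum_i K((x - x_i)/w)."""
    if width <= 0:
        raise ValueError("kernel width must be positive")
    x = np.asarray(train, dtype=float)
    if x.size == 0:
        raise ValueError("kernel_density requires at least one training value")
    q = np.atleast_1d(np.asarray(query, dtype=float))
    u = (q[:, None] - x[None, :]) / width
    dens = _kernel_fn(u, kernel).sum(axis=1) / (x.size * width)
    return dens if dens.size > 1 else float(dens[0])


def _silverman_width(x: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth, robust to near-constant samples."""
    n = x.size
    sd = x.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    if spread <= 0:
        spread = max(abs(x).max(), 1.0) * 1e-3
    return 0.9 * spread * n ** (-0.2)


# ---------------------------------------------------------------------------
# Kernel / Gaussian naive Bayes
# ---------------------------------------------------------------------------


class KernelNaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes with Gaussian or kernel-smoothed class-conditional densities.

    Parameters
    ----------
    distribution : {'normal', 'kernel'}
    kernel : {'box', 'epanechnikov', 'normal', 'triangle'}
        Smoother used when distribution='kernel'.
    width : float, optional
        Absolute smoothing window applied to every feature; default derives a
        per-class, per-feature Silverman width.
    width_scale : float
        Multiplier on the derived width (the tuned hyperparameter).
    class_weight : dict, optional
        Misclassification-cost weights applied through the Bayes decision rule
        (posterior of class c is weighted by class_weight[c] at argmax time).
    """

    def __init__(
        self,
        distribution: str = "normal",
        kernel: str = "normal",
        width: float | None = None,
        width_scale: float = 1.0,
        class_weight: dict | None = None,
    ):
        self.distribution = distribution
        self.kernel = kernel
        self.width = width
        self.width_scale = width_scale
        self.class_weight = class_weight

    def fit(self, X, y):
        if self.distribution not in ("normal", "kernel"):
            raise ValueError("distribution must be 'normal' or 'kernel'")
        if self.kernel not in _KERNELS:
            raise ValueError(f"kernel must be one of {_KERNELS}")
        if self.width is not None and self.width <= 0:
            raise ValueError("width must be positive")
        if self.width_scale <= 0:
            raise ValueError("width_scale must be positive")
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite features")
        y = np.asarray(y)
        self.classes_, counts = np.unique(y, return_counts=True)
        if np.any(counts < 2):
            raise ValueError("each class requires >= 2 training samples")
        self.class_prior_ = counts / counts.sum()
        self.n_features_in_ = X.shape[1]
        feat_var = X.var(axis=0, ddof=1)
        self.theta_, self.var_, self.train_, self.widths_ = {}, {}, {}, {}
        for c in self.classes_:
            Xc = X[y == c]
            if self.distribution == "normal":
                self.theta_[c] = Xc.mean(axis=0)
                self.var_[c] = np.maximum(
                    Xc.var(axis=0, ddof=1), _VARIANCE_FLOOR * np.maximum(feat_var, 1.0)
                )
            else:
                self.train_[c] = Xc
                if self.width is not None:
                    w = np.full(X.shape[1], float(self.width))
                else:
                    w = np.array([_silverman_width(Xc[:, j]) for j in range(X.shape[1])])
                self.widths_[c] = w * self.width_scale
        return self

    def _joint_log_likelihood(self, X):
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite features")
        jll = np.empty((X.shape[0], len(self.classes_)))
        for k, c in enumerate(self.classes_):
            if self.distribution == "normal":
                mu, var = self.theta_[c], self.var_[c]
                ll = -0.5 * (np.log(2 * np.pi * var) + (X - mu) ** 2 / var).sum(axis=1)
            else:
                ll = np.zeros(X.shape[0])
                Xc, w = self.train_[c], self.widths_[c]
                for j in range(X.shape[1]):
                    d = kernel_density(Xc[:, j], self.kernel, w[j], X[:, j])
                    ll += np.log(np.maximum(np.atleast_1d(d), 1e-300))
            jll[:, k] = np.log(self.class_prior_[k]) + ll
        return jll

    def predict_log_proba(self, X):
        jll = self._joint_log_likelihood(X)
        norm = np.logaddexp.reduce(jll, axis=1, keepdims=True)
        return jll - norm

    def predict_proba(self, X):
        return np.exp(self.predict_log_proba(X))

    def predict(self, X):
        check_is_fitted(self, "classes_")
        jll = self._joint_log_likelihood(X)
        if self.class_weight:
            for k, c in enumerate(self.classes_):
                jll[:, k] += np.log(self.class_weight.get(c, 1.0))
        return self.classes_[np.argmax(jll, axis=1)]


# ---------------------------------------------------------------------------
# RUSBoost
# ---------------------------------------------------------------------------


class RUSBoostClassifier(BaseEstimator, ClassifierMixin):
    """Boosting for imbalanced data: random undersampling + AdaBoost updates.

    Each cycle draws all minority samples plus an equal-size uniform sample of
    the majority class, fits a depth-limited decision tree on the subset with
    the current boosting weights, then applies the AdaBoost.M1 weight update
    (shrunk by ``learning_rate``) computed on the full training set. Because
    each learner is trained on a balanced subsample, no misclassification-cost
    compensation is applied to this family.
    """

    def __init__(
        self,
        n_estimators: int = 100,
        learning_rate: float = 0.1,
        max_splits: int = 16,
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.max_splits = max_splits
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must lie in (0, 1]")
        if self.max_splits < 1:
            raise ValueError("max_splits must be >= 1")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        rng = np.random.default_rng(self.random_state)
        self.classes_, counts = np.unique(y, return_counts=True)
        minority = self.classes_[np.argmin(counts)]
        min_idx = np.where(y == minority)[0]
        maj_idx = np.where(y != minority)[0]
        n = len(y)
        w = np.full(n, 1.0 / n)
        self.estimators_, self.estimator_weights_ = [], []
        for t in range(self.n_estimators):
            take = rng.choice(maj_idx, size=len(min_idx), replace=False)
            sub = np.concatenate([min_idx, take])
            tree = DecisionTreeClassifier(
                max_leaf_nodes=self.max_splits + 1,
                random_state=int(rng.integers(2**31 - 1)),
            )
            sw = w[sub]
            tree.fit(X[sub], y[sub], sample_weight=sw / sw.sum())
            pred = tree.predict(X)
            wrong = pred != y
            err = float(w[wrong].sum() / w.sum())
            if err <= 0:
                self.estimators_.append(tree)
                self.estimator_weights_.append(self.learning_rate * 0.5 * math.log(1e10))
                break
            if err >= 0.5:
                if not self.estimators_:
                    # keep one weak learner so predict is defined
                    self.estimators_.append(tree)
                    self.estimator_weights_.append(1e-3)
                break
            alpha = self.learning_rate * 0.5 * math.log((1 - err) / err)
            self.estimators_.append(tree)
            self.estimator_weights_.append(alpha)
            w *= np.exp(alpha * wrong)
            w /= w.sum()
        return self

    def decision_function(self, X):
        check_is_fitted(self, "estimators_")
        X = np.asarray(X, dtype=float)
        pos = self.classes_[-1]  # lexicographically last (uHC after HC)
        score = np.zeros(X.shape[0])
        for tree, alpha in zip(self.estimators_, self.estimator_weights_):
            score += alpha * np.where(tree.predict(X) == pos, 1.0, -1.0)
        return score / max(sum(self.estimator_weights_), 1e-12)

    def predict(self, X):
        score = self.decision_function(X)
        return np.where(score > 0, self.classes_[-1], self.classes_[0])

    def predict_proba(self, X):
        s = self.decision_function(X)  # in [-1, 1]
        p_pos = 0.5 * (s + 1.0)
        return np.column_stack([1.0 - p_pos, p_pos])


# ---------------------------------------------------------------------------
# Logistic lasso and KNN wrappers
# ---------------------------------------------------------------------------


class LogisticLasso(BaseEstimator, ClassifierMixin):
    """L1-regularized logistic regression parameterized by the average-loss
    penalty strength lambda (C = 1 / (n * lambda) at fit time).

    ``score_transform`` is monotone and cannot change predicted labels; it is
    applied only to reported scores.
    """

    _TRANSFORMS = ("none", "logit", "invlogit", "doublelogit")

    def __init__(
        self,
        lam: float = 1.0,
        score_transform: str = "none",
        class_weight: dict | None = None,
        max_iter: int = 1000,
    ):
        self.lam = lam
        self.score_transform = score_transform
        self.class_weight = class_weight
        self.max_iter = max_iter

    def fit(self, X, y):
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.score_transform not in self._TRANSFORMS:
            raise ValueError(f"score_transform must be one of {self._TRANSFORMS}")
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        self.model_ = LogisticRegression(
            l1_ratio=1.0,
            C=1.0 / (n * self.lam),
            solver="liblinear",
            class_weight=self.class_weight,
            max_iter=self.max_iter,
        )
        self.model_.fit(X, y)
        self.classes_ = self.model_.classes_
        self.coef_ = self.model_.coef_
        self.intercept_ = self.model_.intercept_
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(X)

    def predict_proba(self, X):
        return self.model_.predict_proba(X)

    def decision_function(self, X):
        raw = self.model_.decision_function(X)
        if self.score_transform == "none":
            return raw
        p = 1.0 / (1.0 + np.exp(-raw))
        if self.score_transform == "invlogit":
            return p
        if self.score_transform == "doublelogit":
            return 1.0 / (1.0 + np.exp(-2.0 * raw))
        return raw  # 'logit' of invlogit(raw) is raw itself


class KNNClassifier(BaseEstimator, ClassifierMixin):
    """K-nearest neighbors with the full menu of distance functions.

    'correlation', 'cosine' and 'spearman' are handled via transforms to a
    Euclidean-compatible representation or native scipy metrics; 'hamming' and
    'jaccard' operate on features binarized at their training medians, since
    set-type distances are undefined on continuous volumes. Cost weighting is
    applied at decision time to the neighbor-vote posterior.
    """

    def __init__(
        self,
        n_neighbors: int = 5,
        metric: str = "euclidean",
        class_weight: dict | None = None,
    ):
        self.n_neighbors = n_neighbors
        self.metric = metric
        self.class_weight = class_weight

    def _build(self, X):
        m = self.metric
        kw: dict = {}
        if m == "cityblock":
            name = "manhattan"
        elif m == "chebychev":
            name = "chebyshev"
        elif m == "minkowski":
            name, kw = "minkowski", {"p": 3}
        elif m == "seuclidean":
            name = "seuclidean"
            kw = {"metric_params": {"V": np.maximum(X.var(axis=0), 1e-12)}}
        elif m == "mahalanobis":
            name = "mahalanobis"
            cov = np.cov(X, rowvar=False) + 1e-6 * np.eye(X.shape[1])
            kw = {"metric_params": {"VI": np.linalg.inv(cov)}}
        elif m in ("correlation", "cosine"):
            name = m
        elif m in ("hamming", "jaccard", "spearman", "euclidean"):
            name = "euclidean" if m == "spearman" else m
            if m in ("hamming", "jaccard"):
                name = m
        else:
            raise ValueError(f"unknown metric {self.metric!r}; choose from {KNN_METRICS}")
        params = {"n_neighbors": self.n_neighbors, "metric": name, "algorithm": "brute"}
        if "p" in kw:
            params["p"] = kw["p"]
        if "metric_params" in kw:
            params["metric_params"] = kw["metric_params"]
        return KNeighborsClassifier(**params)

    def _transform(self, X):
        X = np.asarray(X, dtype=float)
        if self.metric in ("hamming", "jaccard"):
            return (X > self.medians_).astype(float)
        if self.metric == "spearman":
            # rank against the training sample, giving a Spearman-style geometry
            ranks = np.column_stack([
                np.searchsorted(self.sorted_train_[j], X[:, j], side="left")
                for j in range(X.shape[1])
            ])
            return ranks.astype(float)
        return X

    def fit(self, X, y):
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        X = np.asarray(X, dtype=float)
        self.medians_ = np.median(X, axis=0)
        self.sorted_train_ = np.sort(X, axis=0).T
        Xt = self._transform(X)
        self.knn_ = self._build(Xt)
        self.knn_.fit(Xt, y)
        self.classes_ = self.knn_.classes_
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "knn_")
        import warnings as _warnings

        with _warnings.catch_warnings():
            # inputs for jaccard/hamming are already deliberately binarized
            _warnings.filterwarnings("ignore", message=".*converted to boolean.*")
            return self.knn_.predict_proba(self._transform(X))

    def predict(self, X):
        proba = self.predict_proba(X)
        if self.class_weight:
            w = np.array([self.class_weight.get(c, 1.0) for c in self.classes_])
            proba = proba * w
        return self.classes_[np.argmax(proba, axis=1)]


# ---------------------------------------------------------------------------
# Specs, spaces, factory
# ---------------------------------------------------------------------------


@dataclass
class ClassifierSpec:
    """A classifier family plus its search space and misclassification costs."""

    family: str
    space: list[dict] = field(default_factory=list)
    delta: float = 1.0  # cost of (true minority, predicted majority) errors

    def __post_init__(self):
        if self.family not in CLASSIFIER_FAMILIES + ("majority",):
            raise ValueError(f"unknown family {self.family!r}")
        if not self.space:
            self.space = hyperparameter_space(self.family)
        if self.delta <= 0:
            raise ValueError("delta must be positive")


def hyperparameter_space(family: str) -> list[dict]:
    """The declared search space of each family.

    Each entry: name, kind ('real'|'integer'|'categorical'), and either
    (low, high, log) bounds or a category list.
    """
    if family == "naive_bayes":
        return [
            {"name": "distribution", "kind": "categorical", "categories": ["normal", "kernel"]},
            {"name": "kernel", "kind": "categorical", "categories": list(_KERNELS)},
            {"name": "width_scale", "kind": "real", "low": 1e-2, "high": 1e2, "log": True},
        ]
    if family == "knn":
        return [
            {"name": "n_neighbors", "kind": "integer", "low": 5, "high": 30, "log": False},
            {"name": "metric", "kind": "categorical", "categories": list(KNN_METRICS)},
        ]
    if family == "svm":
        return [
            {"name": "kernel", "kind": "categorical",
             "categories": ["gaussian", "rbf", "linear", "polynomial"]},
            {"name": "kernel_scale", "kind": "real", "low": 0.1, "high": 10.0, "log": True},
            {"name": "box_constraint", "kind": "real", "low": 0.1, "high": 10.0, "log": True},
        ]
    if family == "logistic":
        return [
            {"name": "lam", "kind": "real", "low": 1e-3, "high": 10.0, "log": True},
            {"name": "score_transform", "kind": "categorical",
             "categories": ["none", "logit", "invlogit", "doublelogit"]},
        ]
    if family == "rusboost":
        return [
            {"name": "n_estimators", "kind": "integer", "low": 10, "high": 300, "log": True},
            {"name": "learning_rate", "kind": "real", "low": 0.01, "high": 1.0, "log": True},
            {"name": "max_splits", "kind": "integer", "low": 1, "high": 64, "log": True},
        ]
    if family == "majority":
        return []
    raise ValueError(f"unknown family {family!r}")


def validate_hyperparams(space: list[dict], params: dict) -> None:
    by_name = {p["name"]: p for p in space}
    for name, value in params.items():
        if name not in by_name:
            raise ValueError(f"unknown hyperparameter {name!r}")
        p = by_name[name]
        if p["kind"] == "categorical":
            if value not in p["categories"]:
                raise ValueError(f"{name}={value!r} not in {p['categories']}")
        else:
            if not p["low"] <= value <= p["high"]:
                raise ValueError(
                    f"{name}={value} violates bound [{p['low']}, {p['high']}]"
                )


def apply_cost_matrix(spec: ClassifierSpec, delta: float) -> ClassifierSpec:
    """Return a spec with cost matrix [[0, 1], [delta, 0]].

    delta = 1 reproduces the default (cost-neutral) matrix. RUSBoost specs are
    returned unchanged: its per-cycle undersampling already balances training.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if spec.family == "rusboost":
        return ClassifierSpec(spec.family, spec.space, 1.0)
    return ClassifierSpec(spec.family, spec.space, delta)


def _class_weights(delta: float, minority: str = "uHC", majority: str = "HC") -> dict | None:
    if delta == 1.0:
        return None
    return {minority: delta, majority: 1.0}


def make_classifier(spec: ClassifierSpec, hyperparams: dict | None = None, seed: int = 0):
    """Instantiate a fitted-model handle for the given family and hyperparameters.

    Out-of-space values are rejected with the violated bound named. Families
    whose geometry depends on feature scale (knn, svm, logistic) are wrapped
    in a standardization pipeline.
    """
    params = dict(hyperparams or {})
    validate_hyperparams(spec.space, params)
    cw = _class_weights(spec.delta)
    family = spec.family
    if family == "naive_bayes":
        return KernelNaiveBayes(class_weight=cw, **params)
    if family == "knn":
        clf = KNNClassifier(class_weight=cw, **params)
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])
    if family == "svm":
        kernel = params.pop("kernel", "gaussian")
        scale = params.pop("kernel_scale", 1.0)
        box = params.pop("box_constraint", 1.0)
        if kernel in ("gaussian", "rbf"):
            svc = SVC(kernel="rbf", gamma=1.0 / scale**2, C=box, class_weight=cw,
                      random_state=seed)
        elif kernel == "linear":
            svc = SVC(kernel="linear", C=box, class_weight=cw, random_state=seed)
        else:
            svc = SVC(kernel="poly", degree=3, gamma=1.0 / scale**2, C=box,
                      class_weight=cw, random_state=seed)
        return Pipeline([("scale", StandardScaler()), ("clf", svc)])
    if family == "logistic":
        clf = LogisticLasso(class_weight=cw, **params)
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])
    if family == "rusboost":
        return RUSBoostClassifier(random_state=seed, **params)
    if family == "majority":
        return DummyClassifier(strategy="most_frequent")
    raise ValueError(f"unknown family {family!r}")


def predict_scores(model, X, positive_class: str = "uHC") -> np.ndarray:
    """Continuous score for the positive class, for ROC analysis."""
    est = model.named_steps["clf"] if isinstance(model, Pipeline) else model
    if hasattr(est, "predict_proba") and not isinstance(est, SVC):
        proba = model.predict_proba(X)
        classes = list(est.classes_)
        return np.asarray(proba)[:, classes.index(positive_class)]
    raw = model.decision_function(X)
    classes = list(est.classes_)
    # decision_function is oriented toward classes_[1]
    return raw if classes[1] == positive_class else -raw
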