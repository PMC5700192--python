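"""Uniform interface over the four base learners with probability outputs.

The four classifier families compared by the pipeline are a linear SVM
(with a monotone Platt-style probability calibration), a random forest, an
l1-penalized (lasso) logistic regression and the strong-hierarchy
interaction logistic regression of :mod:`ppiface.hierarchy`.

Default per-method treatments mirror the study design: the linear SVM is
trained on the 18 standardized features inside the balanced-subset ensemble
(no expansion); the random forest is trained directly on the raw imbalanced
18-feature data (no ensemble, no expansion); both logistic variants are
trained on the 243 expanded features inside the balanced-subset ensemble.
Those treatments are wired up in :mod:`ppiface.workflows`; this module only
provides the learners themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC
from sklearn.utils.validation import check_is_fitted, check_X_y

from .hierarchy import HierarchyLogisticClassifier

KINDS = ("linear_svm", "random_forest", "lasso_logistic", "hierarchy_logistic")


class UnsupportedModelOperation(ValueError):
    """Requested introspection is not defined for this learner."""


@dataclass
class BaseLearnerSpec:
    """Declarative description of one base learner.

    ``hyperparams`` are passed to the underlying estimator; ``seed`` feeds
    every stochastic component, so fits are deterministic.
    """

    kind: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown learner kind {self.kind!r}; choose from {KINDS}")


class CalibratedLinearSVM(ClassifierMixin, BaseEstimator):
    """Linear SVM with a monotone sigmoid map from margin to probability.

    The calibration is fitted on the training margins; because the map is
    monotone increasing in the margin, ranking by probability equals ranking
    by margin (the binding requirement for top-k evaluation).
    """

    def __init__(self, C: float = 1.0, max_iter: int = 5000, random_state: int | None = None):
        self.C = C
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("y must be binary with both classes present")
        self.svm_ = LinearSVC(
            C=self.C, max_iter=self.max_iter, random_state=self.random_state
        ).fit(X, y)
        margins = self.svm_.decision_function(X)
        cal = LogisticRegression(C=np.inf, max_iter=1000).fit(
            margins[:, None], y
        )
        # orient so larger margin => larger probability
        self.slope_ = abs(float(cal.coef_[0, 0]))
        self.offset_ = float(cal.intercept_[0])
        return self

    def decision_function(self, X):
        check_is_fitted(self, "svm_")
        return self.svm_.decision_function(X)

    def predict_proba(self, X):
        p = expit(self.offset_ + self.slope_ * self.decision_function(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return self.svm_.predict(X)


class LassoLogistic(ClassifierMixin, BaseEstimator):
    """l1-penalized logistic regression parameterized by the penalty weight.

    Minimizes ``-(1/n) loglik + lam * ||beta||_1`` (intercept unpenalized;
    saga solver), i.e. scikit-learn's ``C = 1 / (n * lam)``.
    """

    def __init__(self, lam: float = 0.01, max_iter: int = 3000, tol: float = 1e-7,
                 random_state: int | None = None):
        self.lam = lam
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("y must be binary with both classes present")
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        C = 1.0 / (len(y) * self.lam)
        self.model_ = LogisticRegression(
            l1_ratio=1.0, C=C, solver="saga", max_iter=self.max_iter,
            tol=self.tol, random_state=self.random_state,
        ).fit(X, y)
        if np.all(self.model_.coef_ == 0.0):
            # exact optimum of the intercept-only model (saga stalls when the
            # penalty wipes out every coefficient)
            rate = np.clip((y == self.classes_[1]).mean(), 1e-12, 1 - 1e-12)
            self.model_.intercept_ = np.array([np.log(rate / (1 - rate))])
        self.coef_ = self.model_.coef_
        self.intercept_ = self.model_.intercept_
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(X)

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(X)


def make_classifier(spec: BaseLearnerSpec) -> BaseEstimator:
    """Instantiate the (unfitted) estimator a spec describes."""
    hp = dict(spec.hyperparams)
    if spec.kind == "linear_svm":
        return CalibratedLinearSVM(random_state=spec.seed, **hp)
    if spec.kind == "random_forest":
        hp.setdefault("n_estimators", 500)
        hp.setdefault("max_features", "sqrt")
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **hp)
    if spec.kind == "lasso_logistic":
        return LassoLogistic(random_state=spec.seed, **hp)
    if spec.kind == "hierarchy_logistic":
        return HierarchyLogisticClassifier(random_state=spec.seed, **hp)
    raise ValueError(spec.kind)


def fit(spec: BaseLearnerSpec, X, y) -> BaseEstimator:
    """Fit a fresh estimator described by ``spec``; deterministic given seed."""
    if len(np.unique(y)) != 2:
        raise ValueError("y must be binary with both classes present")
    return make_classifier(spec).fit(X, y)


def positive_proba(model, X) -> np.ndarray:
    """Positive-class probability vector of any fitted learner."""
    proba = model.predict_proba(X)
    return np.asarray(proba)[:, 1]


def selected_variables(model, zero_tol: float = 1e-8):
    """Terms a fitted model deems relevant.

    Penalized models return the set of nonzero terms (``main:i`` and, for
    the hierarchy model, ``int:i:j``; 1-based).  Random forests return a
    dict mapping every term to its impurity importance.  Linear SVMs do not
    support variable selection.
    """
    if isinstance(model, HierarchyLogisticClassifier):
        return model.selected_terms()
    if isinstance(model, LassoLogistic):
        coefs = np.ravel(model.coef_)
        return {f"main:{i + 1}" for i in np.flatnonzero(np.abs(coefs) > zero_tol)}
    if isinstance(model, RandomForestClassifier):
        return {
            f"main:{i + 1}": float(v)
            for i, v in enumerate(model.feature_importances_)
        }
    raise UnsupportedModelOperation(
        f"{type(model).__name__} does not support variable selection"
    )


def clone_with_seed(model: BaseEstimator, seed: int) -> BaseEstimator:
    """Fresh unfitted copy of ``model`` with its random_state set to seed."""
    new = clone(model)
    if "random_state" in new.get_params():
        new.set_params(random_state=seed)
    return new
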