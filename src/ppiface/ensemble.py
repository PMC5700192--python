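"""Balanced-subset ensemble training (EasyEnsemble), probability
aggregation, and stability selection.

True interface pairs are a tiny fraction of all candidate pairs (P is of
order 1e-3), so a single fit on the raw data is dominated by the negative
class.  The ensemble trains one base learner per *balanced subset* — all
positive rows plus an equal-size random sample of negative rows — and
aggregates the per-model probability estimates by mean, median or weighted
mean (weights = number of training dimers whose top-k pairs under that model
contain at least one true pair).

The same ensemble doubles as the resampling engine for stability selection:
a term is retained if it is selected in a high fraction of subset models
(strictly above 90% for main effects and 80% for interaction effects by
default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from . import learners
from .learners import BaseLearnerSpec

AGGREGATIONS = ("mean", "median", "weighted_mean")


@dataclass(frozen=True)
class BalancedSubset:
    """Row indices of one balanced training subset."""

    positive: np.ndarray
    negative: np.ndarray
    seed: int

    @property
    def indices(self) -> np.ndarray:
        return np.concatenate([self.positive, self.negative])


def make_balanced_subsets(y, T: int | None = None, seed: int = 0) -> list[BalancedSubset]:
    """Draw ``T`` balanced subsets: all positives + equally many negatives.

    Negatives are sampled without replacement within a subset and
    independently (with replacement) across subsets.  ``T = None`` defaults
    to ``min(50, n_neg // n_pos)``.
    """
    y = np.asarray(y).astype(int)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    if len(neg) < len(pos):
        raise ValueError("fewer negatives than positives; nothing to undersample")
    if T is None:
        T = max(1, min(50, len(neg) // len(pos)))
    rng = np.random.default_rng(seed)
    subsets = []
    for t in range(T):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sample = np.random.default_rng(sub_seed).choice(neg, size=len(pos), replace=False)
        subsets.append(BalancedSubset(pos.copy(), np.sort(sample), sub_seed))
    return subsets


def aggregate(P, method: str = "mean", weights=None) -> np.ndarray:
    """Combine a (T, m) matrix of per-model probabilities into one vector."""
    P = np.atleast_2d(np.asarray(P, float))
    if method == "mean":
        return P.mean(axis=0)
    if method == "median":
        return np.median(P, axis=0)
    if method == "weighted_mean":
        if weights is None:
            raise ValueError("weighted_mean requires weights")
        w = np.asarray(weights, float)
        if w.shape[0] != P.shape[0]:
            raise ValueError("one weight per model required")
        if np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be nonnegative and not all zero")
        return w @ P / w.sum()
    raise ValueError(f"unknown aggregation {method!r}; choose from {AGGREGATIONS}")


class EasyEnsembleClassifier(ClassifierMixin, BaseEstimator):
    """Balanced-subset ensemble around one base-learner family.

    Parameters
    ----------
    kind:
        Base learner family (see :data:`ppiface.learners.KINDS`).
    hyperparams:
        Hyperparameters forwarded to each subset model.
    T:
        Number of balanced subsets; ``None`` = ``min(50, n_neg // n_pos)``.
    aggregation:
        ``mean`` (default), ``median`` or ``weighted_mean``; the latter
        requires :func:`training_weights` (or ``weights_``) to be set.
    """

    def __init__(
        self,
        kind: str = "lasso_logistic",
        hyperparams: dict | None = None,
        T: int | None = None,
        aggregation: str = "mean",
        random_state: int = 0,
    ):
        self.kind = kind
        self.hyperparams = hyperparams
        self.T = T
        self.aggregation = aggregation
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        self.classes_ = np.unique(y)
        yb = (y == self.classes_[1]).astype(int)
        self.subsets_ = make_balanced_subsets(yb, self.T, self.random_state)
        self.models_ = []
        for t, sub in enumerate(self.subsets_):
            spec = BaseLearnerSpec(
                self.kind, dict(self.hyperparams or {}), seed=sub.seed % (2**31 - 1)
            )
            idx = sub.indices
            try:
                self.models_.append(learners.fit(spec, X[idx], yb[idx]))
            except Exception as exc:  # surface which subset failed
                raise RuntimeError(f"subset {t} failed to fit: {exc}") from exc
        self.weights_ = None
        self.n_features_in_ = X.shape[1]
        return self

    def proba_matrix(self, X) -> np.ndarray:
        """(T, n) matrix of per-model positive-class probabilities."""
        check_is_fitted(self, "models_")
        return np.vstack([learners.positive_proba(m, X) for m in self.models_])

    def predict_proba(self, X) -> np.ndarray:
        p = aggregate(self.proba_matrix(X), self.aggregation, self.weights_)
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] > 0.5).astype(int)]

    def selection_frequencies(self) -> dict[str, float]:
        """Fraction of subset models selecting each term."""
        check_is_fitted(self, "models_")
        counts: dict[str, int] = {}
        for m in self.models_:
            sel = learners.selected_variables(m)
            if isinstance(sel, dict):  # importance scores: every term "selected"
                sel = set(sel)
            for term in sel:
                counts[term] = counts.get(term, 0) + 1
        return {t: c / len(self.models_) for t, c in sorted(counts.items())}


def train_ensemble(
    X, y, learner: BaseLearnerSpec, T: int | None = None, aggregation: str = "mean"
) -> EasyEnsembleClassifier:
    """Fit an :class:`EasyEnsembleClassifier` from a learner spec."""
    ens = EasyEnsembleClassifier(
        kind=learner.kind, hyperparams=learner.hyperparams, T=T,
        aggregation=aggregation, random_state=learner.seed,
    )
    return ens.fit(X, y)


def training_weights(ensemble, X, y, dimer_ids, k: int = 20) -> np.ndarray:
    """Per-model counts of correctly predicted training dimers.

    A dimer counts as correct for a model if the top-``k`` pairs ranked by
    that model's own probabilities contain at least one true pair.  The
    returned counts serve as ``weighted_mean`` aggregation weights.
    """
    from .evaluation import tp_at_k  # local import to avoid a cycle

    check_is_fitted(ensemble, "models_")
    y = np.asarray(y).astype(int)
    dimer_ids = np.asarray(dimer_ids)
    P = ensemble.proba_matrix(X)
    weights = np.zeros(P.shape[0], dtype=int)
    for t in range(P.shape[0]):
        for d in pd_unique(dimer_ids):
            mask = dimer_ids == d
            if tp_at_k(P[t, mask], y[mask], k) >= 1:
                weights[t] += 1
    return weights


def pd_unique(values: np.ndarray) -> np.ndarray:
    """Unique values in first-seen order."""
    _, idx = np.unique(values, return_index=True)
    return values[np.sort(idx)]


def stability_select(
    ensemble,
    main_threshold: float = 0.90,
    interaction_threshold: float = 0.80,
) -> set[str]:
    """High-frequency terms across the subset models.

    Main-effect terms need selection frequency strictly above
    ``main_threshold``; interaction terms strictly above
    ``interaction_threshold``.
    """
    freqs = ensemble.selection_frequencies()
    selected = set()
    for term, f in freqs.items():
        thr = interaction_threshold if term.startswith("int:") else main_threshold
        if f > thr:
            selected.add(term)
    return selected
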