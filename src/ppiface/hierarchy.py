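"""Sparse logistic regression with pairwise interactions under strong hierarchy.

The model is

    logit P(y=1 | x) = mu + sum_i x_i theta_i + sum_{i<j} x_i x_j theta_{i:j}

fitted by minimizing the penalized average negative log-likelihood

    (1/n) * NLL(mu, theta) + lambda * Omega(theta),

where ``Omega`` is a latent overlapped group-lasso penalty that induces
*strong hierarchy*: an interaction coefficient theta_{i:j} can be nonzero
only if both main effects theta_i and theta_j are nonzero.  Each main effect
is represented as a free l1-penalized copy plus one latent copy per
interaction group; group (i, j) collects (copy of theta_i, copy of theta_j,
theta_{i:j}) under an l2 group penalty, so activating an interaction drags
its two main effects into the model:

    theta_i = alpha_i + sum_j a_i^(ij),
    Omega   = sum_i |alpha_i| + sum_{i<j} || (a_i^(ij), a_j^(ij), theta_{i:j}) ||_2.

The solver is a monotone accelerated proximal-gradient method (FISTA with
backtracking line search and a monotone safeguard).  After fitting, any
interaction whose main effects fall below the zero tolerance is truncated to
zero, so the strong-hierarchy invariant holds for every returned model.

At ``lam = 0`` the objective is smooth and is minimized directly with
L-BFGS on the plain parametrization; it then coincides with unpenalized
logistic regression on the design augmented with product columns.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y


def _nll(eta: np.ndarray, y: np.ndarray) -> float:
    # mean of log(1 + exp(eta)) - y*eta, numerically stable
    return float(np.mean(np.logaddexp(0.0, eta) - y * eta))


def _all_pairs(p: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(p) for j in range(i + 1, p)]


def _cross_pairs(p: int) -> list[tuple[int, int]]:
    # receptor x ligand products of the 18 leading original columns
    if p < 18:
        raise ValueError("cross_only interactions need >= 18 columns")
    return [(i, j) for i in range(9) for j in range(9, 18)]


class HierarchyLogisticClassifier(ClassifierMixin, BaseEstimator):
    """Logistic regression with strong-hierarchy pairwise interactions.

    Parameters
    ----------
    lam:
        Penalty weight ``lambda``.  ``None`` selects it by ``cv``-fold
        cross-validated deviance (one-standard-error rule) on an
        ``n_lambdas``-point log grid from ``lambda_max`` (smallest value
        with an all-zero solution) down to ``lambda_max * lambda_min_ratio``.
    lambda_ratio:
        Cheap alternative to cross-validation: if ``lam`` is None and this
        is set, use ``lambda_ratio * lambda_max`` directly (used inside
        balanced-subset ensembles where per-subset CV is too costly).
    interactions:
        ``"all"`` for every i < j, ``"cross_only"`` for receptor-by-ligand
        products of the 18 leading original columns.
    interaction_pairs:
        Explicit list of (i, j) column pairs; overrides ``interactions``.
    standardize_interactions:
        Standardize product columns after forming them (changes the meaning
        of ``lam``; reported coefficients are mapped back to the raw product
        scale).
    screen_top:
        If set, keep only the ``screen_top`` columns most correlated with the
        response before building interactions (coefficients are reported on
        the full column space, zeros elsewhere).
    tol, max_iter:
        Solver stops when the relative objective change drops below ``tol``
        or after ``max_iter`` iterations.
    zero_tol:
        Coefficients with ``|coef| <= zero_tol`` count as zero.
    """

    def __init__(
        self,
        lam: float | None = None,
        *,
        lambda_ratio: float | None = None,
        n_lambdas: int = 20,
        lambda_min_ratio: float = 1e-3,
        cv: int = 5,
        interactions: str = "all",
        interaction_pairs: list[tuple[int, int]] | None = None,
        standardize_interactions: bool = True,
        screen_top: int | None = None,
        max_iter: int = 5000,
        tol: float = 1e-7,
        zero_tol: float = 1e-8,
        random_state: int | None = None,
    ):
        self.lam = lam
        self.lambda_ratio = lambda_ratio
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.interactions = interactions
        self.interaction_pairs = interaction_pairs
        self.standardize_interactions = standardize_interactions
        self.screen_top = screen_top
        self.max_iter = max_iter
        self.tol = tol
        self.zero_tol = zero_tol
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if self.lam is not None and self.lam < 0:
            raise ValueError("lam must be >= 0")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("y must be binary with both classes present")
        yb = (y == self.classes_[1]).astype(float)
        self.n_features_in_ = X.shape[1]

        if self.screen_top is not None and self.screen_top < X.shape[1]:
            if self.interaction_pairs is not None:
                raise ValueError("screen_top cannot be combined with interaction_pairs")
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            score = np.abs((X - X.mean(0)).T @ (yb - yb.mean())) / sd
            self.support_ = np.sort(np.argsort(score)[::-1][: self.screen_top])
        else:
            self.support_ = np.arange(X.shape[1])
        Xs = X[:, self.support_]
        p = Xs.shape[1]

        if self.interaction_pairs is not None:
            pairs = [tuple(t) for t in self.interaction_pairs]
        elif self.interactions == "cross_only":
            pairs = _cross_pairs(p)
        elif self.interactions == "all":
            pairs = _all_pairs(p)
        else:
            raise ValueError(f"unknown interactions mode {self.interactions!r}")
        self.pairs_ = pairs
        pi = np.array([i for i, _ in pairs], int)
        pj = np.array([j for _, j in pairs], int)

        Z = Xs[:, pi] * Xs[:, pj]
        if self.standardize_interactions:
            self.z_mean_ = Z.mean(axis=0)
            self.z_scale_ = Z.std(axis=0)
            self.z_scale_[self.z_scale_ == 0] = 1.0
        else:
            self.z_mean_ = np.zeros(len(pairs))
            self.z_scale_ = np.ones(len(pairs))
        Zs = (Z - self.z_mean_) / self.z_scale_

        if self.lam is not None:
            self.lambda_ = float(self.lam)
        elif self.lambda_ratio is not None:
            # cheap default tuning: fixed fraction of the critical penalty
            self.lambda_ = self.lambda_ratio * _lambda_max(Xs, Zs, yb, pi, pj)
        else:
            self.lambda_ = self._tune(Xs, Zs, yb, pi, pj)

        if self.lambda_ == 0.0:
            mu, theta, c, trace, converged = _smooth_fit(Xs, Zs, yb, self.tol)
        else:
            mu, theta, c, trace, converged = _fista(
                Xs, Zs, yb, self.lambda_, pi, pj, self.max_iter, self.tol
            )
        self.objective_trace_ = trace
        self.converged_ = converged
        self.n_iter_ = len(trace)

        theta = np.where(np.abs(theta) > self.zero_tol, theta, 0.0)
        c = np.where(np.abs(c) > self.zero_tol, c, 0.0)
        # strong-hierarchy truncation (a no-op in practice for the latent
        # formulation; guarantees the invariant exactly)
        kill = (theta[pi] == 0.0) | (theta[pj] == 0.0)
        c = np.where(kill, 0.0, c)

        self._c_std_ = c
        c_raw = c / self.z_scale_
        self.intercept_ = mu - float(self.z_mean_ / self.z_scale_ @ c)
        self.main_effects_ = np.zeros(self.n_features_in_)
        self.main_effects_[self.support_] = theta
        self.interaction_effects_ = {
            (int(self.support_[i]), int(self.support_[j])): float(v)
            for (i, j), v in zip(pairs, c_raw)
            if v != 0.0
        }
        return self

    # ------------------------------------------------------------------
    def _tune(self, Xs, Zs, yb, pi, pj) -> float:
        """Cross-validated deviance on a log grid, one-standard-error rule."""
        lmax = _lambda_max(Xs, Zs, yb, pi, pj)
        grid = np.geomspace(lmax, lmax * self.lambda_min_ratio, self.n_lambdas)
        skf = StratifiedKFold(
            n_splits=self.cv, shuffle=True, random_state=self.random_state
        )
        dev = np.zeros((self.cv, len(grid)))
        for f, (tr, te) in enumerate(skf.split(Xs, yb)):
            for g, lam in enumerate(grid):
                mu, theta, c, _, _ = _fista(
                    Xs[tr], Zs[tr], yb[tr], lam, pi, pj, self.max_iter, self.tol * 10
                )
                eta = mu + Xs[te] @ theta + Zs[te] @ c
                dev[f, g] = log_loss(yb[te], expit(eta), labels=[0.0, 1.0])
        mean = dev.mean(axis=0)
        best = int(np.argmin(mean))
        cutoff = mean[best] + dev[:, best].std(ddof=1) / np.sqrt(self.cv)
        # grid descends from lambda_max: take the sparsest acceptable fit
        return float(grid[int(np.flatnonzero(mean <= cutoff)[0])])

    # ------------------------------------------------------------------
    def _linear_predictor(self, X) -> np.ndarray:
        check_is_fitted(self, "intercept_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns, expected {self.n_features_in_}"
            )
        eta = self.intercept_ + X @ self.main_effects_
        for (i, j), v in self.interaction_effects_.items():
            eta = eta + v * X[:, i] * X[:, j]
        return eta

    def predict_proba(self, X) -> np.ndarray:
        p = expit(self._linear_predictor(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return self.classes_[(self._linear_predictor(X) > 0).astype(int)]

    def decision_function(self, X):
        return self._linear_predictor(X)

    # ------------------------------------------------------------------
    def selected_terms(self) -> set[str]:
        """Nonzero terms as ``main:i`` / ``int:i:j`` (1-based column ids)."""
        check_is_fitted(self, "intercept_")
        terms = {
            f"main:{i + 1}" for i in np.flatnonzero(self.main_effects_)
        }
        terms |= {f"int:{i + 1}:{j + 1}" for i, j in self.interaction_effects_}
        return terms

    def check_hierarchy(self) -> bool:
        """True iff every nonzero interaction has both main effects nonzero."""
        check_is_fitted(self, "intercept_")
        return all(
            self.main_effects_[i] != 0.0 and self.main_effects_[j] != 0.0
            for i, j in self.interaction_effects_
        )

    # ------------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Flat (term, value) serialization: ``mu``, ``main:i``, ``int:i:j``."""
        check_is_fitted(self, "intercept_")
        rows = [("mu", self.intercept_)]
        rows += [
            (f"main:{i + 1}", v)
            for i, v in enumerate(self.main_effects_)
            if v != 0.0
        ]
        rows += [
            (f"int:{i + 1}:{j + 1}", v) for (i, j), v in self.interaction_effects_.items()
        ]
        pd.DataFrame(rows, columns=["term", "value"]).to_csv(path, sep="\t", index=False)


def fit_hierarchy_logistic(X, y, lam: float | None = None, **opts) -> HierarchyLogisticClassifier:
    """Functional wrapper over :class:`HierarchyLogisticClassifier`."""
    return HierarchyLogisticClassifier(lam=lam, **opts).fit(X, y)


def predict_proba_hierarchy(model: HierarchyLogisticClassifier, X) -> np.ndarray:
    """Positive-class probabilities of a fitted hierarchy model."""
    return model.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------

#: relative weight of each 3-element interaction group in the penalty,
#: the usual sqrt(group size) group-lasso weighting
GROUP_WEIGHT = np.sqrt(3.0)


def _lambda_max(X, Z, y, pi, pj) -> float:
    n = len(y)
    r0 = (y.mean() - y) / n
    gm = X.T @ r0
    gz = Z.T @ r0
    group = np.sqrt(gm[pi] ** 2 + gm[pj] ** 2 + gz**2) / GROUP_WEIGHT
    return float(max(np.max(np.abs(gm)), np.max(group)))


def _smooth_fit(X, Z, y, tol):
    n, p = X.shape
    m = Z.shape[1]

    def fg(w):
        mu, theta, c = w[0], w[1 : 1 + p], w[1 + p :]
        eta = mu + X @ theta + Z @ c
        r = (expit(eta) - y) / n
        grad = np.concatenate([[r.sum()], X.T @ r, Z.T @ r])
        return _nll(eta, y), grad

    w0 = np.zeros(1 + p + m)
    res = minimize(
        fg, w0, jac=True, method="L-BFGS-B",
        options={"maxiter": 20000, "gtol": 1e-12, "ftol": 1e-15},
    )
    w = res.x
    return float(w[0]), w[1 : 1 + p], w[1 + p :], [float(res.fun)], bool(res.success)


def _fista(X, Z, y, lam, pi, pj, max_iter, tol):
    """Monotone FISTA on the latent overlapped-group parametrization."""
    n, p = X.shape
    m = Z.shape[1]

    def theta_of(alpha, G):
        return (
            alpha
            + np.bincount(pi, weights=G[:, 0], minlength=p)
            + np.bincount(pj, weights=G[:, 1], minlength=p)
        )

    def smooth(mu, alpha, G):
        eta = mu + X @ theta_of(alpha, G) + Z @ G[:, 2]
        return _nll(eta, y), eta

    def grads(eta):
        r = (expit(eta) - y) / n
        gm = X.T @ r
        gG = np.column_stack([gm[pi], gm[pj], Z.T @ r])
        return float(r.sum()), gm, gG

    def penalty(alpha, G):
        return lam * (
            np.abs(alpha).sum() + GROUP_WEIGHT * np.linalg.norm(G, axis=1).sum()
        )

    def prox(mu, alpha, G, t):
        a = np.sign(alpha) * np.maximum(np.abs(alpha) - lam * t, 0.0)
        norms = np.linalg.norm(G, axis=1)
        shrink = np.maximum(
            0.0, 1.0 - lam * t * GROUP_WEIGHT / np.maximum(norms, 1e-300)
        )
        return mu, a, G * shrink[:, None]

    mu_x, a_x, G_x = 0.0, np.zeros(p), np.zeros((m, 3))
    mu_v, a_v, G_v = mu_x, a_x.copy(), G_x.copy()
    f_x, _ = smooth(mu_x, a_x, G_x)
    F_x = f_x + penalty(a_x, G_x)
    trace = [F_x]
    t = 1.0
    tk = 1.0  # momentum
    converged = False
    for _ in range(max_iter):
        f_v, eta_v = smooth(mu_v, a_v, G_v)
        g_mu, g_a, g_G = grads(eta_v)
        # backtracking line search from the extrapolation point
        while True:
            mu_z, a_z, G_z = prox(mu_v - t * g_mu, a_v - t * g_a, G_v - t * g_G, t)
            f_z, _ = smooth(mu_z, a_z, G_z)
            d_mu, d_a, d_G = mu_z - mu_v, a_z - a_v, G_z - G_v
            quad = (
                f_v
                + g_mu * d_mu
                + g_a @ d_a
                + float(np.sum(g_G * d_G))
                + (d_mu**2 + d_a @ d_a + float(np.sum(d_G * d_G))) / (2 * t)
            )
            if f_z <= quad + 1e-12:
                break
            t *= 0.5
        F_z = f_z + penalty(a_z, G_z)
        tk_next = (1.0 + np.sqrt(1.0 + 4.0 * tk**2)) / 2.0
        if F_z <= F_x:  # accept the proximal point
            mom = (tk - 1.0) / tk_next
            mu_v = mu_z + mom * (mu_z - mu_x)
            a_v = a_z + mom * (a_z - a_x)
            G_v = G_z + mom * (G_z - G_x)
            accepted = True
            mu_x, a_x, G_x, F_prev, F_x = mu_z, a_z, G_z, F_x, F_z
        else:  # monotone safeguard: keep x, restart momentum at z
            mu_v, a_v, G_v = mu_z, a_z, G_z
            accepted = False
            tk_next = 1.0
        tk = tk_next
        trace.append(F_x)
        if accepted and abs(F_prev - F_x) <= tol * max(1.0, abs(F_x)):
            converged = True
            break
    return mu_x, theta_of(a_x, G_x), G_x[:, 2].copy(), trace, converged
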