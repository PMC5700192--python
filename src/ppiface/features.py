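"""Standardization by training statistics and the 18 -> 243 feature expansion.

The expansion enriches the 18 standardized residue-pair descriptors
(r1..r9 receptor, l1..l9 ligand) with hand-crafted nonlinear recodings, in a
fixed, documented column order:

==========  =====  =========================================================
block       count  contents
==========  =====  =========================================================
original       18  standardized r1..r9, l1..l9
difference      9  d_i = r_i - l_i
quadratic      27  r_i^2 (9), l_i^2 (9), d_i^2 (9)
ratio         153  x_i / x_j over the 18 originals, all i < j
diff ratio     36  d_i / d_j, all i < j
==========  =====  =========================================================

18 + 9 + 27 + 153 + 36 = 243.  Ratios of near-zero standardized variables
are safeguarded: any denominator with ``|den| < eps`` is replaced by
``eps * sign(den)`` with ``sign(0) := +1`` and ``eps = 1e-6``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .data import FEATURE_COLUMNS, N_FEATURES, ResiduePairTable

EPS = 1e-6

_N_ORIG = N_FEATURES
_N_DIFF = 9
_N_QUAD = 27
_N_RATIO = _N_ORIG * (_N_ORIG - 1) // 2
_N_DRATIO = _N_DIFF * (_N_DIFF - 1) // 2
N_EXPANDED = _N_ORIG + _N_DIFF + _N_QUAD + _N_RATIO + _N_DRATIO
assert N_EXPANDED == 243, "block count identity violated"

_ORIG_NAMES = [f"r{i}" for i in range(1, 10)] + [f"l{i}" for i in range(1, 10)]
_DIFF_NAMES = [f"d{i}" for i in range(1, 10)]

# upper-triangular index pairs, numerator = lower index
_RATIO_IJ = [(i, j) for i in range(_N_ORIG) for j in range(i + 1, _N_ORIG)]
_DRATIO_IJ = [(i, j) for i in range(_N_DIFF) for j in range(i + 1, _N_DIFF)]


def expanded_feature_names() -> list[str]:
    """Names of the 243 expanded columns, in the fixed block order."""
    names = list(_ORIG_NAMES)
    names += _DIFF_NAMES
    names += [f"{n}^2" for n in _ORIG_NAMES] + [f"{n}^2" for n in _DIFF_NAMES]
    names += [f"{_ORIG_NAMES[i]}/{_ORIG_NAMES[j]}" for i, j in _RATIO_IJ]
    names += [f"{_DIFF_NAMES[i]}/{_DIFF_NAMES[j]}" for i, j in _DRATIO_IJ]
    assert len(names) == N_EXPANDED
    return names


def _safe_den(den: np.ndarray) -> np.ndarray:
    sign = np.where(den < 0, -1.0, 1.0)  # sign(0) := +1
    return np.where(np.abs(den) < EPS, sign * EPS, den)


def expand_matrix(X: np.ndarray) -> np.ndarray:
    """Expand an (n, 18) matrix of standardized features to (n, 243)."""
    X = check_array(X, ensure_min_features=N_FEATURES)
    if X.shape[1] != N_FEATURES:
        raise ValueError(f"expected {N_FEATURES} features, got {X.shape[1]}")
    r, l = X[:, :9], X[:, 9:]
    d = r - l
    i1, j1 = zip(*_RATIO_IJ)
    i2, j2 = zip(*_DRATIO_IJ)
    blocks = [
        X,
        d,
        r**2,
        l**2,
        d**2,
        X[:, list(i1)] / _safe_den(X[:, list(j1)]),
        d[:, list(i2)] / _safe_den(d[:, list(j2)]),
    ]
    out = np.hstack(blocks)
    assert out.shape[1] == N_EXPANDED
    return out


def expand(row) -> np.ndarray:
    """Expand one standardized 18-vector to its 243-vector."""
    row = np.asarray(row, float)
    if row.shape != (N_FEATURES,):
        raise ValueError(f"expected {N_FEATURES} features, got shape {row.shape}")
    if not np.all(np.isfinite(row)):
        raise ValueError("non-finite input")
    return expand_matrix(row[None, :])[0]


class FeatureExpander(TransformerMixin, BaseEstimator):
    """Stateless transformer applying the fixed 18 -> 243 expansion."""

    def fit(self, X, y=None):
        check_array(X)
        return self

    def transform(self, X) -> np.ndarray:
        return expand_matrix(np.asarray(X, float))

    def get_feature_names_out(self, input_features=None):
        return np.asarray(expanded_feature_names(), dtype=object)


class PairStandardizer(TransformerMixin, BaseEstimator):
    """Column standardizer fitted on a designated training table.

    Means and standard deviations are computed over *all* training rows
    (positives and negatives pooled) and then applied unchanged to any other
    table, so test-set columns are in general not exactly centered.

    Parameters
    ----------
    ddof:
        Degrees-of-freedom correction for the SD (default 1, sample SD).
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X, y=None):
        X = self._coerce(X)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows to fit standardization")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=self.ddof)
        bad = np.flatnonzero(self.scale_ <= 0)
        if bad.size:
            names = [FEATURE_COLUMNS[i] if i < N_FEATURES else str(i) for i in bad]
            raise ValueError(f"constant feature(s): {names}")
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "mean_")
        X = self._coerce(X)
        return (X - self.mean_) / self.scale_

    @staticmethod
    def _coerce(X) -> np.ndarray:
        if isinstance(X, ResiduePairTable):
            X = X.features()
        return check_array(np.asarray(X, float))


def fit_standardizer(train: ResiduePairTable | np.ndarray, ddof: int = 1) -> PairStandardizer:
    return PairStandardizer(ddof=ddof).fit(train)
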