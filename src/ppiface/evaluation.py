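"""Per-dimer ranking metrics, correct-dimer curves, and attribute association.

Prediction quality is judged per dimer by ranking its candidate pairs by
estimated probability (descending, ties broken by original row order):

* ``rank_first_tp`` — 1-based rank of the best-ranked true interface pair;
* ``tp_at_k``       — true pairs among the top k;
* ``correct_dimers(k)`` — dimers with at least one true pair in their top k;
* ``accuracy(k)``   — pooled true positives over ``k * n_dimers``.

Association analysis relates per-dimer ranks to dimer attributes via
Pearson correlation, a sequential (Type-I) ANOVA of
``rank ~ category + P + Distance + NSRP``, and three-level attribute
binning for histogram summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

DEFAULT_CUTPOINTS = {
    "p": (0.002, 0.004),
    "distance": (1.5, 2.0),
    "nsrp": (20000, 35000),
}


def _descending_order(prob: np.ndarray) -> np.ndarray:
    # stable: ties keep original row order
    return np.argsort(-np.asarray(prob, float), kind="stable")


def rank_first_tp(prob, labels) -> int:
    """1-based rank of the first true positive in the probability ordering."""
    labels = np.asarray(labels).astype(int)
    if labels.sum() == 0:
        raise ValueError("no positive pair in dimer")
    order = _descending_order(prob)
    return int(np.flatnonzero(labels[order] == 1)[0]) + 1


def tp_at_k(prob, labels, k: int) -> int:
    """Number of true pairs among the top-k ranked pairs (k capped at n)."""
    labels = np.asarray(labels).astype(int)
    order = _descending_order(prob)
    return int(labels[order][: min(k, len(labels))].sum())


@dataclass
class EvaluationResult:
    """Per-dimer ranks/top-k counts plus pooled correct-dimer curves."""

    per_dimer: pd.DataFrame  # dimer_id, nsrp, nirp, rank_first_tp, tp_at_20
    curve: pd.DataFrame      # k, correct_dimers, accuracy

    def correct_dimers(self, k: int) -> int:
        return int(self.curve.loc[self.curve.k == k, "correct_dimers"].iloc[0])

    def accuracy(self, k: int) -> float:
        return float(self.curve.loc[self.curve.k == k, "accuracy"].iloc[0])


def evaluate(predictions: pd.DataFrame, k_max: int = 150, k_report: int = 20) -> EvaluationResult:
    """Evaluate per-dimer rankings.

    ``predictions`` needs columns ``dimer_id``, ``prob``, ``label``; every
    dimer must contain at least one true pair.
    """
    per_rows = []
    cum_tp = np.zeros(k_max, dtype=int)      # pooled true positives at each k
    correct = np.zeros(k_max, dtype=int)
    n_dimers = 0
    for did, sub in predictions.groupby("dimer_id", sort=False):
        prob = sub["prob"].to_numpy(float)
        labels = sub["label"].to_numpy(int)
        order = _descending_order(prob)
        sorted_labels = labels[order]
        cum = np.cumsum(sorted_labels)
        # tp within top-k, truncated at the dimer's pair count
        ks = np.minimum(np.arange(1, k_max + 1), len(labels)) - 1
        tp_k = cum[ks]
        cum_tp += tp_k
        correct += (tp_k >= 1).astype(int)
        n_dimers += 1
        per_rows.append({
            "dimer_id": did,
            "nsrp": len(labels),
            "nirp": int(labels.sum()),
            "rank_first_tp": rank_first_tp(prob, labels),
            f"tp_at_{k_report}": tp_at_k(prob, labels, k_report),
        })
    ks = np.arange(1, k_max + 1)
    curve = pd.DataFrame({
        "k": ks,
        "correct_dimers": correct,
        "accuracy": cum_tp / (ks * n_dimers),
    })
    return EvaluationResult(pd.DataFrame(per_rows), curve)


@dataclass
class AssociationResult:
    correlations: pd.DataFrame
    p_values: pd.DataFrame


def pearson_attributes(rows: pd.DataFrame, columns=("p", "distance", "nsrp")) -> AssociationResult:
    """Pairwise Pearson r (with two-sided t-test p-values) over attributes."""
    if len(rows) < 3:
        raise ValueError("need at least 3 dimers")
    cols = list(columns)
    k = len(cols)
    r = np.eye(k)
    pv = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            x = rows[cols[i]].to_numpy(float)
            y = rows[cols[j]].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                raise ValueError(f"constant column {cols[i] if np.std(x)==0 else cols[j]!r}")
            res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            pv[i, j] = pv[j, i] = res.pvalue
    idx = pd.Index(cols)
    return AssociationResult(
        pd.DataFrame(r, index=idx, columns=idx),
        pd.DataFrame(pv, index=idx, columns=idx),
    )


def anova_ranks(rows: pd.DataFrame, method: str) -> pd.DataFrame:
    """Sequential (Type-I) ANOVA of first-true-positive rank on attributes.

    Fits ``rank_<method> ~ C(category) + p + distance + nsrp`` by OLS and
    returns the sequential F-tests in that term order.
    """
    col = f"rank_{method}"
    if col not in rows.columns:
        raise ValueError(f"missing rank column {col!r}")
    model = smf.ols(f"{col} ~ C(category) + p + distance + nsrp", data=rows).fit()
    table = sm.stats.anova_lm(model, typ=1)
    table = table.rename(index={"C(category)": "category"})
    return table.loc[["category", "p", "distance", "nsrp"], ["F", "PR(>F)"]]


def sequential_f_tests(rows: pd.DataFrame, response: str, terms: list[list[str]]) -> pd.DataFrame:
    """Independent sequential-SS implementation (used as a cross-check).

    ``terms`` is an ordered list of column groups; categorical columns are
    expanded to treatment dummies.  Returns F and p per group, each tested
    against the residual of the full model.
    """
    y = rows[response].to_numpy(float)
    n = len(y)
    blocks = []
    for group in terms:
        cols = []
        for c in group:
            v = rows[c]
            if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(v, drop_first=True).to_numpy(float)
                cols.append(dummies)
            else:
                cols.append(v.to_numpy(float)[:, None])
        blocks.append(np.hstack(cols))

    def rss(Xd):
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        res = y - Xd @ beta
        return float(res @ res), np.linalg.matrix_rank(Xd)

    X = np.ones((n, 1))
    rss_prev, rank_prev = rss(X)
    full = np.hstack([np.ones((n, 1))] + blocks)
    rss_full, rank_full = rss(full)
    df_resid = n - rank_full
    out = []
    for name_cols, B in zip(terms, blocks):
        X = np.hstack([X, B])
        rss_cur, rank_cur = rss(X)
        df = rank_cur - rank_prev
        F = ((rss_prev - rss_cur) / df) / (rss_full / df_resid)
        p = stats.f.sf(F, df, df_resid)
        out.append({"term": "+".join(name_cols), "F": F, "PR(>F)": p})
        rss_prev, rank_prev = rss_cur, rank_cur
    return pd.DataFrame(out).set_index("term")


def bin_attributes(attrs: pd.DataFrame, cutpoints: dict | None = None) -> pd.DataFrame:
    """Three-level (low/mid/high) discretization of P, Distance and NSRP.

    Boundary convention is left-closed: a value equal to a cutpoint falls in
    the upper bin, so e.g. Distance = 1.5 with cutpoints (1.5, 2) is "mid".
    """
    cuts = dict(DEFAULT_CUTPOINTS)
    cuts.update(cutpoints or {})
    out = {}
    for col, (lo, hi) in cuts.items():
        if not lo < hi:
            raise ValueError(f"cutpoints for {col!r} must be sorted")
        if col not in attrs.columns:
            continue
        v = attrs[col].to_numpy(float)
        out[col] = np.where(v < lo, "low", np.where(v < hi, "mid", "high"))
    binned = pd.DataFrame(out, index=attrs.index)
    if "dimer_id" in attrs.columns:
        binned.insert(0, "dimer_id", attrs["dimer_id"])
    return binned
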