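"""Attribute-driven method selection: pick the classifier per dimer.

The decision list distilled from the per-dimer association analysis:

* dimers in the interaction-driven categories (enzyme-inhibitor EI and
  receptor-containing OR) go to the strong-hierarchy interaction logistic;
* otherwise, large dimers (NSRP strictly above the threshold, default
  20000) go to the lasso logistic — large NSRP is an observable proxy for
  small P, where the sparser model is more robust;
* the remaining small dimers go to the fallback: random forest under the
  ``final1`` variant, hierarchy logistic under ``final2``.

A dimer whose NSRP equals the threshold exactly is treated as "not larger
than" the threshold and takes the fallback branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .data import CATEGORIES, ResiduePairTable
from .evaluation import EvaluationResult, evaluate

VARIANTS = ("final1", "final2")


@dataclass(frozen=True)
class SelectorPolicy:
    variant: str = "final2"
    nsrp_threshold: int = 20000
    interaction_categories: frozenset = field(
        default_factory=lambda: frozenset({"EI", "OR"})
    )

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.nsrp_threshold <= 0:
            raise ValueError("nsrp_threshold must be positive")


def choose_method(category: str, nsrp: int, policy: SelectorPolicy) -> str:
    """Method kind for one dimer; a pure function of (category, NSRP)."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    if category in policy.interaction_categories:
        return "hierarchy_logistic"
    if nsrp > policy.nsrp_threshold:
        return "lasso_logistic"
    return "random_forest" if policy.variant == "final1" else "hierarchy_logistic"


def predict_with_selector(
    table: ResiduePairTable,
    scorers: dict,
    policy: SelectorPolicy = SelectorPolicy(),
    k_max: int = 150,
) -> tuple[pd.DataFrame, EvaluationResult, pd.DataFrame]:
    """Score every dimer with its selected method and evaluate.

    ``scorers`` maps method kind -> object with ``score(table) -> prob``
    per row (see :class:`ppiface.workflows.MethodPipeline`).  Returns the
    per-row predictions, the pooled evaluation, and the per-dimer choices.
    """
    pred_frames, choices = [], []
    for did, sub in table.dimers():
        category = sub.categories.get(did)
        if category is None:
            raise ValueError(f"dimer {did!r} has no category label")
        nsrp = len(sub)
        method = choose_method(category, nsrp, policy)
        if method not in scorers:
            raise ValueError(f"no trained model for method {method!r}")
        prob = scorers[method].score(sub)
        pred_frames.append(pd.DataFrame({
            "dimer_id": did, "prob": prob, "label": sub.labels(),
        }))
        choices.append({
            "dimer_id": did, "category": category, "nsrp": nsrp, "method": method,
        })
    predictions = pd.concat(pred_frames, ignore_index=True)
    return predictions, evaluate(predictions, k_max=k_max), pd.DataFrame(choices)
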