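"""Reusable desk-scale experiments: recovery rates and the selector study.

These routines define the frozen study conditions used both by the test
suite and by the reproduction script: planted-signal recovery for stability
selection, random-forest importance and the hierarchy interaction model,
plus the heterogeneous-benchmark comparison of the per-dimer method
selector against the four single methods.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier

from .ensemble import EasyEnsembleClassifier, stability_select
from .evaluation import evaluate
from .hierarchy import HierarchyLogisticClassifier
from .selector import SelectorPolicy, predict_with_selector
from .simulate import (
    BenchmarkSimSpec,
    heterogeneous_benchmark,
    simulate_benchmark,
    simulate_sparse_logistic,
)
from .workflows import score_table, train_all_methods

GEOMETRIC_IDX = frozenset(range(5)) | frozenset(range(9, 14))


def stability_recovery_trial(seed: int) -> bool:
    """Stability selection recovers 3 planted features out of 30.

    Success: all 3 informative main effects retained (frequency > 90%
    across T=25 balanced subsets) with at most 3 false terms.
    """
    X, y, informative = simulate_sparse_logistic(
        6000, 30, 3, beta=2.0, base_rate=0.02, seed=seed
    )
    ens = EasyEnsembleClassifier(
        kind="lasso_logistic", hyperparams={"lam": 0.01}, T=25, random_state=seed
    ).fit(X, y)
    selected = stability_select(ens)
    wanted = {f"main:{i + 1}" for i in informative}
    return wanted <= selected and len(selected - wanted) <= 3


def rf_importance_trial(seed: int) -> bool:
    """Forest importances rank the geometric-tagged features on top.

    The generator places all class separation on the 10 geometric features;
    success: the forest's top-5 impurity importances are all geometric.
    """
    spec = BenchmarkSimSpec(
        n_dimers=5, nsrp_range=(800.0, 3000.0), seed=seed, mechanism_map={}
    )
    table, _ = simulate_benchmark(spec)
    rf = RandomForestClassifier(
        n_estimators=150, max_features="sqrt", random_state=seed, n_jobs=1
    ).fit(table.features(), table.labels())
    top5 = set(np.argsort(rf.feature_importances_)[::-1][:5])
    return top5 <= GEOMETRIC_IDX


def interaction_recovery_trial(seed: int) -> bool:
    """The hierarchy model recovers a planted pairwise interaction.

    n=2000, p=6, logit = -1 + 2 x1 + 2 x2 + 3 x1 x2; lambda chosen by the
    default cross-validated tuner.  Success: main:1, main:2 and int:1:2 are
    selected and no purely-noise interaction is.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((2000, 6))
    eta = -1.0 + 2 * X[:, 0] + 2 * X[:, 1] + 3 * X[:, 0] * X[:, 1]
    y = (rng.random(2000) < expit(eta)).astype(int)
    model = HierarchyLogisticClassifier(random_state=seed).fit(X, y)
    selected = model.selected_terms()
    interactions = {t for t in selected if t.startswith("int:")}
    return {"main:1", "main:2", "int:1:2"} <= selected and interactions == {"int:1:2"}


def selector_trial(seed: int, T: int = 5) -> dict:
    """One heterogeneous-benchmark comparison: four single methods vs final2.

    Trains all four pipelines on one realization and evaluates correct
    dimers at k=20 on an independent realization, plus the ``final2``
    selector (policy threshold 4000, matching the benchmark's size split).
    """
    train_table, _ = heterogeneous_benchmark(seed=1000 + seed)
    test_table, _ = heterogeneous_benchmark(seed=2000 + seed)
    pipelines = train_all_methods(
        train_table, seed=seed, T=T,
        hyperparams={"random_forest": {"n_estimators": 100}},
    )
    singles = {
        method: evaluate(score_table(pipe, test_table), k_max=20).correct_dimers(20)
        for method, pipe in pipelines.items()
    }
    policy = SelectorPolicy(variant="final2", nsrp_threshold=4000)
    _, result, _ = predict_with_selector(test_table, pipelines, policy, k_max=20)
    final2 = result.correct_dimers(20)
    return {"singles": singles, "final2": final2, "win": final2 >= max(singles.values())}
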