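import numpy as np
import pandas as pd
import pytest

from ppiface.data import ALL_COLUMNS, FEATURE_COLUMNS, ResiduePairTable
from ppiface.simulate import DimerSimSpec, simulate_dimer


def make_table(n_dimers=2, nr=8, nl=6, p=0.1, seed=0, **kwargs):
    """Small multi-dimer residue-pair table for unit tests."""
    frames, cats = [], {}
    for d in range(n_dimers):
        spec = DimerSimSpec(
            n_receptor=nr, n_ligand=nl, p_interact=p, mean_shift=1.5,
            dimer_id=f"T{d}", seed=seed * 100 + d, **kwargs,
        )
        t = simulate_dimer(spec)
        frames.append(t.frame)
        cats.update(t.categories)
    return ResiduePairTable(pd.concat(frames, ignore_index=True), cats)


@pytest.fixture
def small_table():
    return make_table()


@pytest.fixture
def tiny_frame():
    """3-row single-dimer frame built by hand."""
    rng = np.random.default_rng(7)
    rows = []
    for i in range(3):
        rows.append(["D1", f"R{i}", "L0", *rng.normal(size=18), i % 2])
    return pd.DataFrame(rows, columns=ALL_COLUMNS)


@pytest.fixture
def separated_xy():
    """Strongly separated binary data (imbalanced)."""
    rng = np.random.default_rng(11)
    n = 2000
    y = (rng.random(n) < 0.1).astype(int)
    X = rng.standard_normal((n, 18))
    X[y == 1, :6] += 3.0 / np.sqrt(6)
    return X, y
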