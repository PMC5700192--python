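"""Per-dimer descriptors: NSRP, NIRP, P, Distance and category.

* **NSRP** — number of surface residue pairs, the candidate-pair universe of
  the dimer (for a full cross-product table, receptor count x ligand count).
* **NIRP** — number of true interface pairs.
* **P** = NIRP / NSRP, the interacting fraction (kept unrounded internally;
  printed to 2 significant digits).
* **Distance** — Euclidean distance between the mean feature vectors of
  interface and non-interface pairs after z-scoring each feature *within*
  the dimer over all of its pairs (labels pooled).  It indexes how separable
  the two classes are inside that dimer, and is invariant to per-feature
  affine rescaling of the raw features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ResiduePairTable


@dataclass(frozen=True)
class DimerAttributes:
    dimer_id: str
    nsrp: int
    nirp: int
    p: float
    distance: float
    category: str | None = None


def _dimer_distance(feats: np.ndarray, labels: np.ndarray, ddof: int = 0) -> float:
    mean = feats.mean(axis=0)
    sd = feats.std(axis=0, ddof=ddof)
    z = np.where(sd > 0, (feats - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return float(np.linalg.norm(z[labels == 1].mean(0) - z[labels == 0].mean(0)))


def compute_dimer_attributes(
    feats: np.ndarray, labels: np.ndarray, dimer_id: str = "", category: str | None = None,
    ddof: int = 0,
) -> DimerAttributes:
    """Attributes of one dimer from its feature matrix and labels.

    ``ddof`` selects the SD convention of the within-dimer z-scoring
    (default 0: population SD).  A feature constant within the dimer
    contributes 0 to the distance.
    """
    labels = np.asarray(labels).astype(int)
    nsrp = len(labels)
    nirp = int(labels.sum())
    if nsrp < 2:
        raise ValueError(f"dimer {dimer_id!r}: need at least 2 pairs")
    if nirp == 0:
        raise ValueError(f"dimer {dimer_id!r}: no interface pairs; Distance undefined")
    if nirp == nsrp:
        raise ValueError(f"dimer {dimer_id!r}: no non-interface pairs; Distance undefined")
    dist = _dimer_distance(np.asarray(feats, float), labels, ddof=ddof)
    return DimerAttributes(dimer_id, nsrp, nirp, nirp / nsrp, dist, category)


def compute_attributes(table: ResiduePairTable, ddof: int = 0) -> pd.DataFrame:
    """Attribute table (one row per dimer) of a residue-pair table."""
    rows = []
    for did, sub in table.dimers():
        attrs = compute_dimer_attributes(
            sub.features(), sub.labels(), did, table.categories.get(did), ddof=ddof
        )
        rows.append(attrs.__dict__)
    return pd.DataFrame(rows)


def format_sigfigs(x: float, sig: int = 2) -> str:
    """Positional decimal rendering of ``x`` with ``sig`` significant digits."""
    if x == 0:
        return "0"
    exponent = int(np.floor(np.log10(abs(x))))
    decimals = max(0, sig - 1 - exponent)
    return f"{x:.{decimals}f}"


def printed_p_consistent(nirp: int, nsrp: int, p_printed: float) -> bool:
    """Does a printed 2-significant-digit P agree with NIRP/NSRP?

    Exact agreement at printed precision, or within 0.55 units of the last
    printed digit — the slack covers round-half-up versus round-half-even
    discrepancies in typeset tables (e.g. 59/138852 = 0.0004249 printed as
    0.00043).
    """
    exact = nirp / nsrp
    if format_sigfigs(exact, 2) == format_sigfigs(p_printed, 2):
        return True
    unit = 10.0 ** (np.floor(np.log10(abs(p_printed))) - 1)
    return abs(exact - p_printed) <= 0.55 * unit


def round_for_report(attrs) -> dict | pd.DataFrame:
    """Display rendering: P to 2 significant digits, Distance to 2 decimals."""
    if isinstance(attrs, pd.DataFrame):
        out = attrs.copy()
        out["p"] = out["p"].map(lambda v: format_sigfigs(v, 2))
        out["distance"] = out["distance"].map(lambda v: f"{v:.2f}")
        return out
    return {
        **attrs.__dict__,
        "p": format_sigfigs(attrs.p, 2),
        "distance": f"{attrs.distance:.2f}",
    }
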