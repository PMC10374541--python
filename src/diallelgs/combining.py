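"""GEBV-based combining ability and heterosis over a half diallel.

Under the additive+dominance GBLUP decomposition, the additive BLUP of a
hybrid splits into parental general combining abilities,
``g_A^(ij) = GCA_i + GCA_j``, and the dominance BLUP is the specific
combining ability, ``SCA_ij = g_D^(ij)``.  Averaging the additive BLUPs per
parent (G_A^(i), over the N0-1 hybrids containing parent i) and overall
(G_A, over the N1 unordered hybrids, each counted once) inverts that
decomposition:

    GCA_i = (N0 - 1) G_A^(i) / (N0 - 2)  -  N0 G_A / (2 (N0 - 2)).

GEBV-based heterosis follows directly: mid-parent heterosis equals the SCA,
and better-parent heterosis is ``SCA_ij - |GCA_i - GCA_j|``, so BPH <= MPH
with equality exactly when the two parents have equal GCA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .markers import DiallelFrame
from .mme import BreedingPrediction


def sca_from_dominance(g_D_bp: np.ndarray, frame: DiallelFrame) -> np.ndarray:
    """Specific combining ability of each hybrid: its dominance BLUP."""
    g_D_bp = np.asarray(g_D_bp, dtype=float)
    if g_D_bp.shape != (frame.N1,):
        raise DataError(f"expected {frame.N1} dominance BLUPs, got {g_D_bp.shape}")
    return g_D_bp.copy()


def gca_from_additive(
    g_A_bp: np.ndarray, frame: DiallelFrame
) -> tuple[np.ndarray, np.ndarray, float]:
    """General combining ability of each parent from the hybrid additive BLUPs.

    Returns ``(gca, G_bar_A_i, G_bar_A)`` where ``G_bar_A_i`` is the mean
    additive BLUP over the hybrids containing parent i and ``G_bar_A`` the
    mean over all N1 unordered hybrids.  With ``g_A^(ij) = GCA_i + GCA_j``
    the formula recovers the GCA vector exactly.
    """
    g_A_bp = np.asarray(g_A_bp, dtype=float)
    if g_A_bp.shape != (frame.N1,):
        raise DataError(f"expected {frame.N1} additive BLUPs, got {g_A_bp.shape}")
    N0 = frame.N0
    if N0 <= 2:
        raise DataError("GCA needs at least 3 parents (the formula divides by N0-2)")
    sums = np.zeros(N0)
    for (i, j), g in zip(frame.pairs, g_A_bp):
        sums[i] += g
        sums[j] += g
    G_bar_i = sums / (N0 - 1)
    G_bar = float(g_A_bp.mean())
    gca = (N0 - 1) * G_bar_i / (N0 - 2) - N0 * G_bar / (2 * (N0 - 2))
    return gca, G_bar_i, G_bar


def mph(sca: np.ndarray) -> np.ndarray:
    """Mid-parent heterosis; on the GEBV scale this is exactly the SCA."""
    return np.asarray(sca, dtype=float).copy()


def bph(sca: np.ndarray, gca: np.ndarray, frame: DiallelFrame) -> np.ndarray:
    """Better-parent heterosis: ``SCA_ij - |GCA_i - GCA_j|`` per hybrid."""
    sca = np.asarray(sca, dtype=float)
    gca = np.asarray(gca, dtype=float)
    if sca.shape != (frame.N1,):
        raise DataError(f"expected {frame.N1} SCA values, got {sca.shape}")
    if gca.shape != (frame.N0,):
        raise DataError(f"expected {frame.N0} GCA values, got {gca.shape}")
    idx = np.asarray(frame.pairs)
    return sca - np.abs(gca[idx[:, 0]] - gca[idx[:, 1]])


@dataclass
class CombiningAbility:
    """Per-parent GCA and per-hybrid SCA/MPH/BPH for one diallel."""

    frame: DiallelFrame
    gca: np.ndarray
    sca: np.ndarray
    mph: np.ndarray
    bph: np.ndarray
    G_bar_A_i: np.ndarray
    G_bar_A: float


def evaluate_combining(pred: BreedingPrediction) -> CombiningAbility:
    """Derive all combining-ability and heterosis measures from a prediction."""
    frame = pred.frame
    sca = sca_from_dominance(pred.g_D_bp, frame)
    gca, G_bar_i, G_bar = gca_from_additive(pred.g_A_bp, frame)
    return CombiningAbility(
        frame=frame,
        gca=gca,
        sca=sca,
        mph=mph(sca),
        bph=bph(sca, gca, frame),
        G_bar_A_i=G_bar_i,
        G_bar_A=G_bar,
    )


@dataclass
class HybridEvaluation:
    """Ranked hybrid and parent report tables for one fitted diallel."""

    hybrid_table: pd.DataFrame
    parent_table: pd.DataFrame


def rank_hybrids(
    pred: BreedingPrediction,
    ca: CombiningAbility,
    top_k: int | None = None,
    decimals: int | None = None,
) -> pd.DataFrame:
    """Hybrids sorted by GEBV (descending); GEBV ties break lexicographically.

    Columns: parent_i, parent_j, gebv, sca, mph, bph.  ``decimals`` applies
    presentation rounding to the numeric columns.
    """
    frame = pred.frame
    names = frame.pair_names()
    table = pd.DataFrame(
        {
            "parent_i": [a for a, _ in names],
            "parent_j": [b for _, b in names],
            "gebv": pred.gebv,
            "sca": ca.sca,
            "mph": ca.mph,
            "bph": ca.bph,
        }
    )
    table = table.sort_values(
        ["gebv", "parent_i", "parent_j"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    if top_k is not None:
        if top_k > frame.N1:
            raise DataError(f"top_k={top_k} exceeds the {frame.N1} hybrids")
        table = table.head(top_k)
    if decimals is not None:
        table = table.round(decimals)
    return table


def rank_parents(
    ca: CombiningAbility, top_k: int | None = None, decimals: int | None = None
) -> pd.DataFrame:
    """Parents sorted by GCA (descending); ties break on the parent id."""
    table = pd.DataFrame({"parent": ca.frame.parent_ids, "gca": ca.gca})
    table = table.sort_values(
        ["gca", "parent"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    if top_k is not None:
        if top_k > ca.frame.N0:
            raise DataError(f"top_k={top_k} exceeds the {ca.frame.N0} parents")
        table = table.head(top_k)
    if decimals is not None:
        table = table.round(decimals)
    return table


def evaluate_hybrids(
    pred: BreedingPrediction,
    top_k_hybrids: int | None = None,
    top_k_parents: int | None = None,
    decimals: int | None = None,
) -> HybridEvaluation:
    """Full ranked report: hybrid GEBV/SCA/MPH/BPH table and parent GCA table."""
    ca = evaluate_combining(pred)
    return HybridEvaluation(
        hybrid_table=rank_hybrids(pred, ca, top_k_hybrids, decimals),
        parent_table=rank_parents(ca, top_k_parents, decimals),
    )
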