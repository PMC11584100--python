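"""Intratumoral heterogeneity of Ki67 positivity on the hexagonal grid.

Per-hexagon Ki67 positivity percentages (hexagons with fewer than 50 cells
are excluded as insufficiently sampled) are discretized into 10 ranks
(0–10%, >10–20%, ..., >90–100%).  A gray-level-style co-occurrence matrix is
accumulated over adjacent hexagon pairs and summarized by Haralick texture
indicators; the entropy of this matrix is the headline heterogeneity
biomarker, with homogeneity, contrast, dissimilarity and energy computed
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

N_RANKS = 10

__all__ = ["N_RANKS", "RankedHexField", "HaralickIndicators",
           "hexagon_positivity", "rank_percentages", "cooccurrence_matrix",
           "haralick_indicators", "ki67_indicators"]


@dataclass
class RankedHexField:
    """Included hexagons with their positivity percent and rank.

    ``table`` is indexed by axial (q, r) with columns
    ``n_cells, n_pos, percent, rank``.
    """

    table: pd.DataFrame
    min_cells: int


@dataclass(frozen=True)
class HaralickIndicators:
    entropy: float
    homogeneity: float
    contrast: float
    dissimilarity: float
    energy: float


def hexagon_positivity(counts: pd.DataFrame, min_cells: int = 50,
                       marker: str = "tumor_ki67") -> RankedHexField:
    """Per-hexagon positivity percent with the minimum-cell filter.

    ``counts`` comes from :func:`immunohex.hexgrid.assign_cells` and must
    carry ``n_<marker>`` and ``n_<marker>_pos`` columns.  Hexagons with fewer
    than ``min_cells`` cells are excluded as insufficiently sampled; an error
    is raised if none survives.
    """
    ncol, pcol = f"n_{marker}", f"n_{marker}_pos"
    if ncol not in counts.columns:
        raise ValueError(f"counts table lacks column {ncol!r}")
    keep = counts[counts[ncol] >= min_cells]
    if len(keep) == 0:
        raise ValueError(
            f"insufficient tumor sampling: no hexagon reaches {min_cells} cells")
    n = keep[ncol].to_numpy(dtype=float)
    pos = keep[pcol].to_numpy(dtype=float)
    table = pd.DataFrame(index=keep.index)
    table["n_cells"] = n.astype(int)
    table["n_pos"] = pos.astype(int)
    table["percent"] = 100.0 * pos / n
    table["rank"] = rank_percentages(table["percent"].to_numpy())
    return RankedHexField(table=table, min_cells=min_cells)


def rank_percentages(percent):
    """Discretize positivity percent into ranks 1–10.

    Interval 1 is [0, 10]; interval k ≥ 2 is (10(k−1), 10k], so e.g.
    10 → 1, 10.5 → 2, 100 → 10.
    """
    p = np.asarray(percent, dtype=float)
    if np.any((p < 0) | (p > 100)):
        raise ValueError("percent values must lie in [0, 100]")
    rank = np.ceil(p / 10.0).astype(int)
    rank = np.where(rank < 1, 1, rank)
    return rank if rank.ndim else int(rank)


def cooccurrence_matrix(field: RankedHexField, distance: int = 1) -> np.ndarray:
    """Symmetric, normalized rank co-occurrence matrix over adjacent hexagons.

    Every unordered pair of included hexagons within hexagonal ``distance``
    (default 1: the 6-neighbor adjacency) contributes to entries (i, j) and
    (j, i); pairs involving excluded hexagons are skipped.  Raises if no
    adjacent pair exists (the texture indicators are then undefined).
    """
    tab = field.table
    q = tab.index.get_level_values("q").to_numpy()
    r = tab.index.get_level_values("r").to_numpy()
    rank = tab["rank"].to_numpy()
    # all pairs at hex distance in [1, distance]; vectorized over the
    # (modest) number of included hexagons
    dq = q[:, None] - q[None, :]
    dr = r[:, None] - r[None, :]
    d = (np.abs(dq) + np.abs(dr) + np.abs(dq + dr)) // 2
    ii, jj = np.where(np.triu((d >= 1) & (d <= distance)))
    if len(ii) == 0:
        raise ValueError("no adjacent pair of included hexagons; "
                         "co-occurrence matrix undefined")
    mat = np.zeros((N_RANKS, N_RANKS))
    np.add.at(mat, (rank[ii] - 1, rank[jj] - 1), 1.0)
    np.add.at(mat, (rank[jj] - 1, rank[ii] - 1), 1.0)
    return mat / mat.sum()


def haralick_indicators(P: np.ndarray) -> HaralickIndicators:
    """Haralick texture indicators of a normalized co-occurrence matrix.

    entropy = −Σ p·ln p (0·ln 0 := 0); contrast = Σ (i−j)²·p;
    dissimilarity = Σ |i−j|·p; homogeneity (inverse difference moment) =
    Σ p/(1+(i−j)²); energy = Σ p².  Natural logarithm.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("co-occurrence matrix must be square")
    if np.any(P < 0) or not np.isclose(P.sum(), 1.0, atol=1e-9):
        raise ValueError("co-occurrence matrix must be nonnegative and sum to 1")
    i = np.arange(P.shape[0])
    diff = i[:, None] - i[None, :]
    nz = P > 0
    entropy = float(max(0.0, -np.sum(P[nz] * np.log(P[nz]))))
    return HaralickIndicators(
        entropy=entropy,
        homogeneity=float(np.sum(P / (1.0 + diff ** 2))),
        contrast=float(np.sum(diff ** 2 * P)),
        dissimilarity=float(np.sum(np.abs(diff) * P)),
        energy=float(np.sum(P ** 2)),
    )


def ki67_indicators(counts: pd.DataFrame, min_cells: int = 50,
                    distance: int = 1, marker: str = "tumor_ki67") -> dict:
    """One slide's Ki67 indicator row (global % plus texture indicators)."""
    field = hexagon_positivity(counts, min_cells=min_cells, marker=marker)
    P = cooccurrence_matrix(field, distance=distance)
    h = haralick_indicators(P)
    ncol, pcol = f"n_{marker}", f"n_{marker}_pos"
    total = float(counts[ncol].sum())
    return {
        "ki67_pct_global": 100.0 * float(counts[pcol].sum()) / total if total else np.nan,
        "ki67_entropy": h.entropy,
        "ki67_homogeneity": h.homogeneity,
        "ki67_contrast": h.contrast,
        "ki67_dissimilarity": h.dissimilarity,
        "ki67_energy": h.energy,
        "n_hexagons_included": int(len(field.table)),
    }
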