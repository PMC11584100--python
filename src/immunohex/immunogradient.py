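"""Tumor-edge detection, interface-zone ranking, and CD8 gradient indicators.

The tumor edge is found on the hexagon grid from abrupt changes of the
tumor-area fraction along the three lattice axes, keeping only tumor–stroma
transitions (tumor–background transitions at the section border are
discarded).  Hexagons are then ranked by their signed hexagonal distance to
the nearest edge hexagon — positive inside the tumor, negative on the stroma
side — and the interface zone (IZ) keeps ranks −4…+4, i.e. nine rank
classes around a one-rank-wide edge.

Eight indicators summarize the CD8+ density profile across the IZ: mean and
standard deviation of per-hexagon density in the stroma aspect (ranks
−4…−1), tumor edge (rank 0) and tumor aspect (ranks 1…4); the Immunodrop
(ID), the ratio of mean density at rank −1 to rank +1; and the center of
mass (CM), the density-weighted mean rank, negative when infiltrates
concentrate on the stroma side.
"""

from __future__ import annotations

import logging
import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hexgrid import AXIS_NEIGHBOR_PAIRS, NEIGHBOR_OFFSETS

log = logging.getLogger(__name__)

ASPECT_STROMA, ASPECT_EDGE, ASPECT_TUMOR = "S", "TE", "T"

INDICATOR_COLUMNS = ["CD8_m_S", "CD8_sd_S", "CD8_m_TE", "CD8_sd_TE",
                     "CD8_m_T", "CD8_sd_T", "CD8_CM", "CD8_ID"]


@dataclass(frozen=True)
class EdgeDetectionConfig:
    """Tumor-edge and interface-zone parameters.

    ``tau`` is the abrupt-change threshold on the tumor-area-fraction
    difference between the two opposite neighbors along a lattice axis.
    ``min_tumor_presence`` / ``min_stroma_presence`` are minimum area
    fractions required on the high-tumor / low-tumor side for a transition to
    count as tumor–stroma.  ``id_cap`` caps the Immunodrop ratio when the
    tumor-aspect density vanishes.
    """

    tau: float = 0.5
    min_tumor_presence: float = 0.0
    min_stroma_presence: float = 0.0
    iz_half_width: int = 4
    id_cap: float = 100.0

    def __post_init__(self) -> None:
        if not 0.0 < self.tau <= 1.0:
            raise ValueError("tau must lie in (0, 1]")
        if self.iz_half_width < 1:
            raise ValueError("IZ half-width must be ≥ 1")


@dataclass
class InterfaceZone:
    """Ranked interface zone with per-hexagon CD8 densities.

    ``table`` is indexed by axial (q, r) with columns
    ``rank, cd8_count, tissue_area_mm2, density``.
    """

    table: pd.DataFrame
    half_width: int

    def rank_mean_density(self) -> pd.Series:
        return self.table.groupby("rank")["density"].mean()

    def to_frame(self) -> pd.DataFrame:
        """Flat export: ``q, r, rank, cd8_count, tissue_area_mm2, density``."""
        return self.table[["rank", "cd8_count", "tissue_area_mm2",
                           "density"]].reset_index()


def detect_tumor_edge(hexes: pd.DataFrame, config: EdgeDetectionConfig) -> set:
    """Edge hexagons from abrupt tumor-fraction changes along lattice axes.

    ``hexes`` is indexed by axial (q, r) with tissue fraction columns.  A
    hexagon is flagged when along at least one axis the tumor-fraction
    difference between its two opposite neighbors exceeds ``tau`` and the
    low-tumor neighbor is stroma-like (stroma fraction ≥ background
    fraction), i.e. a tumor–stroma rather than tumor–background transition.
    """
    frac = _fraction_lookup(hexes)
    dominant = _dominant_class(hexes)
    if not (dominant == "tumor").any():
        raise ValueError("no interface: map contains no tumor-dominant hexagons")
    if not (dominant == "stroma").any():
        raise ValueError("no interface: map contains no stroma-dominant hexagons")

    edge = set()
    for (q, r), (ft, fs, fb) in frac.items():
        if np.isnan(ft):
            continue
        # the edge band traces the tumor boundary itself: only the
        # tumor-dominant side of a sharp transition is rank 0 (keeps the
        # central edge one rank wide; the stroma side becomes rank −1)
        if not (ft >= fs and fb <= 0.5):
            continue
        for (da, db) in AXIS_NEIGHBOR_PAIRS:
            a = frac.get((q + da[0], r + da[1]))
            b = frac.get((q + db[0], r + db[1]))
            if a is None or b is None or np.isnan(a[0]) or np.isnan(b[0]):
                continue
            if abs(a[0] - b[0]) <= config.tau:
                continue
            lo, hi = (a, b) if a[0] < b[0] else (b, a)
            if hi[0] < config.min_tumor_presence:
                continue
            # tumor–stroma transition: the low-tumor side must be stroma-like
            if lo[1] >= max(lo[2], config.min_stroma_presence):
                edge.add((q, r))
                break
    if not edge:
        raise ValueError("no interface: no abrupt tumor–stroma transition found")
    return edge


def assign_ranks(edge: set, hexes: pd.DataFrame,
                 config: EdgeDetectionConfig) -> pd.Series:
    """Signed rank of every includable hexagon.

    |rank| is the BFS distance over the 6-neighbor adjacency to the nearest
    edge hexagon (rank 0); the sign comes from the dominant tissue class
    (tumor → +, stroma → −).  Background-dominant hexagons are excluded, as
    are hexagons unreachable from the edge through included hexagons.
    """
    if not edge:
        raise ValueError("empty edge set")
    dominant = _dominant_class(hexes)
    nodes = set(dominant[dominant != "background"].index)
    nodes |= set(edge)
    dist = {h: 0 for h in edge}
    queue = deque(edge)
    while queue:
        q, r = queue.popleft()
        d = dist[(q, r)]
        for dq, dr in NEIGHBOR_OFFSETS:
            nb = (q + dq, r + dr)
            if nb in nodes and nb not in dist:
                dist[nb] = d + 1
                queue.append(nb)
    unreachable = nodes - set(dist)
    if unreachable:
        log.info("excluding %d hexagons unreachable from the tumor edge",
                 len(unreachable))
    sign = dominant.map({"tumor": 1, "stroma": -1})
    ranks = {}
    for h, d in dist.items():
        ranks[h] = 0 if d == 0 else int(d * sign.get(h, 0))
    out = pd.Series(ranks, name="rank")
    out.index = pd.MultiIndex.from_tuples(out.index, names=["q", "r"])
    return out.astype(int)


def extract_interface_zone(ranks: pd.Series, hexes: pd.DataFrame,
                           cd8_counts: pd.DataFrame,
                           half_width: int = 4,
                           marker: str = "cd8") -> InterfaceZone:
    """Clip the rank map to ranks within ±``half_width`` and attach densities.

    With the default half-width of 4 the IZ spans exactly 9 rank classes.
    Hexagons with zero analyzed-tissue area are excluded.  A missing rank
    class inside the IZ is tolerated with a warning (its indicators are
    computed from the remaining classes).
    """
    keep = ranks[ranks.abs() <= half_width]
    tab = pd.DataFrame({"rank": keep})
    tab = tab.join(hexes[["tissue_area_mm2"]], how="left")
    col = f"n_{marker}_pos"
    if col not in cd8_counts.columns:
        raise ValueError(f"CD8 count table lacks column {col!r}")
    tab = tab.join(cd8_counts[[col]].rename(columns={col: "cd8_count"}), how="left")
    tab["cd8_count"] = tab["cd8_count"].fillna(0).astype(int)
    tab = tab[tab["tissue_area_mm2"] > 0]
    tab["density"] = cd8_density(tab["cd8_count"], tab["tissue_area_mm2"])
    present = set(tab["rank"].unique())
    missing = set(range(-half_width, half_width + 1)) - present
    if missing:
        warnings.warn(f"IZ rank classes with no hexagons: {sorted(missing)}",
                      stacklevel=2)
    return InterfaceZone(table=tab, half_width=half_width)


def cd8_density(count, tissue_area_mm2):
    """CD8+ cells per mm² of analyzed (tumor+stroma) tissue."""
    count = np.asarray(count, dtype=float)
    area = np.asarray(tissue_area_mm2, dtype=float)
    if np.any(area <= 0):
        raise ValueError("analyzed-tissue area must be positive")
    return count / area


def aspect_statistics(iz: InterfaceZone) -> dict:
    """Mean/SD of per-hexagon CD8 density in the three IZ aspects.

    Stroma aspect: ranks −half_width…−1; edge: rank 0; tumor aspect: ranks
    1…half_width.  An aspect with no hexagons yields NaN indicators.
    SDs use the population convention unless an aspect has ≥ 2 hexagons, in
    which case the sample SD (ddof=1) is reported.
    """
    tab = iz.table
    out = {}
    for aspect, mask in [
        (ASPECT_STROMA, tab["rank"] < 0),
        (ASPECT_EDGE, tab["rank"] == 0),
        (ASPECT_TUMOR, tab["rank"] > 0),
    ]:
        d = tab.loc[mask, "density"].to_numpy()
        if len(d) == 0:
            out[f"CD8_m_{aspect}"] = np.nan
            out[f"CD8_sd_{aspect}"] = np.nan
        else:
            out[f"CD8_m_{aspect}"] = float(np.mean(d))
            out[f"CD8_sd_{aspect}"] = float(np.std(d, ddof=1)) if len(d) > 1 else 0.0
    return out


def immunodrop(iz: InterfaceZone, config: EdgeDetectionConfig | None = None) -> tuple[float, bool]:
    """Immunodrop: mean density at rank −1 over mean density at rank +1.

    Returns ``(value, flagged)``; flagged is True when the ratio had to be
    capped (zero tumor-aspect density) or defaulted to 1 (both zero).
    """
    config = config or EdgeDetectionConfig()
    means = iz.rank_mean_density()
    if -1 not in means.index or 1 not in means.index:
        raise ValueError("Immunodrop undefined: rank −1 or +1 class missing")
    num, den = float(means.loc[-1]), float(means.loc[1])
    if den == 0.0:
        return (1.0, True) if num == 0.0 else (config.id_cap, True)
    return num / den, False


def center_of_mass(iz: InterfaceZone) -> float:
    """Density-weighted mean rank of the CD8 profile (rank classes with no
    hexagons are simply absent from both sums)."""
    means = iz.rank_mean_density()
    total = float(means.sum())
    if total <= 0:
        raise ValueError("center of mass undefined: no CD8 density mass in IZ")
    return float((means.index.to_numpy() * means.to_numpy()).sum() / total)


def immunogradient_indicators(iz: InterfaceZone,
                              config: EdgeDetectionConfig | None = None) -> dict:
    """The eight CD8 indicator columns for one slide."""
    out = aspect_statistics(iz)
    try:
        out["CD8_CM"] = center_of_mass(iz)
    except ValueError:
        out["CD8_CM"] = np.nan
    try:
        out["CD8_ID"], out["CD8_ID_flagged"] = immunodrop(iz, config)
    except ValueError:
        out["CD8_ID"], out["CD8_ID_flagged"] = np.nan, True
    return out


def _fraction_lookup(hexes: pd.DataFrame) -> dict:
    need = {"frac_tumor", "frac_stroma", "frac_background"}
    if not need <= set(hexes.columns):
        raise ValueError(f"hex table lacks tissue fraction columns {sorted(need)}")
    return {
        (int(q), int(r)): (ft, fs, fb)
        for (q, r), ft, fs, fb in zip(
            hexes.index, hexes["frac_tumor"], hexes["frac_stroma"],
            hexes["frac_background"])
    }


def _dominant_class(hexes: pd.DataFrame) -> pd.Series:
    """tumor/stroma by argmax of area fraction; background-dominant
    (frac_background > 0.5) or pixel-less hexagons are 'background'."""
    ft = hexes["frac_tumor"]
    fs = hexes["frac_stroma"]
    fb = hexes["frac_background"]
    out = np.where(fb > 0.5, "background",
                   np.where(ft >= fs, "tumor", "stroma"))
    out = np.where(ft.isna(), "background", out)
    return pd.Series(out, index=hexes.index)


def rank_map_raster(ranks: pd.Series, grid, shape: tuple[int, int]) -> np.ndarray:
    """Label raster of IZ ranks for visual QC (pixels outside the ranked
    zone are coded 127)."""
    h, w = shape
    jj, ii = np.meshgrid(np.arange(w), np.arange(h), indexing="xy")
    q, r = grid.point_to_axial(jj.ravel() + 0.5, ii.ravel() + 0.5)
    px = pd.MultiIndex.from_arrays([q, r], names=["q", "r"])
    vals = ranks.reindex(px).fillna(127).to_numpy()
    return vals.astype(np.int8).reshape(h, w)
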