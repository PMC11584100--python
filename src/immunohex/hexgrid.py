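"""Randomized hexagonal tessellation of a slide.

A pointy-top hexagonal lattice with axial coordinates (q, r) is placed over
the slide with a random origin offset, so that repeated analyses subsample
the tissue at different grid phases.  Cells (point coordinates) and tissue
label rasters are binned into hexagons; the per-hexagon aggregates (cell
counts by marker, tissue-class area fractions, analyzed-tissue area) are the
shared substrate for both the Ki67-heterogeneity and the CD8-immunogradient
indicator families.

Geometry conventions
--------------------
* Pointy-top orientation: hexagon vertices point up/down; the center of
  hexagon (q, r) is at ``x = s*sqrt(3)*(q + r/2) + ox``,
  ``y = s*1.5*r + oy`` where ``s`` is the side length in pixels.
* The circumcircle diameter equals ``2*s``; the center-to-center pitch of
  adjacent hexagons is ``sqrt(3)*s``.
* A point is assigned to exactly one hexagon by fractional axial coordinates
  followed by cube rounding, which yields a deterministic partition of the
  plane (boundary points are resolved by the rounding rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd

SQRT3 = np.sqrt(3.0)

#: physical area of a regular hexagon with side ``s`` is ``(3*sqrt(3)/2) * s**2``
HEX_AREA_FACTOR = 3.0 * SQRT3 / 2.0


@dataclass(frozen=True)
class GridConfig:
    """Configuration of one hexagonal grid.

    Parameters
    ----------
    side_px:
        Hexagon side length in pixels (circumcircle radius).
    resolution_um_per_px:
        Physical pixel size.  The defaults of the two indicator families are
        a side of 525 px (262.5 μm) for the Ki67 grid and 130 px (65 μm) for
        the CD8 grid at 0.5 μm/px; see :func:`ki67_grid_config` and
        :func:`cd8_grid_config`.
    seed:
        Seed for the random origin offset.  ``offset_px``, when given,
        overrides the random draw (used for grid-placement sensitivity
        studies).
    """

    side_px: float
    resolution_um_per_px: float = 0.5
    seed: int = 0
    offset_px: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.side_px > 0:
            raise ValueError(f"hexagon side must be positive, got {self.side_px}")
        if not self.resolution_um_per_px > 0:
            raise ValueError("resolution must be positive")

    @property
    def side_um(self) -> float:
        return self.side_px * self.resolution_um_per_px

    @property
    def pitch_px(self) -> float:
        """Center-to-center distance of adjacent hexagons."""
        return SQRT3 * self.side_px

    @property
    def hex_area_mm2(self) -> float:
        """Full area of one hexagon in mm²."""
        return HEX_AREA_FACTOR * (self.side_um / 1000.0) ** 2


def ki67_grid_config(resolution_um_per_px: float = 0.5, seed: int = 0) -> GridConfig:
    """Default Ki67 grid: side 262.5 μm (525 px at 0.5 μm/px)."""
    return GridConfig(side_px=262.5 / resolution_um_per_px,
                      resolution_um_per_px=resolution_um_per_px, seed=seed)


def cd8_grid_config(resolution_um_per_px: float = 0.5, seed: int = 0) -> GridConfig:
    """Default CD8 grid: side 65 μm (130 px at 0.5 μm/px)."""
    return GridConfig(side_px=65.0 / resolution_um_per_px,
                      resolution_um_per_px=resolution_um_per_px, seed=seed)


# -- axial coordinate transforms -------------------------------------------

def axial_to_xy(q, r, side: float, offset=(0.0, 0.0)):
    q = np.asarray(q, dtype=float)
    r = np.asarray(r, dtype=float)
    x = side * SQRT3 * (q + r / 2.0) + offset[0]
    y = side * 1.5 * r + offset[1]
    return x, y

def xy_to_axial(x, y, side: float, offset=(0.0, 0.0)):
    """Map points to the axial coordinates of their containing hexagon."""
    x = (np.asarray(x, dtype=float) - offset[0]) / side
    y = (np.asarray(y, dtype=float) - offset[1]) / side
    qf = SQRT3 / 3.0 * x - y / 3.0
    rf = 2.0 / 3.0 * y
    return _cube_round(qf, rf)

def _cube_round(qf, rf):
    sf = -qf - rf
    q = np.round(qf)
    r = np.round(rf)
    s = np.round(sf)
    dq = np.abs(q - qf)
    dr = np.abs(r - rf)
    ds = np.abs(s - sf)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    q = np.where(fix_q, -r - s, q)
    r = np.where(fix_r, -q - s, r)
    return q.astype(np.int64), r.astype(np.int64)


def hex_distance(a, b) -> int:
    """Hexagonal lattice distance between axial coordinates ``a`` and ``b``.

    Equals the length of the shortest path over the 6-neighbor adjacency.
    """
    dq = np.asarray(a[0]) - np.asarray(b[0])
    dr = np.asarray(a[1]) - np.asarray(b[1])
    d = (np.abs(dq) + np.abs(dr) + np.abs(dq + dr)) // 2
    return int(d) if np.ndim(d) == 0 else d


#: axial offsets of the 6 neighbors, grouped as 3 opposite pairs (the three
#: lattice axes used by the tumor-edge detector).
AXIS_NEIGHBOR_PAIRS = (
    ((1, 0), (-1, 0)),
    ((0, 1), (0, -1)),
    ((1, -1), (-1, 1)),
)

NEIGHBOR_OFFSETS = tuple(o for pair in AXIS_NEIGHBOR_PAIRS for o in pair)


# -- grid construction ------------------------------------------------------

@dataclass
class HexGrid:
    """A concrete grid instance: config + realized offset + hexagon list."""

    config: GridConfig
    bounds: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    offset: tuple[float, float]
    hexes: pd.DataFrame = field(repr=False)  # columns q, r, center_x_px, center_y_px

    def point_to_axial(self, x, y):
        return xy_to_axial(x, y, self.config.side_px, self.offset)

    @property
    def axial_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_arrays(
            [self.hexes["q"].to_numpy(), self.hexes["r"].to_numpy()], names=["q", "r"])


def make_grid(bounds: tuple[float, float, float, float], config: GridConfig) -> HexGrid:
    """Build a hexagonal grid covering a pixel rectangle.

    Every point of ``bounds = (xmin, ymin, xmax, ymax)`` is covered by exactly
    one listed hexagon.  The grid origin offset is drawn uniformly over one
    lattice period from ``config.seed`` unless ``config.offset_px`` pins it.
    """
    xmin, ymin, xmax, ymax = map(float, bounds)
    if not (xmax > xmin and ymax > ymin):
        raise ValueError(f"bounds rectangle is empty: {bounds}")
    s = config.side_px
    if config.offset_px is not None:
        offset = (float(config.offset_px[0]), float(config.offset_px[1]))
    else:
        rng = np.random.default_rng(config.seed)
        # fundamental domain of the lattice translations
        offset = (float(rng.uniform(0.0, SQRT3 * s)), float(rng.uniform(0.0, 1.5 * s)))

    # enumerate candidate axial coords from the bounding box of the corners,
    # then keep hexagons whose center lies within bounds expanded by one
    # circumradius (a hexagon containing an in-bounds point has its center
    # within distance s of that point)
    corners_x = np.array([xmin, xmax, xmin, xmax])
    corners_y = np.array([ymin, ymin, ymax, ymax])
    qc, rc = xy_to_axial(corners_x, corners_y, s, offset)
    q_range = np.arange(qc.min() - 3, qc.max() + 4)
    r_range = np.arange(rc.min() - 3, rc.max() + 4)
    qq, rr = np.meshgrid(q_range, r_range, indexing="ij")
    qq = qq.ravel()
    rr = rr.ravel()
    cx, cy = axial_to_xy(qq, rr, s, offset)
    keep = ((cx >= xmin - s) & (cx <= xmax + s) &
            (cy >= ymin - s) & (cy <= ymax + s))
    hexes = pd.DataFrame({
        "q": qq[keep], "r": rr[keep],
        "center_x_px": cx[keep], "center_y_px": cy[keep],
    }).reset_index(drop=True)
    return HexGrid(config=config, bounds=(xmin, ymin, xmax, ymax),
                   offset=offset, hexes=hexes)


def assign_cells(cells: pd.DataFrame, grid: HexGrid) -> pd.DataFrame:
    """Bin a cell table into hexagons, counting cells by marker and positivity.

    ``cells`` must have columns ``x_px, y_px, marker, positive``.  Every cell
    is counted in exactly one hexagon (totals are conserved).  Cells outside
    the grid bounds are rejected.

    Returns a DataFrame indexed like ``grid.hexes`` (one row per grid
    hexagon) with columns ``n_<marker>`` and ``n_<marker>_pos``.
    """
    required = {"x_px", "y_px", "marker", "positive"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cell table missing columns: {sorted(missing)}")
    xmin, ymin, xmax, ymax = grid.bounds
    x = cells["x_px"].to_numpy(dtype=float)
    y = cells["y_px"].to_numpy(dtype=float)
    out = (x < xmin) | (x > xmax) | (y < ymin) | (y > ymax)
    if out.any():
        bad = cells.loc[out, ["x_px", "y_px"]].head(5)
        raise ValueError(
            f"{int(out.sum())} cells lie outside grid bounds {grid.bounds}; "
            f"first offenders:\n{bad.to_string()}")

    counts = pd.DataFrame(index=grid.axial_index)
    if len(cells) == 0:
        return counts.fillna(0)
    q, r = grid.point_to_axial(x, y)
    tbl = pd.DataFrame({
        "q": q, "r": r,
        "marker": cells["marker"].to_numpy(),
        "positive": cells["positive"].to_numpy(dtype=int),
    })
    for marker, sub in tbl.groupby("marker", sort=True):
        g = sub.groupby(["q", "r"])["positive"].agg(["size", "sum"])
        counts[f"n_{marker}"] = g["size"]
        counts[f"n_{marker}_pos"] = g["sum"]
    counts = counts.fillna(0).astype(np.int64)
    # conservation guard: the grid covers the bounds, so nothing may be lost
    total = sum(int(counts[c].sum()) for c in counts.columns if not c.endswith("_pos"))
    if total != len(cells):
        raise AssertionError("cell assignment lost or duplicated cells")
    return counts


@numba.njit(cache=True)
def _raster_label_counts(labels, side, ox, oy, qmin, rmin, nq, nr):
    """Per-hexagon pixel counts by tissue class, fused cube-round + bincount.

    One pass over the raster; pixel (i, j) is attributed by the same cube
    rounding as :func:`xy_to_axial` applied to its center.
    """
    h, w = labels.shape
    cnt = np.zeros((3, nq * nr), dtype=np.int64)
    c_q = SQRT3 / 3.0 / side
    inv3s = 1.0 / (3.0 * side)
    for i in range(h):
        y = i + 0.5 - oy
        rf = 2.0 * y * inv3s
        qf0 = -y * inv3s
        for j in range(w):
            x = j + 0.5 - ox
            qf = c_q * x + qf0
            sf = -qf - rf
            q = round(qf)
            r = round(rf)
            s = round(sf)
            dq = abs(q - qf)
            dr = abs(r - rf)
            ds = abs(s - sf)
            if dq > dr and dq > ds:
                q = -r - s
            elif dr > ds:
                r = -q - s
            lab = labels[i, j]
            cnt[lab, (int(q) - qmin) * nr + (int(r) - rmin)] += 1
    return cnt


def tissue_fractions(labels: np.ndarray, resolution_um_per_px: float,
                     grid: HexGrid) -> pd.DataFrame:
    """Per-hexagon tissue-class area fractions from a label raster.

    ``labels`` is a (H, W) array over {0: background, 1: stroma, 2: tumor};
    pixel (i, j) is attributed to the hexagon containing its center
    ``(j + 0.5, i + 0.5)``.  Fractions are pixel-count ratios within each
    hexagon and sum to 1 over observed pixels.  The analyzed-tissue area is
    the tumor+stroma pixel area in mm².

    Returns a DataFrame indexed like ``grid.hexes`` with columns
    ``n_px, frac_tumor, frac_stroma, frac_background, tissue_area_mm2``.
    Hexagons with no raster pixels get ``n_px = 0`` and NaN fractions.
    """
    if resolution_um_per_px is None or not resolution_um_per_px > 0:
        raise ValueError("a positive μm-per-pixel resolution is required")
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("label raster must be 2-D")
    h, w = labels.shape
    # axial bounding box of the raster corners, with a safety ring
    cq, cr = grid.point_to_axial(np.array([0.5, w - 0.5, 0.5, w - 0.5]),
                                 np.array([0.5, 0.5, h - 0.5, h - 0.5]))
    qmin, rmin = int(cq.min()) - 2, int(cr.min()) - 2
    nq = int(cq.max()) + 2 - qmin + 1
    nr = int(cr.max()) + 2 - rmin + 1
    cnt = _raster_label_counts(labels.astype(np.uint8), grid.config.side_px,
                               grid.offset[0], grid.offset[1],
                               qmin, rmin, nq, nr)

    px_area_mm2 = (resolution_um_per_px / 1000.0) ** 2
    out = pd.DataFrame(index=grid.axial_index)
    gq = out.index.get_level_values("q").to_numpy()
    gr = out.index.get_level_values("r").to_numpy()
    inside = (gq >= qmin) & (gq < qmin + nq) & (gr >= rmin) & (gr < rmin + nr)
    gkey = np.where(inside, (gq - qmin) * nr + (gr - rmin), 0)
    n_bg = np.where(inside, cnt[0][gkey], 0)
    n_st = np.where(inside, cnt[1][gkey], 0)
    n_tu = np.where(inside, cnt[2][gkey], 0)
    n_px = n_bg + n_st + n_tu
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = n_px.astype(float)
        out["n_px"] = n_px
        out["frac_tumor"] = np.where(n_px > 0, n_tu / denom, np.nan)
        out["frac_stroma"] = np.where(n_px > 0, n_st / denom, np.nan)
        out["frac_background"] = np.where(n_px > 0, n_bg / denom, np.nan)
    out["tissue_area_mm2"] = (n_st + n_tu) * px_area_mm2
    return out


def hex_aggregate_table(grid: HexGrid, counts: pd.DataFrame | None = None,
                        fractions: pd.DataFrame | None = None,
                        marker: str | None = None) -> pd.DataFrame:
    """Flat per-hexagon aggregate for CSV export.

    Columns: ``q, r, center_x_px, center_y_px, n_cells, n_pos, frac_tumor,
    frac_stroma, frac_background, tissue_area_mm2`` (count/fraction columns
    zero/NaN where the corresponding input is not given).
    """
    out = grid.hexes.set_index(["q", "r"]).copy()
    if counts is not None:
        if marker is None:
            ncols = [c for c in counts.columns
                     if c.startswith("n_") and not c.endswith("_pos")]
            marker = ncols[0][2:] if ncols else None
        if marker is not None and f"n_{marker}" in counts.columns:
            out["n_cells"] = counts[f"n_{marker}"]
            out["n_pos"] = counts[f"n_{marker}_pos"]
    for col in ("n_cells", "n_pos"):
        if col not in out.columns:
            out[col] = 0
    if fractions is not None:
        out = out.join(fractions[["frac_tumor", "frac_stroma",
                                  "frac_background", "tissue_area_mm2"]])
    else:
        for col in ("frac_tumor", "frac_stroma", "frac_background"):
            out[col] = np.nan
        out["tissue_area_mm2"] = np.nan
    cols = ["center_x_px", "center_y_px", "n_cells", "n_pos", "frac_tumor",
            "frac_stroma", "frac_background", "tissue_area_mm2"]
    return out[cols].fillna({"n_cells": 0, "n_pos": 0}).reset_index()
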