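import numpy as np
import pandas as pd
import pytest

from immunohex import hexgrid, synthetic


@pytest.fixture(scope="session")
def half_plane_tissue() -> synthetic.TissueMap:
    """1.2 × 1.2 mm half-plane slide: stroma left, tumor right."""
    return synthetic.generate_tissue_map(synthetic.TissueScenario(
        width_px=2400, height_px=2400,
        geometry=synthetic.HalfPlane(boundary_x_px=1200), margin_px=10))


@pytest.fixture(scope="session")
def gradient_slide(half_plane_tissue):
    """Half-plane tissue plus a κ=4 CD8 gradient and patchy Ki67 cells."""
    cells = synthetic.generate_cells(half_plane_tissue, synthetic.CellScenario(
        tumor_density=2000.0, ki67_base=0.2, ki67_patch_spread=0.2,
        ki67_patch_diameter_um=300.0, cd8_stroma_density=300.0,
        cd8_kappa=4.0, cd8_decay_um=2000.0, seed=11))
    return half_plane_tissue, cells


@pytest.fixture()
def small_grid() -> hexgrid.HexGrid:
    return hexgrid.make_grid((0, 0, 1000, 800),
                             hexgrid.GridConfig(side_px=50.0, seed=3))


def make_ranked_field(entries):
    """RankedHexField-style table from [(q, r, rank), ...] tuples."""
    from immunohex.ki67 import RankedHexField
    idx = pd.MultiIndex.from_tuples([(q, r) for q, r, _ in entries],
                                    names=["q", "r"])
    tab = pd.DataFrame({
        "n_cells": 100, "n_pos": 0,
        "percent": [10.0 * rk - 5.0 for *_, rk in entries],
        "rank": [rk for *_, rk in entries],
    }, index=idx)
    return RankedHexField(table=tab, min_cells=50)


def make_interface_zone(rank_density_pairs, half_width=4, area=0.01):
    """InterfaceZone from [(rank, density), ...]; unit tissue areas."""
    from immunohex.immunogradient import InterfaceZone
    idx = pd.MultiIndex.from_tuples([(k, 0) for k in range(len(rank_density_pairs))],
                                    names=["q", "r"])
    tab = pd.DataFrame({
        "rank": [rk for rk, _ in rank_density_pairs],
        "tissue_area_mm2": area,
        "density": [d for _, d in rank_density_pairs],
    }, index=idx)
    tab["cd8_count"] = (tab["density"] * area).round().astype(int)
    return InterfaceZone(table=tab, half_width=half_width)
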