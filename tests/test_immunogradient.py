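"""Tumor-edge detection, interface-zone ranking, CD8 gradient indicators."""

from collections import deque

import numpy as np
import pandas as pd
import pytest

from immunohex import hexgrid, immunogradient
from immunohex.immunogradient import (EdgeDetectionConfig, aspect_statistics,
                                      assign_ranks, cd8_density,
                                      center_of_mass, detect_tumor_edge,
                                      extract_interface_zone, immunodrop)

from conftest import make_interface_zone


def geometric_hexes(grid, tumor_fn, background_fn=None):
    """Hex table with fractions derived from the center position."""
    c = grid.hexes.set_index(["q", "r"])
    ft = np.array([tumor_fn(x, y) for x, y in
                   zip(c.center_x_px, c.center_y_px)], dtype=float)
    fb = (np.array([background_fn(x, y) for x, y in
                    zip(c.center_x_px, c.center_y_px)], dtype=float)
          if background_fn else np.zeros(len(c)))
    out = pd.DataFrame(index=c.index)
    out["frac_tumor"] = ft * (1 - fb)
    out["frac_background"] = fb
    out["frac_stroma"] = 1.0 - out.frac_tumor - out.frac_background
    out["tissue_area_mm2"] = grid.config.hex_area_mm2 * (1 - fb)
    out["n_px"] = 1000
    return out


@pytest.fixture()
def half_plane_setup():
    grid = hexgrid.make_grid((0, 0, 2000, 1600),
                             hexgrid.GridConfig(side_px=60.0, seed=5))
    hexes = geometric_hexes(grid, lambda x, y: 1.0 if x >= 1000 else 0.0)
    return grid, hexes


class TestEdgeDetection:
    def test_half_plane_edge_is_a_band_at_the_boundary(self, half_plane_setup):
        grid, hexes = half_plane_setup
        edge = detect_tumor_edge(hexes, EdgeDetectionConfig())
        centers = grid.hexes.set_index(["q", "r"])
        xs = centers.loc[sorted(edge), "center_x_px"]
        pitch = grid.config.pitch_px
        # every edge hexagon center within ~one hexagon of the true boundary
        assert (abs(xs - 1000) <= 1.5 * pitch).all()
        # the band spans the full slide height (connected across rows)
        ys = np.sort(centers.loc[sorted(edge), "center_y_px"].to_numpy())
        assert ys.min() < 2 * pitch and ys.max() > 1600 - 2 * pitch
        assert np.diff(ys).max() <= 1.1 * pitch

    def test_uniform_tumor_map_has_no_interface(self, half_plane_setup):
        grid, _ = half_plane_setup
        hexes = geometric_hexes(grid, lambda x, y: 1.0)
        with pytest.raises(ValueError, match="no interface"):
            detect_tumor_edge(hexes, EdgeDetectionConfig())

    def test_tumor_background_transition_not_edge(self, half_plane_setup):
        # tumor | background at x=1000, stroma beyond x=1600: the only
        # abrupt tumor change is a tumor–background transition, not an edge
        grid, _ = half_plane_setup
        hexes = geometric_hexes(
            grid, lambda x, y: 1.0 if x < 1000 else 0.0,
            background_fn=lambda x, y: 1.0 if 1000 <= x <= 1600 else 0.0)
        with pytest.raises(ValueError, match="no interface"):
            detect_tumor_edge(hexes, EdgeDetectionConfig())

    def test_disk_edge_count_tracks_perimeter_over_pitch(self):
        radius = 500.0
        grid = hexgrid.make_grid((0, 0, 2000, 2000),
                                 hexgrid.GridConfig(side_px=40.0, seed=2))
        hexes = geometric_hexes(
            grid, lambda x, y: 1.0 if (x - 1000) ** 2 + (y - 1000) ** 2
            <= radius ** 2 else 0.0)
        edge = detect_tumor_edge(hexes, EdgeDetectionConfig())
        expected = 2 * np.pi * radius / grid.config.pitch_px
        assert len(edge) == pytest.approx(expected, rel=0.30)


class TestRankAssignment:
    @staticmethod
    def _bfs_oracle(edge, nodes):
        dist = {h: 0 for h in edge}
        queue = deque(edge)
        while queue:
            q, r = queue.popleft()
            for dq, dr in hexgrid.NEIGHBOR_OFFSETS:
                nb = (q + dq, r + dr)
                if nb in nodes and nb not in dist:
                    dist[nb] = dist[(q, r)] + 1
                    queue.append(nb)
        return dist

    def test_edge_is_rank_zero_and_neighbors_rank_one(self, half_plane_setup):
        grid, hexes = half_plane_setup
        cfg = EdgeDetectionConfig()
        edge = detect_tumor_edge(hexes, cfg)
        ranks = assign_ranks(edge, hexes, cfg)
        assert (ranks.loc[list(edge)] == 0).all()
        some_edge = next(iter(edge))
        for dq, dr in hexgrid.NEIGHBOR_OFFSETS:
            nb = (some_edge[0] + dq, some_edge[1] + dr)
            if nb in ranks.index and nb not in edge:
                assert abs(ranks.loc[nb]) == 1

    def test_sign_follows_dominant_tissue(self, half_plane_setup):
        grid, hexes = half_plane_setup
        cfg = EdgeDetectionConfig()
        ranks = assign_ranks(detect_tumor_edge(hexes, cfg), hexes, cfg)
        tab = pd.DataFrame({"rank": ranks}).join(hexes)
        off_edge = tab[tab["rank"] != 0]
        assert (np.sign(off_edge["rank"]) ==
                np.where(off_edge.frac_tumor >= off_edge.frac_stroma, 1, -1)).all()

    @pytest.mark.parametrize("seed", [0, 1])
    def test_rank_magnitude_matches_bfs_oracle(self, seed):
        # random blob lattice ≤ 500 hexagons
        rng = np.random.default_rng(seed)
        grid = hexgrid.make_grid((0, 0, 1500, 1200),
                                 hexgrid.GridConfig(side_px=45.0, seed=seed))
        cx = rng.uniform(400, 1100), rng.uniform(400, 800)
        rad = rng.uniform(200, 350)
        hexes = geometric_hexes(
            grid, lambda x, y: 1.0 if (x - cx[0]) ** 2 + (y - cx[1]) ** 2
            <= rad ** 2 else 0.0)
        assert len(hexes) <= 500
        cfg = EdgeDetectionConfig()
        edge = detect_tumor_edge(hexes, cfg)
        ranks = assign_ranks(edge, hexes, cfg)
        oracle = self._bfs_oracle(edge, set(hexes.index))
        for h, rk in ranks.items():
            assert abs(rk) == oracle[h]

    def test_background_dominant_hexagons_excluded(self, half_plane_setup):
        grid, hexes = half_plane_setup
        hexes = hexes.copy()
        victim = hexes.index[10]
        hexes.loc[victim, ["frac_tumor", "frac_stroma", "frac_background"]] = \
            [0.1, 0.2, 0.7]
        cfg = EdgeDetectionConfig()
        ranks = assign_ranks(detect_tumor_edge(hexes, cfg), hexes, cfg)
        assert victim not in ranks.index


class TestInterfaceZone:
    def test_half_plane_iz_has_nine_rank_classes(self, half_plane_setup):
        grid, hexes = half_plane_setup
        cfg = EdgeDetectionConfig()
        ranks = assign_ranks(detect_tumor_edge(hexes, cfg), hexes, cfg)
        counts = pd.DataFrame({"n_cd8_pos": 0}, index=hexes.index)
        iz = extract_interface_zone(ranks, hexes, counts, half_width=4)
        assert set(iz.table["rank"].unique()) == set(range(-4, 5))
        assert iz.table["rank"].abs().max() <= 4

    def test_half_width_one_gives_three_classes(self, half_plane_setup):
        grid, hexes = half_plane_setup
        cfg = EdgeDetectionConfig(iz_half_width=1)
        ranks = assign_ranks(detect_tumor_edge(hexes, cfg), hexes, cfg)
        counts = pd.DataFrame({"n_cd8_pos": 0}, index=hexes.index)
        iz = extract_interface_zone(ranks, hexes, counts, half_width=1)
        assert set(iz.table["rank"].unique()) == {-1, 0, 1}


class TestDensity:
    def test_full_hexagon_closed_form(self):
        area = 1.5 * np.sqrt(3) * 0.065 ** 2  # side 65 μm
        assert cd8_density(11, area) == pytest.approx(1002.0, rel=0.001)

    def test_zero_cells_zero_density_and_proportionality(self):
        assert cd8_density(0, 0.01) == 0.0
        assert cd8_density(7, 0.005) == pytest.approx(2 * cd8_density(7, 0.01))

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError, match="area"):
            cd8_density(3, 0.0)


class TestAspectStatistics:
    def test_uniform_profile_means_equal_sds_zero(self):
        iz = make_interface_zone([(r, 200.0) for r in range(-4, 5)])
        stats = aspect_statistics(iz)
        for a in ("S", "TE", "T"):
            assert stats[f"CD8_m_{a}"] == pytest.approx(200.0)
            assert stats[f"CD8_sd_{a}"] == 0.0

    def test_hand_table_one_hexagon_per_rank(self):
        iz = make_interface_zone([(r, float(d)) for d, r in
                                  enumerate(range(-4, 5), start=1)])
        stats = aspect_statistics(iz)
        assert stats["CD8_m_S"] == pytest.approx(2.5)
        assert stats["CD8_m_TE"] == pytest.approx(5.0)
        assert stats["CD8_m_T"] == pytest.approx(7.5)

    def test_missing_aspect_flagged_as_nan(self):
        iz = make_interface_zone([(0, 100.0), (1, 50.0)])
        stats = aspect_statistics(iz)
        assert np.isnan(stats["CD8_m_S"])
        assert stats["CD8_m_TE"] == pytest.approx(100.0)


class TestImmunodropAndCM:
    def test_stated_ratio(self):
        iz = make_interface_zone([(-1, 400.0), (1, 100.0)])
        value, flagged = immunodrop(iz)
        assert value == pytest.approx(4.0)
        assert not flagged

    def test_flat_profile_gives_one(self):
        iz = make_interface_zone([(r, 123.0) for r in range(-4, 5)])
        assert immunodrop(iz)[0] == pytest.approx(1.0)

    def test_zero_denominator_capped_and_flagged(self):
        iz = make_interface_zone([(-1, 400.0), (1, 0.0)])
        value, flagged = immunodrop(iz, EdgeDetectionConfig(id_cap=50.0))
        assert value == 50.0 and flagged

    def test_both_zero_defaults_to_one_flagged(self):
        iz = make_interface_zone([(-1, 0.0), (1, 0.0)])
        assert immunodrop(iz) == (1.0, True)

    def test_missing_rank_class_is_an_error(self):
        iz = make_interface_zone([(0, 10.0), (1, 10.0)])
        with pytest.raises(ValueError, match="rank"):
            immunodrop(iz)

    def test_cm_symmetric_profile_is_zero(self):
        iz = make_interface_zone([(r, 100.0 + 30 * abs(r)) for r in range(-4, 5)])
        assert center_of_mass(iz) == pytest.approx(0.0, abs=1e-12)

    def test_cm_point_mass_and_two_point_profiles(self):
        assert center_of_mass(make_interface_zone([(-4, 77.0)])) == -4.0
        iz = make_interface_zone([(-1, 300.0), (1, 100.0)])
        assert center_of_mass(iz) == pytest.approx(-0.5)

    def test_cm_undefined_without_mass(self):
        with pytest.raises(ValueError, match="center of mass"):
            center_of_mass(make_interface_zone([(0, 0.0)]))


class TestEndToEndGradient:
    def test_kappa4_slide_shows_drop_and_negative_cm(self, gradient_slide):
        tissue, cells = gradient_slide
        grid = hexgrid.make_grid((0, 0, 2400, 2400),
                                 hexgrid.cd8_grid_config(seed=21))
        fr = hexgrid.tissue_fractions(tissue.labels,
                                      tissue.resolution_um_per_px, grid)
        counts = hexgrid.assign_cells(cells[cells.marker == "cd8"], grid)
        cfg = EdgeDetectionConfig()
        edge = detect_tumor_edge(fr, cfg)
        ranks = assign_ranks(edge, fr, cfg)
        iz = extract_interface_zone(ranks, fr, counts)
        ind = immunogradient.immunogradient_indicators(iz, cfg)
        assert ind["CD8_ID"] > 1.5
        assert ind["CD8_CM"] < -0.3
        assert ind["CD8_m_S"] > ind["CD8_m_T"]
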