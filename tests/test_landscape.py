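"""Landscape metrics: closed forms, invariances, brute-force equivalence."""

import math

import numpy as np
import pytest

from emscape.landscape import (
    DEFAULT_CLASS_NAMES,
    LandscapeRaster,
    ai,
    circular_mask,
    class_proportion,
    enn_mn,
    iji,
    label_patches,
    lsi,
    para,
    read_ascii_grid,
    shape_index,
    shei,
    summarize_buffer,
    write_ascii_grid,
)


def raster(grid, cell=1.0, nodata=-9999):
    return LandscapeRaster(np.asarray(grid), cell, nodata, dict(DEFAULT_CLASS_NAMES))


def solid(code, size, cell=1.0):
    return raster(np.full((size, size), code), cell)


class TestPatches:
    def test_diagonal_cells_join_under_8_connectivity(self):
        g = np.full((3, 3), 2)
        g[0, 0] = g[1, 1] = 1
        ps = label_patches(raster(g))
        assert len(ps.by_class(1)) == 1

    def test_block_area_perimeter(self):
        g = np.full((6, 6), 2)
        g[1:5, 1:5] = 1
        ps = label_patches(raster(g))
        (p,) = ps.by_class(1)
        assert p.area == 16.0
        assert p.perimeter == 16.0

    def test_np_counts_all_patches(self):
        g = np.full((6, 9), 2)
        g[0:2, 0:2] = 1
        g[4:6, 0:2] = 1
        g[0:2, 6:8] = 3
        assert label_patches(raster(g)).np_total == 4  # 3 blocks + background

    def test_all_nodata_rejected(self):
        with pytest.raises(ValueError, match="all-nodata"):
            label_patches(raster(np.full((3, 3), -9999)))

    def test_perimeter_counts_nodata_and_border(self):
        g = np.array([[1, -9999], [1, 1]])
        ps = label_patches(raster(g))
        (p,) = ps.by_class(1)
        assert p.perimeter == 8.0  # 3 cells: 12 edges - 2*2 shared = 8


class TestClosedForms:
    def test_lsi_single_class_square(self):
        assert lsi(label_patches(solid(1, 8))) == pytest.approx(1.0)

    def test_lsi_two_class_vertical_split(self):
        g = np.full((8, 8), 1)
        g[:, 4:] = 2
        assert lsi(label_patches(raster(g))) == pytest.approx(1.25)

    def test_lsi_increases_with_internal_edge(self):
        g = np.full((8, 8), 1)
        base = lsi(label_patches(raster(g)))
        g[3, 3] = 2
        assert lsi(label_patches(raster(g))) > base

    def test_shei_two_even_classes(self):
        g = np.full((10, 10), 1)
        g[:, 5:] = 2
        assert shei(label_patches(raster(g))) == pytest.approx(1.0)

    def test_shei_single_class_zero(self):
        assert shei(label_patches(solid(1, 5))) == 0.0

    def test_shei_hand_computed(self):
        g = np.full((10, 10), 1)
        g[: 2][:] = 2  # 20 cells
        g[2:3][:] = 3  # 10 cells
        ps = label_patches(raster(g))
        p = np.array([0.7, 0.2, 0.1])
        expect = -(p * np.log(p)).sum() / math.log(3)
        assert shei(ps) == pytest.approx(expect)

    def test_ai_solid_block_100(self):
        g = np.full((6, 6), 2)
        g[1:5, 1:5] = 1
        assert ai(label_patches(raster(g)), 1) == pytest.approx(100.0)

    def test_ai_isolated_cells_zero(self):
        g = np.full((8, 8), 2)
        g[::2, ::2] = 1
        assert ai(label_patches(raster(g)), 1) == pytest.approx(0.0)

    def test_ai_single_cell_convention(self):
        g = np.full((4, 4), 2)
        g[1, 1] = 1
        assert ai(label_patches(raster(g)), 1) == 100.0

    def test_iji_equal_split_100(self):
        # native forest column between grassland and timber columns
        g = np.zeros((6, 6), dtype=int)
        g[:, :2] = 2
        g[:, 2:4] = 1
        g[:, 4:] = 3
        assert iji(label_patches(raster(g)), 1) == pytest.approx(100.0)

    def test_iji_single_neighbour_zero(self):
        g = np.zeros((6, 6), dtype=int)
        g[:, :3] = 2
        g[:, 3:] = 1
        g[0, 0] = 3  # third class present, but forest shares edge with grass only
        ps = label_patches(raster(g))
        assert iji(ps, 1) == pytest.approx(0.0)

    def test_iji_two_class_scene_undefined(self):
        g = np.zeros((4, 4), dtype=int)
        g[:, :2] = 1
        g[:, 2:] = 2
        assert math.isnan(iji(label_patches(raster(g)), 1))

    def test_enn_two_cells_three_apart(self):
        g = np.full((5, 7), 2)
        g[2, 1] = 1
        g[2, 4] = 1
        assert enn_mn(label_patches(raster(g, cell=30.0)), 1) == pytest.approx(90.0)

    def test_enn_single_patch_undefined(self):
        g = np.full((4, 4), 2)
        g[1, 1] = 1
        assert math.isnan(enn_mn(label_patches(raster(g)), 1))

    def test_enn_matches_bruteforce_three_patches(self):
        g = np.full((3, 12), 2)
        g[1, 0] = g[1, 5] = g[1, 9] = 1
        got = enn_mn(label_patches(raster(g)), 1)
        # per-patch nearest neighbour distances: 5, 4, 4 cells
        assert got == pytest.approx((5 + 4 + 4) / 3)

    def test_para_and_scale_dependence(self):
        g = np.full((6, 6), 2)
        g[1:5, 1:5] = 1
        (p1,) = label_patches(raster(g, cell=1.0)).by_class(1)
        (p2,) = label_patches(raster(g, cell=2.0)).by_class(1)
        assert para(p1) == pytest.approx(1.0)
        assert para(p2) == pytest.approx(0.5)
        assert shape_index(p1) == pytest.approx(shape_index(p2))

    def test_shape_square_one_strip_125(self):
        g = np.full((6, 6), 2)
        g[1:5, 1:5] = 1
        (sq,) = label_patches(raster(g)).by_class(1)
        assert shape_index(sq) == pytest.approx(1.0)
        g2 = np.full((3, 6), 2)
        g2[1, 1:5] = 1
        (strip,) = label_patches(raster(g2)).by_class(1)
        assert shape_index(strip) == pytest.approx(1.25)

    def test_class_proportions_sum_to_100(self, rng):
        g = rng.integers(1, 5, size=(15, 15))
        ps = label_patches(raster(g))
        total = sum(class_proportion(ps, c) for c in ps.class_codes())
        assert total == pytest.approx(100.0)
        assert class_proportion(ps, 6) == 0.0


class TestInvariances:
    @pytest.mark.parametrize("transform", [np.rot90, np.fliplr, np.flipud])
    def test_metrics_invariant_under_symmetry(self, rng, transform):
        g = rng.integers(1, 5, size=(12, 12))
        a = label_patches(raster(g))
        b = label_patches(raster(transform(g)))
        assert a.np_total == b.np_total
        assert lsi(a) == pytest.approx(lsi(b))
        assert shei(a) == pytest.approx(shei(b))
        assert ai(a) == pytest.approx(ai(b))

    def test_bounds_on_random_scenes(self, rng):
        for _ in range(25):
            g = rng.integers(1, 5, size=(10, 10))
            ps = label_patches(raster(g))
            assert lsi(ps) >= 1.0 - 1e-12
            assert 0 <= shei(ps) <= 1
            for c in ps.class_codes():
                assert 0 <= ai(ps, c) <= 100
                v = iji(ps, c)
                assert math.isnan(v) or -1e-9 <= v <= 100 + 1e-9
            for p in ps.patches:
                assert shape_index(p) >= 1.0 - 1e-12

    def test_like_joins_match_bruteforce(self, rng):
        g = rng.integers(1, 4, size=(9, 9))
        ps = label_patches(raster(g))
        for code in ps.class_codes():
            joins = 0
            for i in range(9):
                for j in range(9):
                    if g[i, j] != code:
                        continue
                    if i + 1 < 9 and g[i + 1, j] == code:
                        joins += 1
                    if j + 1 < 9 and g[i, j + 1] == code:
                        joins += 1
            assert ps.like_joins.get(code, 0) == joins


class TestReport:
    def scene(self):
        g = np.full((20, 20), 2)
        g[2:8, 2:8] = 1
        g[12:18, 12:18] = 3
        return raster(g, cell=30.0)

    def test_report_columns_exact(self):
        from emscape.landscape import REPORT_COLUMNS

        rep = summarize_buffer(self.scene())
        assert list(rep.index) == REPORT_COLUMNS

    def test_report_values_match_component_metrics(self):
        r = self.scene()
        rep = summarize_buffer(r)
        ps = label_patches(r)
        assert rep["NP"] == ps.np_total
        assert rep["LSI"] == pytest.approx(lsi(ps))
        assert rep["P_NF"] == pytest.approx(class_proportion(ps, 1))
        assert rep["N_NF"] == 1
        assert math.isnan(rep["ENN"])
        assert rep["SHAPE"] == pytest.approx(1.0)

    def test_water_urban_excluded_by_default(self):
        g = np.full((10, 10), 2)
        g[0:5, 0:5] = 1
        g[9, 9] = 5  # water
        rep = summarize_buffer(raster(g))
        # proportions computed over land classes only
        assert rep["P_NF"] == pytest.approx(100 * 25 / 99)

    def test_missing_focal_patch_rejected(self):
        with pytest.raises(ValueError, match="no patch with id"):
            summarize_buffer(self.scene(), focal_patch_id=999)


class TestMask:
    def test_circular_mask_radius(self):
        m = circular_mask((7, 7), (3, 3), 2.0)
        assert m[3, 3] and m[3, 5] and not m[0, 0]
        assert m.sum() == 13


class TestIO:
    def test_ascii_grid_round_trip(self, tmp_path, rng):
        g = rng.integers(1, 5, size=(6, 8))
        r = raster(g, cell=30.0)
        p = tmp_path / "scene.asc"
        write_ascii_grid(r, p)
        back = read_ascii_grid(p)
        np.testing.assert_array_equal(back.grid, r.grid)
        assert back.cell_size == 30.0
        assert back.nodata == r.nodata

    def test_header_mismatch_rejected(self, tmp_path):
        p = tmp_path / "bad.asc"
        p.write_text("ncols 3\nnrows 2\ncellsize 1\n1 1 1\n")
        with pytest.raises(ValueError, match="header says"):
            read_ascii_grid(p)
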