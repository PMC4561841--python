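"""Raster indices, zonal statistics, and the collinearity screen."""

import numpy as np
import pandas as pd
import pytest

from chorusnet.terrain import (
    LANDCOVER_CODES,
    CollinearityFilter,
    RasterGrid,
    _segment_mask,
    buffer_stats,
    collinearity_screen,
    corridor_stats,
    cti,
    read_ascii_grid,
    rsp,
    slope_and_flowacc,
    srr,
    topo_distance,
    write_ascii_grid,
)

_MIN_TANB = np.tan(0.001)


def grid(values, cellsize=30.0, xll=0.0, yll=0.0):
    return RasterGrid(np.asarray(values, dtype=float), xll, yll, cellsize)


def brute_accumulation(z: np.ndarray) -> np.ndarray:
    """Independent upslope-cell count: follow steepest-descent receivers
    (computed here from scratch) and count, for each cell, every cell whose
    drainage path passes through it. Valid on grids without flats."""
    nrows, ncols = z.shape
    offsets = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
    recv = {}
    for i in range(nrows):
        for j in range(ncols):
            candidates = []
            for di, dj in offsets:
                ni, nj = i + di, j + dj
                if 0 <= ni < nrows and 0 <= nj < ncols:
                    drop = (z[i, j] - z[ni, nj]) / np.hypot(di, dj)
                    candidates.append((drop, (ni, nj)))
            drop, target = max(candidates, key=lambda t: t[0])
            recv[(i, j)] = target if drop > 0 else None
    acc = np.zeros_like(z)
    for start in recv:
        cell = start
        seen = set()
        while cell is not None and cell not in seen:
            acc[cell] += 1
            seen.add(cell)
            cell = recv[cell]
    return acc


class TestSlopeAndFlow:
    def test_flat_dem_zero_slope(self):
        slope, _ = slope_and_flowacc(grid(np.full((5, 5), 42.0)))
        assert np.all(slope == 0)

    def test_single_cell_accumulates_itself(self):
        _, acc = slope_and_flowacc(grid([[7.0]]))
        assert acc[0, 0] == 1

    def test_inclined_plane_increments_along_fall_line(self):
        z = np.tile(np.arange(6, dtype=float)[::-1] * 5, (4, 1))  # falls east
        _, acc = slope_and_flowacc(grid(z))
        for row in acc:
            np.testing.assert_array_equal(row, np.arange(1, 7))

    def test_matches_brute_force_on_random_terrain(self):
        rng = np.random.default_rng(8)
        z = rng.uniform(0, 100, size=(8, 8))  # continuous: no flats
        _, acc = slope_and_flowacc(grid(z))
        np.testing.assert_array_equal(acc, brute_accumulation(z))

    def test_all_nan_dem_rejected(self):
        with pytest.raises(ValueError):
            slope_and_flowacc(grid(np.full((3, 3), np.nan)))


class TestCti:
    def test_flat_dem_uses_slope_floor(self):
        g = grid(np.zeros((4, 4)), cellsize=10.0)
        out = cti(g)
        _, acc = slope_and_flowacc(g)
        expected = np.log(acc * 10.0 / _MIN_TANB)
        np.testing.assert_allclose(out, expected)

    def test_monotone_decreasing_in_slope(self):
        cs = 10.0
        gentle = grid(np.tile(np.arange(5) * 1.0, (5, 1)), cellsize=cs)
        steep = grid(np.tile(np.arange(5) * 8.0, (5, 1)), cellsize=cs)
        # compare center cells: identical accumulation structure, steeper slope
        assert cti(steep)[2, 2] < cti(gentle)[2, 2]

    def test_plane_interior_matches_manual_formula(self):
        cs = 10.0
        z = np.tile(np.arange(3, dtype=float)[::-1] * 2.0, (3, 1))
        g = grid(z, cellsize=cs)
        slope, acc = slope_and_flowacc(g)
        out = cti(g)
        i, j = 1, 1
        manual = np.log(acc[i, j] * cs / max(np.tan(slope[i, j]), _MIN_TANB))
        assert out[i, j] == pytest.approx(manual)
        assert slope[i, j] == pytest.approx(np.arctan(2.0 / cs))


class TestSrrRsp:
    def test_srr_two_level_zone(self):
        g = grid([[0.0, 10.0], [0.0, 10.0]])
        assert srr(g, np.ones((2, 2), bool)) == pytest.approx(0.5)

    def test_srr_skewed_zone(self):
        g = grid([[0.0, 0.0], [0.0, 10.0]])
        assert srr(g, np.ones((2, 2), bool)) == pytest.approx(0.25)

    def test_srr_flat_zone_midpoint_convention(self):
        g = grid(np.full((3, 3), 5.0))
        assert srr(g, np.ones((3, 3), bool)) == 0.5

    def test_srr_empty_zone_rejected(self):
        with pytest.raises(ValueError):
            srr(grid(np.zeros((2, 2))), np.zeros((2, 2), bool))

    def test_rsp_extremes_and_ramp(self):
        z = np.tile(np.arange(11, dtype=float), (11, 1))
        g = grid(z, cellsize=10.0)
        low = (5.0, 55.0)    # westmost column center
        high = (105.0, 55.0)
        mid = (55.0, 55.0)
        r = 200.0  # window covers the whole grid
        assert rsp(g, low, r) == pytest.approx(0.0)
        assert rsp(g, high, r) == pytest.approx(1.0)
        assert rsp(g, mid, r) == pytest.approx(0.5)

    def test_rsp_flat_window(self):
        g = grid(np.full((5, 5), 3.0))
        assert rsp(g, (75.0, 75.0), 50.0) == 0.5

    def test_rsp_off_grid_center_rejected(self):
        with pytest.raises(ValueError):
            rsp(grid(np.zeros((3, 3))), (-500.0, 0.0), 30.0)


def make_rasters(landcover=None, dem=None, summer=0.4, annual=1.0, shape=(9, 9), cellsize=10.0):
    lc = landcover if landcover is not None else np.full(shape, LANDCOVER_CODES["meadow"], float)
    z = dem if dem is not None else np.zeros(shape)
    return {
        "dem": grid(z, cellsize),
        "landcover": grid(lc, cellsize),
        "ppt_summer": grid(np.full(shape, summer), cellsize),
        "ppt_annual": grid(np.full(shape, annual), cellsize),
        "impervious": grid((lc == LANDCOVER_CODES["impervious"]).astype(float), cellsize),
    }


class TestBufferStats:
    def test_all_meadow_smoothed_ratio(self):
        rasters = make_rasters()
        out = buffer_stats(rasters, (45.0, 45.0), radius=16.0)  # 3x3 = 9 cells
        assert out["mf_at"] == pytest.approx(10.0)  # (9+1)/(0+1)
        assert out["imperv_at"] == 0.0

    def test_uniform_precipitation_ratio(self):
        out = buffer_stats(make_rasters(summer=0.4, annual=1.0), (45.0, 45.0), radius=25.0)
        assert out["pratio_at"] == pytest.approx(0.4)

    def test_off_grid_buffer_rejected(self):
        with pytest.raises(ValueError):
            buffer_stats(make_rasters(), (1e6, 1e6), radius=20.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        z = rng.uniform(0, 50, (9, 9))
        base = make_rasters(dem=z)
        shifted = make_rasters(dem=z)
        for g in shifted.values():
            g.xllcorner += 1000.0
            g.yllcorner += 2000.0
        a = buffer_stats(base, (45.0, 45.0), radius=30.0)
        b = buffer_stats(shifted, (1045.0, 2045.0), radius=30.0)
        for key in a:
            assert a[key] == pytest.approx(b[key], abs=1e-12)


class TestCorridorStats:
    def test_uniform_raster_any_bandwidth(self):
        rasters = make_rasters(summer=0.37)
        for bw in (30.0, 60.0, 120.0, 240.0):
            out = corridor_stats(rasters, (15.0, 45.0), (75.0, 45.0), bandwidth=bw)
            assert out["pratio_bet"] == pytest.approx(0.37)

    def test_bandwidth_nesting(self):
        g = grid(np.zeros((10, 10)), cellsize=10.0)
        masks = {
            bw: _segment_mask(g, (15.0, 55.0), (85.0, 35.0), bw / 2.0)
            for bw in (30.0, 60.0, 120.0, 240.0)
        }
        assert np.all(masks[30.0] <= masks[60.0])
        assert np.all(masks[60.0] <= masks[120.0])
        assert np.all(masks[120.0] <= masks[240.0])

    def test_cell_selection_matches_brute_force(self):
        g = grid(np.zeros((10, 10)), cellsize=10.0)
        p, q = (12.0, 81.0), (88.0, 23.0)
        half = 30.0
        mask = _segment_mask(g, p, q, half)
        px, py = p
        qx, qy = q
        for i in range(10):
            for j in range(10):
                cx = (j + 0.5) * 10.0
                cy = (10 - i - 0.5) * 10.0
                # brute-force point-to-segment distance
                vx, vy = qx - px, qy - py
                t = max(0.0, min(1.0, ((cx - px) * vx + (cy - py) * vy) / (vx**2 + vy**2)))
                d = np.hypot(cx - (px + t * vx), cy - (py + t * vy))
                assert mask[i, j] == (d <= half)

    def test_symmetric_in_endpoints(self):
        rng = np.random.default_rng(2)
        rasters = make_rasters(dem=rng.uniform(0, 30, (9, 9)))
        a = corridor_stats(rasters, (15.0, 15.0), (75.0, 65.0), 60.0)
        b = corridor_stats(rasters, (75.0, 65.0), (15.0, 15.0), 60.0)
        for key in a:
            assert a[key] == pytest.approx(b[key])

    def test_zero_length_corridor_warns_and_degrades(self):
        with pytest.warns(UserWarning, match="zero-length"):
            out = corridor_stats(make_rasters(), (45.0, 45.0), (45.0, 45.0), 60.0)
        assert out["pratio_bet"] == pytest.approx(0.4)


class TestTopoDistance:
    def test_flat_equals_euclidean(self):
        g = grid(np.full((20, 20), 7.0), cellsize=10.0)
        assert topo_distance(g, (10.0, 10.0), (150.0, 100.0)) == pytest.approx(
            np.hypot(140.0, 90.0)
        )

    def test_45_degree_slope_scales_by_sqrt2(self):
        cs = 10.0
        cols = np.arange(30, dtype=float)
        z = np.tile((cols + 0.5) * cs, (5, 1))  # z = x exactly at cell centers
        g = grid(z, cellsize=cs)
        d = topo_distance(g, (25.0, 25.0), (255.0, 25.0))
        assert d == pytest.approx(230.0 * np.sqrt(2), rel=1e-9)

    def test_identical_endpoints_zero(self):
        g = grid(np.zeros((5, 5)))
        assert topo_distance(g, (20.0, 20.0), (20.0, 20.0)) == 0.0

    def test_relief_never_shortens(self):
        rng = np.random.default_rng(3)
        flat = grid(np.zeros((12, 12)), cellsize=10.0)
        rough = grid(rng.uniform(0, 15, (12, 12)), cellsize=10.0)
        p, q = (15.0, 15.0), (105.0, 95.0)
        assert topo_distance(rough, p, q) >= topo_distance(flat, p, q)


class TestAsciiGridIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        g = RasterGrid(rng.uniform(0, 10, (4, 6)), 100.0, 250.0, 30.0)
        path = tmp_path / "g.asc"
        write_ascii_grid(g, path)
        g2 = read_ascii_grid(path)
        np.testing.assert_allclose(g2.values, g.values, atol=1e-6)
        assert (g2.xllcorner, g2.yllcorner, g2.cellsize) == (100.0, 250.0, 30.0)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "bad.asc"
        path.write_text("ncols 2\n1 2\n3 4\n")
        with pytest.raises(ValueError, match="nrows"):
            read_ascii_grid(path)


class TestCollinearityScreen:
    def test_perfect_duplicate_drops_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=50)})
        kept = collinearity_screen(df)
        assert "c" in kept and len(kept) == 2

    def test_orthogonal_design_keeps_all(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        assert set(collinearity_screen(df)) == set("abcd")

    def test_near_duplicate_dropped_and_vifs_bounded(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=300)
        y = rng.normal(size=300)
        near = 0.95 * x + 0.05 * rng.normal(size=300)  # r > 0.95 with x
        df = pd.DataFrame({"x": x, "near": near, "y": y})
        filt = CollinearityFilter().fit(df)
        assert "y" in filt.retained_ and len(filt.retained_) == 2
        assert CollinearityFilter._vifs(df[filt.retained_]).max() < 5

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"a": rng.normal(size=30), "k": np.ones(30),
                           "b": rng.normal(size=30)})
        with pytest.warns(UserWarning, match="constant"):
            kept = collinearity_screen(df)
        assert "k" not in kept

    def test_transform_subsets_columns(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=60)
        df = pd.DataFrame({"a": x, "b": -x, "c": rng.normal(size=60)})
        filt = CollinearityFilter().fit(df)
        out = filt.transform(df)
        assert list(out.columns) == filt.retained_

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            collinearity_screen(pd.DataFrame({"a": [1.0, 2.0]}))
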