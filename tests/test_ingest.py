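import datetime as dt
import logging

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon

import cropwater as cw
from cropwater.grid import RasterGrid
from cropwater.ingest import FieldBoundary, field_pixel_mask

D0 = dt.date(2022, 6, 1)


def _single_layer(grid, array, date=D0, var="et"):
    return {date: {var: np.asarray(array, dtype=float)}}


def square(col0, row0, cols, rows, s):
    return Polygon(
        [(col0 * s, row0 * s), ((col0 + cols) * s, row0 * s),
         ((col0 + cols) * s, (row0 + rows) * s), (col0 * s, (row0 + rows) * s)]
    )


def brute_force_zonal(grid, array, polygon):
    """Independent oracle: loop every pixel center with a point-in-polygon
    test, applying the same left/top-inclusive rule for boundary centers."""
    s = grid.pixel_size_m
    eps = 1e-9 * s
    vals = []
    for r in range(grid.rows):
        for c in range(grid.cols):
            x, y = (c + 0.5) * s, (r + 0.5) * s
            pt = Point(x, y)
            inside = polygon.contains(pt)
            if not inside and polygon.intersects(pt):
                inside = polygon.contains(Point(x + eps, y + eps))
            if inside and np.isfinite(array[r, c]):
                vals.append(array[r, c])
    return (float(np.mean(vals)), len(vals)) if vals else (float("nan"), 0)


def random_star_polygon(rng, grid):
    """Irregular simple polygon: random radii around a random center, sorted
    by angle."""
    s = grid.pixel_size_m
    cx = rng.uniform(0.25, 0.75) * grid.cols * s
    cy = rng.uniform(0.25, 0.75) * grid.rows * s
    n = int(rng.integers(5, 12))
    # jittered evenly-spaced angles: gaps stay < pi, so the polygon is simple
    angles = 2 * np.pi * (np.arange(n) + rng.uniform(0, 0.8, n)) / n
    radii = rng.uniform(0.1, 0.45) * min(grid.cols, grid.rows) * s
    radii = radii * rng.uniform(0.4, 1.0, n)
    pts = [(cx + r * np.cos(a), cy + r * np.sin(a)) for r, a in zip(radii, angles)]
    return Polygon(pts)


class TestZonalDailyStats:
    def test_single_pixel_field(self):
        grid = RasterGrid(3, 3, 10.0)
        arr = np.zeros((3, 3))
        arr[1, 1] = 7.0
        layers = _single_layer(grid, arr)
        out = cw.zonal_daily_stats(layers, grid, [("f1", "corn", square(1, 1, 1, 1, 10.0))])
        assert out.loc[0, "mean"] == 7.0
        assert out.loc[0, "n_pixels"] == 1

    def test_four_pixel_mean(self):
        grid = RasterGrid(2, 2, 10.0)
        arr = np.array([[2.0, 4.0], [6.0, 8.0]])
        out = cw.zonal_daily_stats(
            _single_layer(grid, arr), grid, [("f1", "corn", square(0, 0, 2, 2, 10.0))]
        )
        assert out.loc[0, "mean"] == 5.0
        assert out.loc[0, "n_pixels"] == 4

    def test_matches_brute_force_on_random_scenes(self):
        grid = RasterGrid(50, 50, 70.0)
        rng = np.random.default_rng(12)
        for _ in range(5):
            arr = rng.normal(5, 2, grid.shape)
            arr[rng.random(grid.shape) < 0.1] = np.nan  # nodata holes
            poly = random_star_polygon(rng, grid)
            out = cw.zonal_daily_stats(_single_layer(grid, arr), grid, [("f", "c", poly)])
            mean_o, n_o = brute_force_zonal(grid, arr, poly)
            assert out.loc[0, "n_pixels"] == n_o
            assert out.loc[0, "mean"] == pytest.approx(mean_o, rel=1e-12)

    def test_permutation_invariance(self, noisy_scene):
        bounds = [
            FieldBoundary(r.field_id, r.crop, r.polygon)
            for r in noisy_scene.field_table.itertuples()
        ]
        a = cw.zonal_daily_stats(noisy_scene.daily_layers, noisy_scene.grid, bounds)
        b = cw.zonal_daily_stats(noisy_scene.daily_layers, noisy_scene.grid, bounds[::-1])
        key = ["variable", "field_id", "date"]
        pd.testing.assert_frame_equal(
            a.sort_values(key, ignore_index=True), b.sort_values(key, ignore_index=True)
        )

    def test_conservation_of_field_totals(self, noisy_scene):
        """Sum over fields of mean x pixel count equals the raster total over
        all field pixels, per date/variable."""
        bounds = noisy_scene.field_polygons()
        stats = cw.zonal_daily_stats(noisy_scene.daily_layers, noisy_scene.grid, bounds)
        field_mask = noisy_scene.class_map >= 0
        for d in noisy_scene.dates[:: 25]:
            for var, arr in noisy_scene.daily_layers[d].items():
                sub = stats[(stats["date"] == pd.Timestamp(d)) & (stats["variable"] == var)]
                total = (sub["mean"] * sub["n_pixels"]).sum()
                expected = np.nansum(arr[field_mask])
                assert total == pytest.approx(expected, rel=1e-9, abs=1e-9)

    def test_boundary_outside_grid_flagged(self, caplog):
        grid = RasterGrid(4, 4, 10.0)
        far = square(100, 100, 2, 2, 10.0)
        with caplog.at_level(logging.WARNING, logger="cropwater.ingest"):
            out = cw.zonal_daily_stats(
                _single_layer(grid, np.ones((4, 4))), grid, [("f_far", "corn", far)]
            )
        assert "outside" in caplog.text
        assert (out["n_pixels"] == 0).all()  # emitted, not dropped

    def test_adjacent_fields_do_not_double_count(self):
        """Half-open convention: a shared edge never assigns a center twice."""
        grid = RasterGrid(4, 4, 10.0)
        left = square(0, 0, 2, 4, 10.0)
        right = square(2, 0, 2, 4, 10.0)
        m_left = field_pixel_mask(grid, left)
        m_right = field_pixel_mask(grid, right)
        assert not np.any(m_left & m_right)
        assert (m_left.sum() + m_right.sum()) == grid.n_pixels

    def test_no_boundaries_raises(self):
        grid = RasterGrid(2, 2, 10.0)
        with pytest.raises(ValueError):
            cw.zonal_daily_stats(_single_layer(grid, np.ones((2, 2))), grid, [])


class TestClassAreas:
    def test_count_times_area(self):
        cm = np.full((10, 10), -1)
        cm.ravel()[:100] = 0
        out = cw.tabulate_class_areas(cm, 0.49, labels=["corn"])
        assert out.loc[0, "crop"] == "corn"
        assert out.loc[0, "pixel_count"] == 100
        assert out.loc[0, "area_ha"] == pytest.approx(49.0)

    def test_empty_map(self):
        out = cw.tabulate_class_areas(np.full((5, 5), -1), 0.49)
        assert out.empty

    def test_three_class_map_matches_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        cm = rng.integers(-1, 3, size=(30, 30))
        labels = ["corn", "alfalfa", "soy"]
        out = cw.tabulate_class_areas(cm, 0.49, labels=labels).set_index("crop")
        counts = {lab: 0 for lab in labels}
        for v in cm.ravel():  # brute-force scan
            if v >= 0:
                counts[labels[v]] += 1
        for lab in labels:
            assert out.loc[lab, "pixel_count"] == counts[lab]

    def test_clip_then_tabulate_equals_tabulate_then_subset(self):
        rng = np.random.default_rng(6)
        cm = rng.integers(-1, 3, size=(20, 20))
        region = np.zeros((20, 20), dtype=bool)
        region[:10, :] = True
        clipped = cw.tabulate_class_areas(cm, 0.49, region_mask=region)
        manual = cw.tabulate_class_areas(cm[:10, :], 0.49)
        pd.testing.assert_frame_equal(clipped, manual)

    def test_nonpositive_pixel_area_rejected(self):
        with pytest.raises(ValueError):
            cw.tabulate_class_areas(np.zeros((2, 2), dtype=int), 0.0)


class TestDropEmpty:
    def test_removes_zero_pixel_records(self):
        df = pd.DataFrame(
            {
                "field_id": list("abcde"),
                "crop": "corn",
                "date": pd.Timestamp(D0),
                "variable": "et",
                "mean": [1.0, 2.0, np.nan, 4.0, 5.0],
                "n_pixels": [3, 3, 0, 3, 3],
            }
        )
        out = cw.drop_empty(df)
        assert len(out) == 4
        assert np.isfinite(out["mean"]).all()

    def test_all_valid_identity(self):
        df = pd.DataFrame(
            {"field_id": ["a"], "crop": ["c"], "date": [pd.Timestamp(D0)],
             "variable": ["et"], "mean": [1.0], "n_pixels": [2]}
        )
        pd.testing.assert_frame_equal(cw.drop_empty(df), df)

    def test_empty_month_absent_downstream(self, clean_scene):
        """Blanking a whole month of ET rasters removes that month from the
        aggregation, matching a manual removal list."""
        layers = {
            d: {v: a for v, a in lay.items()}
            for d, lay in clean_scene.daily_layers.items()
            if not (d.month == 7)
        }
        stats = cw.drop_empty(
            cw.zonal_daily_stats(layers, clean_scene.grid, clean_scene.field_polygons())
        )
        assert not (pd.to_datetime(stats["date"]).dt.month == 7).any()
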