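"""Feature description: zonal attributes, initial slope, joins, coral cover."""

import numpy as np
import pytest
import shapely
from hypothesis import given, settings
from hypothesis import strategies as st
from matplotlib.path import Path as MplPath
from shapely.affinity import translate
from shapely.geometry import Polygon, box
from _oracles import cover_fraction_monte_carlo

from reefmounds import (
    AnnulusSpec,
    FeaturePolygon,
    Grid,
    MoundSpec,
    SyntheticSceneConfig,
    attributes_table,
    classify_cover,
    compute_bpi,
    cover_class,
    delineate,
    describe_features,
    generate_dem,
    initial_slope,
    join_current,
    rugosity,
)
from conftest import make_mound_grid


def _describe(dem, bpi, features, **kw):
    return describe_features(dem, bpi, features, rugosity(dem), **kw)


def _feature(poly, fid=1):
    return FeaturePolygon(feature_id=fid, ring=poly, raw_ring=poly)


class TestDescribe:
    def test_flat_topped_block(self):
        # 10-m-high flat block on a horizontal seabed at 150 m depth
        z = np.full((40, 40), -150.0)
        z[15:25, 15:25] = -140.0
        dem = Grid(z, 2.0, origin=(0.0, 80.0))
        ring = box(26.0, 26.0, 54.0, 54.0)  # block plus a seabed margin
        rec = _describe(dem, compute_bpi(dem, AnnulusSpec(2, 6)),
                        [_feature(ring)], compute_initial_slope=False)[0]
        assert rec.min_wd == pytest.approx(140.0)
        assert rec.max_wd == pytest.approx(150.0)
        assert rec.max_vrelief == pytest.approx(10.0)
        assert rec.mbg_w_l == pytest.approx(1.0)
        assert 140.0 <= rec.mean_wd <= 150.0

    def test_planted_mound_height_and_orientation_recovered(self):
        mound = MoundSpec(150, 150, 8.0, sd_major=9.0, sd_minor=4.0, azimuth_deg=30.0)
        cfg = SyntheticSceneConfig(
            grid_shape=(150, 150), cell_size=2.0, base_depth=150.0,
            plane_slope_deg=0.0, ridge=None, mounds=[mound], noise_sd=0.0, seed=0,
        )
        dem, registry = generate_dem(cfg)
        cells = registry[0]["footprint_cells"]
        xs = (cells[:, 1] + 0.5) * 2.0
        ys = 300.0 - (cells[:, 0] + 0.5) * 2.0
        ring = shapely.concave_hull(shapely.MultiPoint(np.column_stack([xs, ys])), ratio=0.5)
        ring = ring.buffer(1.5)
        rec = _describe(dem, compute_bpi(dem), [_feature(ring)],
                        compute_initial_slope=False)[0]
        # crest can be missed by at most one cell of the steepest flank, and
        # the outline truncates the skirt at the 0.2-m footprint threshold
        g_max = mound.height / (mound.sd_minor * np.sqrt(np.e))
        assert rec.max_vrelief <= 8.0 + 1e-6
        assert rec.max_vrelief >= 8.0 - 0.2 - g_max * 2.0
        assert abs(rec.mbg_orient - 30.0) <= 5.0

    def test_zonal_mean_depth_matches_point_in_polygon_loop(self, small_scene_features):
        dem, bpi, features, _ = small_scene_features
        recs = _describe(dem, bpi, features, compute_initial_slope=False)
        feat, rec = features[2], recs[2]
        path = MplPath(np.asarray(feat.ring.exterior.coords))
        depths = []
        for row in range(dem.shape[0]):
            for col in range(dem.shape[1]):
                x, y = dem.cell_center(row, col)
                if path.contains_point((x, y)):
                    depths.append(-dem.values[row, col])
        assert rec.mean_wd == pytest.approx(np.mean(depths), abs=1e-6)

    def test_confined_contour_deeper_than_summit_shallower_than_base(
        self, small_scene_features
    ):
        dem, bpi, features, _ = small_scene_features
        recs = _describe(dem, bpi, features, compute_initial_slope=False)
        for rec in recs:
            assert rec.min_wd < rec.confcl_wd <= rec.max_wd + 1e-9
            assert 0 <= rec.min_vrelief <= rec.max_vrelief

    def test_empty_polygon_yields_nodata_record_with_warning(self, small_scene_features):
        dem, bpi, _, _ = small_scene_features
        tiny = _feature(box(10.0, 10.0, 10.5, 10.5), fid=99)
        with pytest.warns(UserWarning, match="no cell centres"):
            rec = _describe(dem, bpi, [tiny], compute_initial_slope=False)[0]
        assert np.isnan(rec.mean_wd)

    def test_translation_invariance(self, small_scene_features):
        dem, bpi, features, _ = small_scene_features
        recs = _describe(dem, bpi, features, compute_initial_slope=False)
        dx, dy = 5000.0, -3000.0
        dem2 = Grid(dem.values, dem.cell_size, (dem.origin[0] + dx, dem.origin[1] + dy))
        bpi2 = Grid(bpi.values, bpi.cell_size, dem2.origin)
        feats2 = [
            FeaturePolygon(f.feature_id, translate(f.ring, dx, dy),
                           translate(f.raw_ring, dx, dy))
            for f in features
        ]
        recs2 = _describe(dem2, bpi2, feats2, compute_initial_slope=False)
        for a, b in zip(recs, recs2):
            assert a.mean_wd == pytest.approx(b.mean_wd, abs=1e-9)
            assert a.max_vrelief == pytest.approx(b.max_vrelief, abs=1e-9)
            assert a.area == pytest.approx(b.area, rel=1e-12)
            assert a.mbg_orient == pytest.approx(b.mbg_orient, abs=1e-9)

    def test_reproducible_across_runs(self, small_scene_features):
        dem, bpi, features, _ = small_scene_features
        a = attributes_table(_describe(dem, bpi, features))
        b = attributes_table(_describe(dem, bpi, features))
        assert a.equals(b)


class TestInitialSlope:
    @staticmethod
    def _skirt_feature(dem, height=8.0, sd=5.0):
        # outline covering the whole planted skirt (mound term < 0.2 m outside)
        cx = dem.shape[1] * dem.cell_size / 2
        cy = dem.shape[0] * dem.cell_size / 2
        radius = sd * np.sqrt(2 * np.log(height / 0.2)) + 2 * dem.cell_size
        return _feature(shapely.Point(cx, cy).buffer(radius, quad_segs=32))

    def test_mound_on_horizontal_plane_is_flat(self):
        dem = make_mound_grid(shape=(70, 70), plane_slope_deg=0.0)
        assert initial_slope(dem, self._skirt_feature(dem)) < 0.5

    def test_mound_on_five_degree_plane_recovers_plane(self):
        dem = make_mound_grid(shape=(70, 70), plane_slope_deg=5.0)
        assert initial_slope(dem, self._skirt_feature(dem)) == pytest.approx(5.0, abs=0.5)

    def test_zero_cell_feature_errors(self):
        dem = make_mound_grid()
        with pytest.raises(ValueError, match="no cell centres"):
            initial_slope(dem, _feature(box(1.0, 1.0, 1.2, 1.2)))

    def test_feature_touching_edge_errors(self):
        dem = make_mound_grid()
        with pytest.raises(ValueError, match="edge"):
            initial_slope(dem, _feature(box(-5.0, -5.0, 30.0, 30.0)))


class TestJoinCurrent:
    def test_uniform_current_everywhere(self, small_scene_features):
        dem, bpi, features, _ = small_scene_features
        recs = _describe(dem, bpi, features, compute_initial_slope=False)
        cur = Grid(np.full((4, 4), 0.3), 100.0, origin=(0.0, 400.0))
        recs = join_current(recs, features, cur)
        assert all(r.max_current == pytest.approx(0.3) for r in recs)

    def test_two_sided_current(self, small_scene_features):
        dem, bpi, features, _ = small_scene_features
        recs = _describe(dem, bpi, features, compute_initial_slope=False)
        vals = np.zeros((4, 4))
        vals[:, :2] = 0.2
        vals[:, 2:] = 0.7
        cur = Grid(vals, 100.0, origin=(0.0, 400.0))
        recs = join_current(recs, features, cur)
        for f, r in zip(features, recs):
            expect = 0.2 if f.ring.centroid.x < 200 else 0.7
            assert r.max_current == pytest.approx(expect)

    def test_random_current_matches_direct_indexing(self, small_scene_features, rng):
        dem, bpi, features, _ = small_scene_features
        recs = _describe(dem, bpi, features, compute_initial_slope=False)
        vals = rng.uniform(0.1, 0.9, (4, 4))
        cur = Grid(vals, 100.0, origin=(0.0, 400.0))
        recs = join_current(recs, features, cur)
        for f, r in zip(features, recs):
            col = int(f.ring.centroid.x // 100)
            row = int((400 - f.ring.centroid.y) // 100)
            assert r.max_current == pytest.approx(vals[row, col])

    def test_centroid_outside_extent_warns(self, small_scene_features):
        dem, bpi, features, _ = small_scene_features
        recs = _describe(dem, bpi, features, compute_initial_slope=False)
        cur = Grid(np.full((2, 2), 0.5), 10.0, origin=(-1000.0, -1000.0))
        with pytest.warns(UserWarning, match="outside"):
            recs = join_current(recs, features, cur)
        assert all(np.isnan(r.max_current) for r in recs)


class TestCoverClass:
    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(pct=st.floats(0, 100))
    def test_classify_assigns_exactly_one_halfopen_bin(self, pct):
        cls = classify_cover(pct)
        bounds = {"=0": (0, 0), "]0;25]": (0, 25), "]25;50]": (25, 50),
                  "]50;75]": (50, 75), "]75;100]": (75, 100)}
        lo, hi = bounds[cls]
        assert (pct == 0 and cls == "=0") or lo < pct <= hi

    def test_classify_bins_are_right_inclusive(self):
        assert classify_cover(0.0) == "=0"
        assert classify_cover(0.01) == "]0;25]"
        assert classify_cover(25.0) == "]0;25]"
        assert classify_cover(50.0) == "]25;50]"
        assert classify_cover(75.0001) == "]75;100]"
        assert classify_cover(100.0) == "]75;100]"
        with pytest.raises(ValueError):
            classify_cover(101.0)

    def test_no_overlap_half_overlap_full_overlap(self, small_scene_features):
        dem, bpi, features, _ = small_scene_features
        feat = _feature(box(0.0, 0.0, 20.0, 20.0))
        recs = _describe(dem, bpi, [feat], compute_initial_slope=False)
        no = cover_class([recs[0]], [feat], [box(100.0, 100.0, 110.0, 110.0)])[0]
        assert (no.cover_pct, no.cover_class, no.presence) == (0.0, "=0", False)
        half = cover_class([recs[0]], [feat], [box(0.0, 0.0, 10.0, 20.0)])[0]
        assert half.cover_pct == pytest.approx(50.0)
        assert half.cover_class == "]25;50]"  # 50 is right-inclusive
        full = cover_class([recs[0]], [feat], [box(-5.0, -5.0, 25.0, 25.0)])[0]
        assert full.cover_pct == pytest.approx(100.0)
        assert full.presence is True

    def test_random_overlap_matches_monte_carlo(self, small_scene_features, rng):
        dem, bpi, features, _ = small_scene_features
        feat = features[0]
        rec = _describe(dem, bpi, [feat], compute_initial_slope=False)[0]
        cx, cy = feat.ring.centroid.x, feat.ring.centroid.y
        corals = [
            shapely.Point(cx + 4, cy - 2).buffer(6.0),
            shapely.Point(cx - 7, cy + 5).buffer(4.0),
        ]
        rec = cover_class([rec], [feat], corals)[0]
        mc = 100.0 * cover_fraction_monte_carlo(feat.ring, corals, rng)
        assert rec.cover_pct == pytest.approx(mc, abs=1.0)

    def test_cover_classes_partition_features(self, small_scene_features, rng):
        dem, bpi, features, _ = small_scene_features
        recs = _describe(dem, bpi, features, compute_initial_slope=False)
        corals = [
            shapely.Point(f.ring.centroid.x + rng.uniform(-8, 8),
                          f.ring.centroid.y + rng.uniform(-8, 8)).buffer(rng.uniform(1, 9))
            for f in features[::2]
        ]
        recs = cover_class(recs, features, corals)
        counts = {cls: 0 for cls in ("=0", "]0;25]", "]25;50]", "]50;75]", "]75;100]")}
        for r in recs:
            assert 0 <= r.cover_pct <= 100
            counts[r.cover_class] += 1
        assert sum(counts.values()) == len(features)

    def test_invalid_coral_geometry_repaired(self, small_scene_features):
        dem, bpi, features, _ = small_scene_features
        feat = features[0]
        rec = _describe(dem, bpi, [feat], compute_initial_slope=False)[0]
        cx, cy = feat.ring.centroid.x, feat.ring.centroid.y
        bowtie = Polygon([(cx - 5, cy - 5), (cx + 5, cy + 5), (cx + 5, cy - 5), (cx - 5, cy + 5)])
        assert not bowtie.is_valid
        rec = cover_class([rec], [feat], [bowtie])[0]
        assert rec.cover_pct > 0
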