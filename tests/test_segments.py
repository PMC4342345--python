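"""Segment classification rules and rectangle/composition geometry."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import permeascape as ps
from permeascape.segments import (
    build_segments,
    composition,
    find_b_segments,
    find_w_segments,
    mean_membership,
    segment_pixels,
    segment_table,
    within_median,
)
from permeascape.types import (
    CLASS_CODES,
    LANDCOVER_CLASSES,
    LandCoverRaster,
    MembershipSurface,
    PopulationPartition,
    SampleSite,
    Segment,
)


def _uniform_raster(n=40, code=1, res=30.0, origin=(0.0, None)):
    classes = np.full((n, n), code, dtype=np.int16)
    oy = origin[1] if origin[1] is not None else n * res
    return LandCoverRaster(origin_x=origin[0], origin_y=oy, resolution=res,
                           classes=classes)


def _seg(ax, ay, bx, by, category="W", pops=(1, 1)):
    return Segment(site_a=SampleSite(id="p", x=ax, y=ay),
                   site_b=SampleSite(id="q", x=bx, y=by),
                   category=category, pop_a=pops[0], pop_b=pops[1])


class TestWithinMedian:
    def test_collinear_population(self):
        sites = [SampleSite(id=f"s{i}", x=0.0, y=1000.0 * i) for i in range(3)]
        part = PopulationPartition(k=1, site_to_pop={s.id: 1 for s in sites})
        assert within_median(part, sites) == 1000.0

    def test_two_populations_global_scope(self):
        sites = [SampleSite(id=f"a{i}", x=0.0, y=1000.0 * i) for i in range(3)]
        sites += [SampleSite(id=f"b{i}", x=9000.0, y=1000.0 * i) for i in range(3)]
        pops = {s.id: (1 if s.id.startswith("a") else 2) for s in sites}
        part = PopulationPartition(k=2, site_to_pop=pops)
        # brute force: each population contributes {1000, 1000, 2000}
        assert within_median(part, sites, scope="global") == 1000.0

    def test_single_site_population_contributes_nothing(self, fig2_sites):
        sites, part = fig2_sites
        # population 3 has one site; median over pops 1-2 only
        assert within_median(part, sites) == 1000.0

    def test_undefined_when_no_multisite_population(self):
        sites = [SampleSite(id="s1", x=0, y=0), SampleSite(id="s2", x=10, y=0)]
        part = PopulationPartition(k=2, site_to_pop={"s1": 1, "s2": 2})
        with pytest.raises(ValueError):
            within_median(part, sites)


class TestBSegments:
    def test_fig2_geometry_single_b_segment(self, fig2_sites):
        sites, part = fig2_sites
        segs = find_b_segments(part, sites, threshold=1000.0)
        assert len(segs) == 1
        (seg,) = segs
        assert {seg.site_a.id, seg.site_b.id} == {"a1", "b1"}
        assert seg.length == pytest.approx(600.0)

    def test_empty_when_all_pairs_beyond_threshold(self, fig2_sites):
        sites, part = fig2_sites
        assert find_b_segments(part, sites, threshold=100.0) == []

    def test_tie_broken_lexicographically(self):
        # two site pairs at identical minimum distance
        sites = [SampleSite(id="a1", x=0, y=0), SampleSite(id="a2", x=0, y=500),
                 SampleSite(id="b1", x=400, y=0), SampleSite(id="b2", x=400, y=500)]
        part = PopulationPartition(k=2, site_to_pop={"a1": 1, "a2": 1, "b1": 2, "b2": 2})
        segs = find_b_segments(part, sites, threshold=450.0)
        assert len(segs) == 1
        assert (segs[0].site_a.id, segs[0].site_b.id) == ("a1", "b1")


class TestWSegments:
    def test_fig2_w_segments(self, fig2_sites):
        sites, part = fig2_sites
        b = find_b_segments(part, sites, threshold=1000.0)
        w = find_w_segments(part, sites, b)
        assert len(w) == 2
        by_pop = {seg.pop_a: seg for seg in w}
        # population 1: |1000-600| ties between (a1,a2) and (a2,a3); lexicographic
        assert {by_pop[1].site_a.id, by_pop[1].site_b.id} == {"a1", "a2"}
        # population 2 has exactly two sites: that pair regardless of match
        assert {by_pop[2].site_a.id, by_pop[2].site_b.id} == {"b1", "b2"}

    def test_isolated_population_uses_fallback_length(self):
        sites = [SampleSite(id="s1", x=0, y=0), SampleSite(id="s2", x=0, y=700),
                 SampleSite(id="s3", x=0, y=2500)]
        part = PopulationPartition(k=1, site_to_pop={s.id: 1 for s in sites})
        w = find_w_segments(part, sites, [], fallback_length=776.0)
        assert len(w) == 1
        assert {w[0].site_a.id, w[0].site_b.id} == {"s1", "s2"}  # 700 nearest 776

    def test_full_fixture_one_b_two_w(self, fig2_sites):
        sites, part = fig2_sites
        segs = build_segments(part, sites)
        cats = sorted(s.category for s in segs)
        assert cats == ["B", "W", "W"]


class TestSegmentPixels:
    def test_axis_aligned_count(self):
        # length 300 m, width 60 m, 30 m pixels, endpoints at pixel
        # centers: 11 columns x 2 rows (half-open across the axis)
        raster = _uniform_raster(n=20, res=30.0)
        seg = _seg(15.0, 285.0, 315.0, 285.0)
        pix = segment_pixels(seg, width=60.0, raster=raster)
        assert len(pix) == 22

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        raster = _uniform_raster(n=30, res=30.0)
        for _ in range(10):
            ax, ay, bx, by = rng.uniform(100, 800, 4)
            width = rng.uniform(5, 400)
            seg = _seg(ax, ay, bx, by)
            pix = {tuple(p) for p in segment_pixels(seg, width, raster)}
            # independent brute force over every pixel center
            L = seg.length
            ux, uy = (bx - ax) / L, (by - ay) / L
            nx, ny = -uy, ux
            expected = set()
            for r in range(raster.n_rows):
                for c in range(raster.n_cols):
                    px = raster.origin_x + (c + 0.5) * 30.0
                    py = raster.origin_y - (r + 0.5) * 30.0
                    t = (px - ax) * ux + (py - ay) * uy
                    s = (px - ax) * nx + (py - ay) * ny
                    if -1e-6 <= t <= L + 1e-6 and -width / 2 + 1e-6 < s <= width / 2 + 1e-6:
                        expected.add((r, c))
            if not expected:
                expected = {raster.index_of(ax, ay), raster.index_of(bx, by)}
            assert pix == expected

    def test_thin_width_never_empty(self):
        raster = _uniform_raster(n=20, res=30.0)
        seg = _seg(100.0, 100.0, 140.0, 130.0)
        pix = segment_pixels(seg, width=3.0, raster=raster)
        assert len(pix) >= 1

    def test_rotation_invariant_pixel_count(self):
        raster = _uniform_raster(n=40, res=30.0)
        cx = cy = 40 * 30 / 2
        seg = _seg(cx - 200, cy - 110, cx + 160, cy + 70)
        n0 = len(segment_pixels(seg, 75.0, raster))
        # rotate the scene by 90 degrees about the raster center
        rot = _seg(cx - (cy - 110 - cy), cy + (cx - 200 - cx),
                   cx - (cy + 70 - cy), cy + (cx + 160 - cx))
        n90 = len(segment_pixels(rot, 75.0, raster))
        assert n0 == n90

    @given(st.integers(0, 6))
    def test_pixel_count_nondecreasing_in_width(self, i):
        raster = _uniform_raster(n=25, res=30.0)
        seg = _seg(80.0, 90.0, 430.0, 600.0)
        widths = [3, 10, 25, 50, 100, 200, 400, 1000]
        a = len(segment_pixels(seg, widths[i], raster))
        b = len(segment_pixels(seg, widths[i + 1], raster))
        assert b >= a


class TestComposition:
    def test_uniform_forest(self):
        raster = _uniform_raster(n=20, code=CLASS_CODES["forest"])
        comp = composition(_seg(50, 50, 500, 400), 100.0, raster)
        assert comp[LANDCOVER_CLASSES.index("forest")] == 1.0
        assert comp.sum() == pytest.approx(1.0)

    def test_half_forest_half_agriculture(self):
        classes = np.full((40, 40), CLASS_CODES["forest"], dtype=np.int16)
        classes[:, 20:] = CLASS_CODES["agriculture"]
        raster = LandCoverRaster(origin_x=0, origin_y=1200, resolution=30,
                                 classes=classes)
        # segment centered on the boundary (x = 600), axis along it
        seg = _seg(600.0, 200.0, 600.0, 1000.0)
        comp = composition(seg, 300.0, raster)
        f = comp[LANDCOVER_CLASSES.index("forest")]
        a = comp[LANDCOVER_CLASSES.index("agriculture")]
        pix = len(segment_pixels(seg, 300.0, raster))
        assert abs(f - 0.5) <= 1.0 / np.sqrt(pix)  # one-pixel-row discretisation
        assert f + a == pytest.approx(1.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(8)
        classes = rng.integers(1, 10, size=(30, 30)).astype(np.int16)
        r0 = LandCoverRaster(origin_x=0, origin_y=900, resolution=30, classes=classes)
        r1 = LandCoverRaster(origin_x=12345, origin_y=900 + 777, resolution=30,
                             classes=classes)
        seg0 = _seg(100, 150, 700, 600)
        seg1 = _seg(100 + 12345, 150 + 777, 700 + 12345, 600 + 777)
        for w in (10.0, 100.0, 400.0):
            assert np.array_equal(composition(seg0, w, r0), composition(seg1, w, r1))


class TestMeanMembership:
    def _surface(self, value=0.8, k=2):
        probs = np.zeros((100, 100, k))
        probs[:, :, 0] = value
        probs[:, :, 1] = 1 - value
        return MembershipSurface(probs=probs, xmin=0, ymin=0, xmax=1200, ymax=1200)

    def test_constant_grid(self):
        raster = _uniform_raster(n=40, res=30.0)
        surf = self._surface(0.8)
        modal = ps.modal_surface(surf)
        seg = _seg(100, 100, 900, 700)
        for w in (3.0, 100.0, 1000.0):
            assert mean_membership(seg, w, modal, surf, raster) == pytest.approx(0.8)

    def test_matches_enumeration(self):
        rng = np.random.default_rng(9)
        raster = _uniform_raster(n=40, res=30.0)
        probs = rng.dirichlet(np.ones(2), size=(100, 100))
        surf = MembershipSurface(probs=probs, xmin=0, ymin=0, xmax=1200, ymax=1200)
        modal = ps.modal_surface(surf)
        seg = _seg(100, 150, 800, 900)
        pix = segment_pixels(seg, 200.0, raster)
        x, y = raster.pixel_center(pix[:, 0], pix[:, 1])
        row, col = surf.index_of(x, y)
        expected = float(np.mean([modal[r, c] for r, c in zip(row, col)]))
        assert mean_membership(seg, 200.0, modal, surf, raster) == pytest.approx(expected)


class TestSegmentTable:
    def test_endpoint_cluster_consistency(self, small_scenario):
        scen = small_scenario
        segs = build_segments(scen.partition, scen.sites)
        for seg in segs:
            pa = scen.partition.site_to_pop[seg.site_a.id]
            pb = scen.partition.site_to_pop[seg.site_b.id]
            assert (seg.category == "B") == (pa != pb)

    def test_tidy_table_shape_and_sums(self, small_scenario):
        scen = small_scenario
        segs = build_segments(scen.partition, scen.sites)
        modal = ps.modal_surface(scen.surface)
        table = segment_table(segs, scen.raster, modal_grid=modal,
                              surf=scen.surface, widths=(3.0, 100.0))
        assert len(table) == 2 * len(segs)
        comp = table[list(LANDCOVER_CLASSES)].to_numpy()
        assert np.allclose(comp.sum(axis=1), 1.0, atol=1e-9)
        assert table["membership"].between(0, 1).all()
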