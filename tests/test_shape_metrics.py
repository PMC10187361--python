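import numpy as np
import pytest

from ccshape.imaging_io import CCMask
from ccshape.phantom import AnnulusSectorSpec, make_annulus_sector, make_cc_phantom
from ccshape.shape_metrics import (
    EmptyMaskError,
    MedialCurve,
    TopologyError,
    clean_mask,
    compute_all_metrics,
    compute_area,
    compute_perimeter,
    curvature_profile,
    extract_medial_curve,
    subdivide_regions,
    thickness_profile,
)


def brute_force_area_and_edges(lab):
    """Exhaustive pixel counting and boundary-edge counting oracle."""
    n = 0
    edges = 0
    rows, cols = lab.shape
    for r in range(rows):
        for c in range(cols):
            if not lab[r, c]:
                continue
            n += 1
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < rows and 0 <= cc < cols) or not lab[rr, cc]:
                    edges += 1
    return n, edges


class TestCleanMask:
    def test_hole_filled(self):
        lab = np.ones((7, 7), dtype=np.uint8)
        lab[3, 3] = 0
        out = clean_mask(CCMask(lab))
        assert out.count() == 49

    def test_largest_component_kept(self):
        lab = np.zeros((20, 20), dtype=np.uint8)
        lab[1:11, 1:11] = 1      # 100 px
        lab[15:16, 15:20] = 1    # 5 px
        out = clean_mask(CCMask(lab))
        assert out.count() == 100

    def test_empty_rejected(self):
        with pytest.raises(EmptyMaskError):
            clean_mask(CCMask(np.zeros((4, 4), dtype=np.uint8)))


class TestAreaAndPerimeter:
    def test_rectangle_area_scales_with_spacing(self):
        lab = np.zeros((20, 20), dtype=np.uint8)
        lab[5:9, 5:15] = 1
        assert compute_area(CCMask(lab, (1.0, 1.0))) == 40.0
        assert compute_area(CCMask(lab, (0.5, 0.5))) == 10.0

    def test_sector_area_closed_form(self, quarter_sector):
        _, mask, truth = quarter_sector
        assert compute_area(mask) == pytest.approx(truth.area, rel=0.02)

    def test_disk_perimeter(self):
        yy, xx = np.mgrid[0:200, 0:200]
        r2 = ((yy + 0.5 - 100) * 0.5) ** 2 + ((xx + 0.5 - 100) * 0.5) ** 2
        disk = CCMask((r2 <= 400).astype(np.uint8), (0.5, 0.5))
        assert compute_perimeter(disk) == pytest.approx(2 * np.pi * 20, rel=0.02)

    def test_sector_perimeter_closed_form(self, quarter_sector):
        _, mask, truth = quarter_sector
        assert compute_perimeter(mask) == pytest.approx(truth.perimeter, rel=0.03)

    def test_rectangle_perimeter_rounds_corners(self):
        # sub-pixel contour on the smoothed field keeps straight edges
        # exact but rounds the four corners by roughly a pixel
        lab = np.zeros((20, 20), dtype=np.uint8)
        lab[5:9, 5:15] = 1
        p = compute_perimeter(CCMask(lab))
        assert p == pytest.approx(2 * (10 + 4), rel=0.10)
        assert p < 2 * (10 + 4)

    def test_brute_force_bounds_on_small_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            lab = np.zeros((32, 32), dtype=np.uint8)
            r, c = rng.integers(6, 20, 2)
            lab[r:r + rng.integers(4, 10), c:c + rng.integers(4, 10)] = 1
            mask = CCMask(lab)
            n, edges = brute_force_area_and_edges(lab)
            assert compute_area(mask) == float(n)
            # the sub-pixel contour is never longer than the pixel-edge
            # boundary and never shorter than it by more than sqrt(2)
            p = compute_perimeter(mask)
            assert p <= edges + 1e-9
            assert p >= edges / np.sqrt(2) - 1e-9


class TestMedialCurve:
    def test_rectangle_runs_tip_to_tip(self, rect_mask):
        curve = extract_medial_curve(rect_mask)
        assert curve.length == pytest.approx(40.0, abs=2.5)
        # anterior-first: first point has the larger column coordinate
        assert curve.points[0, 1] > curve.points[-1, 1]
        assert curve.euclidean_distance / curve.length > 0.98

    def test_sector_arc_length(self, quarter_sector):
        _, mask, truth = quarter_sector
        curve = extract_medial_curve(mask)
        assert curve.length == pytest.approx(truth.medial_length, rel=0.03)
        assert curve.euclidean_distance == pytest.approx(
            truth.euclidean_distance, rel=0.03)

    def test_annular_mask_rejected(self):
        yy, xx = np.mgrid[0:128, 0:128]
        r = np.hypot(yy - 64, xx - 64)
        ring = CCMask(((r > 20) & (r < 30)).astype(np.uint8))
        with pytest.raises(TopologyError):
            extract_medial_curve(ring)

    def test_empty_rejected(self):
        with pytest.raises(EmptyMaskError):
            extract_medial_curve(CCMask(np.zeros((8, 8), dtype=np.uint8)))


class TestThickness:
    def test_rectangle_interior_thickness(self, rect_mask):
        curve = extract_medial_curve(rect_mask)
        prof = thickness_profile(rect_mask, curve)
        interior = prof.samples[prof.interior]
        assert np.median(interior) == pytest.approx(4.0, abs=0.4)

    def test_sector_thickness(self, quarter_sector):
        _, mask, truth = quarter_sector
        curve = extract_medial_curve(mask)
        prof = thickness_profile(mask, curve)
        assert prof.samples[prof.interior].mean() == pytest.approx(
            truth.thickness, rel=0.05)

    def test_hypoplasia_to_normal_ratio(self):
        def interior_mean(mask):
            curve = extract_medial_curve(mask)
            prof = thickness_profile(mask, curve)
            return prof.samples[prof.interior].mean()

        ratios = [interior_mean(make_cc_phantom(s, "hypoplasia").mask)
                  / interior_mean(make_cc_phantom(s, "normal").mask)
                  for s in (1, 2, 3, 4)]
        assert np.mean(ratios) == pytest.approx(0.5, abs=0.1)


class TestCurvature:
    def test_straight_line_is_flat(self):
        s = np.arange(0, 30.0)
        pts = np.column_stack([np.full_like(s, 5.0), 40 - s])
        curve = MedialCurve(pts, s)
        np.testing.assert_allclose(curvature_profile(curve).samples, 0, atol=1e-6)

    def test_circular_arc_magnitude(self):
        s = np.arange(0, 39.0)
        pts = np.column_stack([64 - 25 * np.cos(s / 25), 64 + 25 * np.sin(s / 25)])
        arcl = np.concatenate([[0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        k = curvature_profile(MedialCurve(pts, arcl)).samples
        np.testing.assert_allclose(np.abs(k[3:-3]), 0.04, atol=0.002)

    def test_scaling_halves_curvature(self):
        s = np.arange(0, 39.0)
        pts = np.column_stack([64 - 25 * np.cos(s / 25), 64 + 25 * np.sin(s / 25)])
        arcl = np.concatenate([[0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        k1 = np.abs(curvature_profile(MedialCurve(pts, arcl)).samples[5:-5]).mean()
        k2 = np.abs(curvature_profile(
            MedialCurve(pts * 2, arcl * 2)).samples[5:-5]).mean()
        assert k2 == pytest.approx(k1 / 2, rel=0.05)


class TestAllMetrics:
    def test_sector_suite(self, quarter_sector):
        spec, mask, truth = quarter_sector
        m = compute_all_metrics(mask)
        assert m.total_curve == pytest.approx(spec.angle, rel=0.05)
        assert m.total_euclidean_dist == pytest.approx(
            truth.euclidean_distance, rel=0.03)
        assert m.total_mean_curve == pytest.approx(truth.curvature, rel=0.05)

    def test_invariants_on_phantoms(self):
        for seed in (0, 3):
            for cls in ("normal", "dysplasia"):
                m = compute_all_metrics(make_cc_phantom(seed, cls).mask,
                                        curvature_mode="circle")
                assert m.total_euclidean_dist <= m.total_medial_curve_length
                assert m.total_min_thickness <= m.total_mean_thick <= m.total_max_thickness
                assert m.total_perimeter >= 2 * m.total_euclidean_dist

    def test_rotation_invariance_quarter_turn(self, quarter_sector):
        _, mask, _ = quarter_sector
        rot = CCMask(np.rot90(mask.labels).copy(), mask.pixel_spacing)
        a = compute_all_metrics(mask, curvature_mode="circle")
        b = compute_all_metrics(rot, curvature_mode="circle")
        for key in ("Total Area", "Total Perimeter", "Total MedialCurveLength",
                    "Total MeanThick", "Total EuclideanDist"):
            assert a.to_dict()[key] == pytest.approx(b.to_dict()[key], rel=0.01)

    def test_scaling_covariance(self):
        spec_a = AnnulusSectorSpec(20, 30, np.pi / 2, (64, 64), 0.5)
        mask_a, _ = make_annulus_sector(spec_a, (256, 256))
        mask_b = CCMask(mask_a.labels, pixel_spacing=(1.0, 1.0))  # 2x spacing
        a = compute_all_metrics(mask_a, curvature_mode="circle").to_dict()
        b = compute_all_metrics(mask_b, curvature_mode="circle").to_dict()
        assert b["Total Area"] == pytest.approx(4 * a["Total Area"], rel=1e-6)
        assert b["Total Perimeter"] == pytest.approx(2 * a["Total Perimeter"], rel=0.01)
        assert b["Total MedialCurveLength"] == pytest.approx(
            2 * a["Total MedialCurveLength"], rel=0.02)
        # curvature windows have a fixed physical size, so the flatter
        # upscaled arc is estimated with relatively less lever arm
        assert b["Total MeanCurve"] == pytest.approx(
            a["Total MeanCurve"] / 2, rel=0.12)


class TestRegions:
    def test_uniform_sector_region_area_ratio(self, quarter_sector):
        _, mask, _ = quarter_sector
        curve = extract_medial_curve(mask)
        regions = subdivide_regions(mask, curve)
        areas = np.array([regions.regional[f"{n} Area"]
                          for n in ("Genu", "Body", "Splenium")])
        total = areas.sum()
        np.testing.assert_allclose(areas / total, [0.25, 0.5, 0.25], atol=0.05)

    def test_region_areas_partition_total(self, quarter_sector):
        _, mask, _ = quarter_sector
        curve = extract_medial_curve(mask)
        regions = subdivide_regions(mask, curve)
        total = sum(regions.regional[f"{n} Area"]
                    for n in ("Genu", "Body", "Splenium"))
        assert total == pytest.approx(compute_area(mask), abs=1e-9)

    def test_splenium_bulb_has_larger_max_thickness(self):
        # posterior (splenium) end of the normal phantom is built thicker
        m = compute_all_metrics(make_cc_phantom(2, "normal").mask,
                                curvature_mode="circle")
        assert m.regional["Splenium MaxThick"] > m.regional["Body MaxThick"]
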