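import numpy as np
import pytest
from scipy import ndimage

from ccshape.imaging_io import ValidationError
from ccshape.phantom import (
    AnnulusSectorSpec,
    GeometryError,
    corrupt_mask,
    make_annulus_sector,
    make_cc_phantom,
    make_dataset,
)
from ccshape.shape_metrics import thickness_profile, extract_medial_curve


class TestAnnulusSector:
    def test_closed_form_truth(self, quarter_sector):
        _, _, truth = quarter_sector
        assert truth.area == pytest.approx((np.pi / 4) * (900 - 400))
        assert truth.curvature == pytest.approx(0.04)
        assert truth.thickness == pytest.approx(10.0)
        assert truth.euclidean_distance == pytest.approx(50 * np.sin(np.pi / 4))

    def test_pixel_count_area_matches_closed_form(self, quarter_sector):
        _, mask, truth = quarter_sector
        assert mask.count() * 0.25 == pytest.approx(truth.area, rel=0.02)

    @pytest.mark.parametrize("spacing, rel", [(0.5, 0.02), (0.125, 0.005)])
    def test_area_converges_with_resolution(self, spacing, rel):
        grid = int(128 / spacing)
        spec = AnnulusSectorSpec(20, 30, np.pi / 2, (64, 64), spacing)
        mask, truth = make_annulus_sector(spec, (grid, grid))
        assert mask.count() * spacing**2 == pytest.approx(truth.area, rel=rel)

    def test_degenerate_arc_raises(self):
        spec = AnnulusSectorSpec(20, 30, 1e-4, (64, 64), 0.5)
        with pytest.raises(GeometryError):
            make_annulus_sector(spec, (256, 256))

    def test_sector_exceeding_grid_raises(self):
        spec = AnnulusSectorSpec(20, 70, np.pi / 2, (64, 64), 0.5)
        with pytest.raises(GeometryError):
            make_annulus_sector(spec, (256, 256))


class TestCCPhantom:
    def test_determinism(self):
        a = make_cc_phantom(7, "dysplasia")
        b = make_cc_phantom(7, "dysplasia")
        np.testing.assert_array_equal(a.mask.labels, b.mask.labels)
        np.testing.assert_array_equal(a.image.intensities, b.image.intensities)

    def test_shape_and_contrast_polarity(self):
        for contrast, brighter in [("T1w", True), ("T2w", False), ("FLAIR", True)]:
            s = make_cc_phantom(3, "normal", contrast=contrast)
            assert s.image.shape == (256, 256)
            fg = s.image.intensities[s.mask.labels == 1].mean()
            bg = s.image.intensities[s.mask.labels == 0].mean()
            assert (fg > bg) == brighter

    def test_hypoplasia_thins_by_half(self):
        # distance-transform thickness oracle on both masks
        ratios = []
        for seed in (1, 2, 3):
            nrm = make_cc_phantom(seed, "normal")
            hyp = make_cc_phantom(seed, "hypoplasia")

            def mean_thick(mask):
                curve = extract_medial_curve(mask)
                prof = thickness_profile(mask, curve)
                return prof.samples[prof.interior].mean()

            ratios.append(mean_thick(hyp.mask) / mean_thick(nrm.mask))
        assert 0.35 < np.mean(ratios) < 0.65

    def test_agenesis_removes_area(self):
        for seed in (1, 5, 9):
            nrm = make_cc_phantom(seed, "normal")
            age = make_cc_phantom(seed, "agenesis")
            assert age.mask.count() < nrm.mask.count()

    def test_truth_only_for_unwarped_classes(self):
        assert make_cc_phantom(0, "normal").truth is not None
        assert make_cc_phantom(0, "hypoplasia").truth is not None
        assert make_cc_phantom(0, "dysplasia").truth is None
        assert make_cc_phantom(0, "hypoplasia_dysplasia").truth is None

    def test_single_connected_component(self):
        for seed in range(5):
            for cls in ("normal", "hypoplasia", "dysplasia"):
                s = make_cc_phantom(seed, cls)
                _, n = ndimage.label(s.mask.labels, structure=np.ones((3, 3)))
                assert n == 1, f"{cls} seed {seed}: {n} components"

    def test_unknown_class_rejected(self):
        with pytest.raises(ValidationError):
            make_cc_phantom(0, "weird")
        with pytest.raises(ValidationError):
            make_cc_phantom(0, "normal", contrast="CT")


class TestDataset:
    def test_exact_counts_by_largest_remainder(self):
        samples = make_dataset(100, {"normal": 0.8, "hypoplasia": 0.2}, seed=7)
        labels = [s.label for s in samples]
        assert labels.count("normal") == 80
        assert labels.count("hypoplasia") == 20

    def test_determinism(self):
        a = make_dataset(10, {"normal": 0.5, "agenesis": 0.5}, seed=3)
        b = make_dataset(10, {"normal": 0.5, "agenesis": 0.5}, seed=3)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.mask.labels, sb.mask.labels)

    def test_bad_mix_rejected(self):
        with pytest.raises(ValidationError):
            make_dataset(10, {"normal": 0.5, "hypoplasia": 0.4}, seed=0)


class TestCorruptMask:
    @pytest.mark.parametrize("mode", ["box_delete", "dilate", "speckle"])
    def test_corruption_changes_mask(self, normal_phantom, mode):
        rng = np.random.default_rng(0)
        bad = corrupt_mask(normal_phantom.mask, mode, rng)
        assert bad.shape == normal_phantom.mask.shape
        assert not np.array_equal(bad.labels, normal_phantom.mask.labels)

    def test_unknown_mode_rejected(self, normal_phantom):
        with pytest.raises(ValidationError):
            corrupt_mask(normal_phantom.mask, "blur", np.random.default_rng(0))
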