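import numpy as np
import pytest

from ccshape.augmentation import (
    AugmentationConfig,
    add_random_boxes,
    alter_contrast,
    build_training_set,
    downsample_upsample,
    rotate_sweep,
)
from ccshape.imaging_io import CCMask, MidsagittalImage, ValidationError
from ccshape.segmentation import mean_iou


def _img(arr):
    return MidsagittalImage(np.asarray(arr, dtype=float))


class TestDownsampleUpsample:
    def test_constant_image_unchanged(self):
        img = _img(np.full((64, 64), 3.5))
        out = downsample_upsample(img, 4)
        np.testing.assert_allclose(out.intensities, 3.5, atol=1e-6)

    def test_reduces_high_frequency_variance(self):
        stripes = np.tile([0.0, 1.0], (64, 32))  # one-pixel period along columns
        out = downsample_upsample(_img(stripes), 2, axis=1)
        assert out.intensities.var() < stripes.var()
        assert out.shape == (64, 64)

    def test_factor_exceeding_axis_rejected(self):
        with pytest.raises(ValidationError):
            downsample_upsample(_img(np.zeros((64, 64))), 300)


class TestAlterContrast:
    def test_matching_to_own_histogram_is_identity(self):
        rng = np.random.default_rng(0)
        arr = rng.random((64, 64))
        out = alter_contrast(_img(arr), _img(arr))
        np.testing.assert_allclose(out.intensities, arr, atol=1e-6)

    def test_cdf_matches_reference(self):
        rng = np.random.default_rng(1)
        src = rng.normal(0.3, 0.05, (96, 96))
        ref = rng.normal(0.7, 0.15, (96, 96))
        out = alter_contrast(_img(src), _img(ref)).intensities
        qs = np.linspace(0.05, 0.95, 19)
        np.testing.assert_allclose(np.quantile(out, qs), np.quantile(ref, qs), atol=0.02)

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(2)
        src = rng.random((32, 32))
        ref = rng.normal(0, 2, (32, 32))
        out = alter_contrast(_img(src), _img(ref)).intensities
        assert np.all(np.argsort(src.ravel()) == np.argsort(out.ravel(), kind="stable"))

    def test_constant_image_maps_to_reference_median(self):
        ref = np.arange(100, dtype=float).reshape(10, 10)
        out = alter_contrast(_img(np.full((8, 8), 5.0)), _img(ref))
        np.testing.assert_allclose(out.intensities, np.median(ref))

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        src = _img(rng.random((64, 64)))
        ref = _img(rng.normal(0.5, 0.2, (64, 64)))
        once = alter_contrast(src, ref)
        twice = alter_contrast(once, ref)
        np.testing.assert_allclose(twice.intensities, once.intensities, atol=1e-6)


class TestRotateSweep:
    def _pair(self):
        rng = np.random.default_rng(0)
        img = rng.random((64, 64))
        lab = np.zeros((64, 64), dtype=np.uint8)
        lab[20:44, 24:40] = 1
        return _img(img), CCMask(lab)

    def test_count_at_15_degrees(self):
        img, msk = self._pair()
        assert len(rotate_sweep(img, msk, 15)) == 24

    def test_square_symmetric_mask_pixel_counts(self):
        lab = np.zeros((65, 65), dtype=np.uint8)
        lab[22:43, 22:43] = 1  # square centered on the grid center
        img = _img(np.ones((65, 65)))
        counts = {pair[1].count() for pair in rotate_sweep(img, CCMask(lab), 90)}
        assert len(counts) == 1

    def test_full_turn_recovers_mask(self):
        img, msk = self._pair()
        cur_i, cur_m = img, msk
        for _ in range(4):
            cur_i, cur_m = rotate_sweep(cur_i, cur_m, 90)[1]
        dice = 2 * mean_iou(cur_m, msk) / (1 + mean_iou(cur_m, msk))
        assert dice >= 0.99

    def test_pixel_count_preserved_within_tolerance(self):
        img, msk = self._pair()
        for _, m in rotate_sweep(img, msk, 45):
            assert abs(m.count() - msk.count()) / msk.count() < 0.05

    def test_non_divisor_step_rejected(self):
        img, msk = self._pair()
        with pytest.raises(ValidationError):
            rotate_sweep(img, msk, 17)


class TestRandomBoxes:
    def test_single_box_pixel_count(self):
        cfg = AugmentationConfig(n_boxes_range=(1, 1), box_size_range=(10, 10))
        img = _img(np.ones((64, 64)) + np.arange(64)[None, :] * 0.01)
        out = add_random_boxes(img, cfg, np.random.default_rng(0))
        changed = np.sum(out.intensities != img.intensities)
        assert changed == 100

    def test_zero_boxes_is_identity(self):
        cfg = AugmentationConfig(n_boxes_range=(0, 0))
        img = _img(np.random.default_rng(1).random((64, 64)))
        out = add_random_boxes(img, cfg, np.random.default_rng(2))
        np.testing.assert_array_equal(out.intensities, img.intensities)

    def test_determinism(self):
        cfg = AugmentationConfig()
        img = _img(np.random.default_rng(1).random((128, 128)))
        a = add_random_boxes(img, cfg, np.random.default_rng(9))
        b = add_random_boxes(img, cfg, np.random.default_rng(9))
        np.testing.assert_array_equal(a.intensities, b.intensities)


class TestBuildTrainingSet:
    def _inputs(self):
        rng = np.random.default_rng(0)
        img = _img(rng.random((96, 96)))
        lab = np.zeros((96, 96), dtype=np.uint8)
        lab[30:60, 40:70] = 1
        return [img], [CCMask(lab)]

    def test_product_count(self):
        imgs, msks = self._inputs()
        cfg = AugmentationConfig(downsample_factors=(2, 3, 4, 5), rotation_step=15,
                                 box_variants=1, target_shape=(64, 64))
        pairs = build_training_set(imgs, msks, cfg)
        assert len(pairs) == 5 * 24 * 2

    def test_outputs_resized_and_binary(self):
        imgs, msks = self._inputs()
        cfg = AugmentationConfig(downsample_factors=(2,), rotation_step=90,
                                 box_variants=0, target_shape=(64, 64))
        pairs = build_training_set(imgs, msks, cfg)
        assert len(pairs) == 2 * 4
        for img, msk in pairs:
            assert img.shape == (64, 64) and msk.shape == (64, 64)
            assert set(np.unique(msk.labels)) <= {0, 1}
            assert np.all(np.isfinite(img.intensities))

    def test_deterministic_given_seed(self):
        imgs, msks = self._inputs()
        cfg = AugmentationConfig(downsample_factors=(2,), rotation_step=90,
                                 box_variants=1, target_shape=(64, 64), rng_seed=5)
        a = build_training_set(imgs, msks, cfg)
        b = build_training_set(imgs, msks, cfg)
        for (ia, ma), (ib, mb) in zip(a, b):
            np.testing.assert_array_equal(ia.intensities, ib.intensities)
            np.testing.assert_array_equal(ma.labels, mb.labels)

    def test_mismatched_pairs_rejected(self):
        imgs, msks = self._inputs()
        with pytest.raises(ValidationError):
            build_training_set(imgs, msks + msks)
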