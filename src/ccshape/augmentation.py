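"""Training-set degradations for the midCC segmenter.

Emulates the artefacts of clinical acquisitions: through-plane
resolution loss (downsample then upsample along the anterior-posterior
axis by integer factors), contrast alteration (histogram matching to a
reference image), a clockwise rotation sweep in fixed increments with
the mask rotated jointly, random black occluding boxes (mimicking
partial agenesis and field-of-view cuts), and a final resize to the
network grid.

Interpolation is linear for images and threshold-0.5 for masks so masks
stay strictly binary.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
from scipy import ndimage
from skimage.exposure import match_histograms
from skimage.transform import resize

from ccshape.imaging_io import CCMask, MidsagittalImage, ValidationError

__all__ = [
    "AugmentationConfig",
    "downsample_upsample",
    "alter_contrast",
    "rotate_sweep",
    "add_random_boxes",
    "build_training_set",
]


@dataclasses.dataclass
class AugmentationConfig:
    downsample_factors: tuple[int, ...] = (2, 3, 4, 5)
    rotation_step: float = 15.0
    n_boxes_range: tuple[int, int] = (1, 4)
    box_size_range: tuple[int, int] = (10, 40)
    box_variants: int = 1
    target_shape: tuple[int, int] = (256, 256)
    rng_seed: int = 0

    def __post_init__(self):
        if any(f < 2 for f in self.downsample_factors):
            raise ValidationError("downsample factors must be >= 2")
        if not 0 < self.rotation_step <= 90:
            raise ValidationError("rotation step must be in (0, 90]")
        if self.box_size_range[0] < 1:
            raise ValidationError("box sizes must be >= 1")


def downsample_upsample(image: MidsagittalImage, factor: int, axis: int = 1) -> MidsagittalImage:
    """Lose resolution along one in-plane axis (default: the
    anterior-posterior column axis) and resample back to the input grid."""
    if factor < 2:
        raise ValidationError("factor must be >= 2")
    n = image.shape[axis]
    if factor >= n:
        raise ValidationError(f"factor {factor} >= axis length {n}")
    arr = image.intensities
    small_shape = list(arr.shape)
    small_shape[axis] = max(int(round(n / factor)), 1)
    small = resize(arr, small_shape, order=1, preserve_range=True, anti_aliasing=True)
    restored = resize(small, arr.shape, order=1, preserve_range=True)
    return MidsagittalImage(restored, pixel_spacing=image.pixel_spacing,
                            contrast=image.contrast,
                            provenance=image.provenance + f"|down{factor}")


def alter_contrast(image: MidsagittalImage,
                   reference: MidsagittalImage | np.ndarray) -> MidsagittalImage:
    """Histogram-match the image to a reference intensity distribution.

    The remapping is monotone, so the rank order of pixel intensities is
    preserved.  A constant input (degenerate histogram) maps to the
    reference median.
    """
    ref = reference.intensities if isinstance(reference, MidsagittalImage) else np.asarray(reference)
    arr = image.intensities
    if arr.max() == arr.min():
        out = np.full_like(arr, float(np.median(ref)))
    else:
        out = match_histograms(arr, ref)
    return MidsagittalImage(out, pixel_spacing=image.pixel_spacing,
                            contrast=image.contrast,
                            provenance=image.provenance + "|histmatch")


def rotate_sweep(image: MidsagittalImage, mask: CCMask,
                 step_degrees: float = 15.0) -> list[tuple[MidsagittalImage, CCMask]]:
    """Rotate image and mask jointly clockwise in fixed increments.

    Returns ``360 / step`` pairs (the 0-degree original included),
    rotated about the grid center; out-of-frame regions fill with the
    image minimum, and masks are re-binarized at 0.5.
    """
    if 360.0 % step_degrees != 0:
        raise ValidationError("step must divide 360")
    n = int(360.0 / step_degrees)
    arr = image.intensities
    fill = float(arr.min())
    out = []
    for k in range(n):
        angle = k * step_degrees
        if angle == 0:
            img_r, msk_r = arr.copy(), mask.labels.copy()
        else:
            # scipy rotates counter-clockwise for positive angles in
            # array coordinates; negate for a clockwise sweep
            img_r = ndimage.rotate(arr, -angle, reshape=False, order=1, cval=fill)
            msk_f = ndimage.rotate(mask.labels.astype(float), -angle,
                                   reshape=False, order=1, cval=0.0)
            msk_r = (msk_f >= 0.5).astype(np.uint8)
        out.append((
            MidsagittalImage(img_r, pixel_spacing=image.pixel_spacing,
                             contrast=image.contrast,
                             provenance=image.provenance + f"|rot{angle:g}"),
            CCMask(msk_r, pixel_spacing=mask.pixel_spacing),
        ))
    return out


def add_random_boxes(image: MidsagittalImage, config: AugmentationConfig,
                     rng: np.random.Generator) -> MidsagittalImage:
    """Overlay random axis-aligned rectangles set to the image minimum."""
    arr = image.intensities.copy()
    lo_n, hi_n = config.n_boxes_range
    n_boxes = int(rng.integers(lo_n, hi_n + 1))
    fill = float(arr.min())
    lo_s, hi_s = config.box_size_range
    if hi_s >= min(arr.shape):
        raise ValidationError("box sizes must fit inside the grid")
    for _ in range(n_boxes):
        h = int(rng.integers(lo_s, hi_s + 1))
        w = int(rng.integers(lo_s, hi_s + 1))
        r = int(rng.integers(0, arr.shape[0] - h + 1))
        c = int(rng.integers(0, arr.shape[1] - w + 1))
        arr[r:r + h, c:c + w] = fill
    return MidsagittalImage(arr, pixel_spacing=image.pixel_spacing,
                            contrast=image.contrast,
                            provenance=image.provenance + f"|boxes{n_boxes}")


def _resize_pair(image: MidsagittalImage, mask: CCMask,
                 shape: tuple[int, int]) -> tuple[MidsagittalImage, CCMask]:
    if image.shape == tuple(shape):
        return image, mask
    img = resize(image.intensities, shape, order=1, preserve_range=True)
    msk = resize(mask.labels.astype(float), shape, order=1, preserve_range=True) >= 0.5
    sr = image.pixel_spacing[0] * image.shape[0] / shape[0]
    sc = image.pixel_spacing[1] * image.shape[1] / shape[1]
    return (MidsagittalImage(img, pixel_spacing=(sr, sc), contrast=image.contrast,
                             provenance=image.provenance + "|resized"),
            CCMask(msk.astype(np.uint8), pixel_spacing=(sr, sc)))


def build_training_set(
    images: list[MidsagittalImage],
    masks: list[CCMask],
    config: AugmentationConfig | None = None,
) -> list[tuple[MidsagittalImage, CCMask]]:
    """Full augmentation product, resized to ``config.target_shape``.

    Product per input pair: {original + one image per downsample factor}
    x {360/step rotations} x {1 + box_variants box versions} (the clean
    version plus ``box_variants`` independently boxed ones); masks stay
    binary throughout.
    """
    config = config or AugmentationConfig()
    if len(images) != len(masks):
        raise ValidationError("images and masks must be paired")
    rng = np.random.default_rng(config.rng_seed)
    out: list[tuple[MidsagittalImage, CCMask]] = []
    for image, mask in zip(images, masks):
        resolutions = [image] + [downsample_upsample(image, f)
                                 for f in config.downsample_factors]
        for res_img, variant in itertools.product(resolutions, range(1 + config.box_variants)):
            boxed = add_random_boxes(res_img, config, rng) if variant > 0 else res_img
            for img_r, msk_r in rotate_sweep(boxed, mask, config.rotation_step):
                out.append(_resize_pair(img_r, msk_r, config.target_shape))
    return out
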