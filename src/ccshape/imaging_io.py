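"""Image, mask and feature-table containers plus file I/O.

Coordinate convention for 2D slices: row axis runs inferior -> superior
(rendered downward), column axis runs posterior -> anterior (rendered
rightward).  The phantom generator enforces this convention, so
"anterior tip" is always the tip with the larger column coordinate.
All physical lengths are millimetres; areas are mm^2.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Sequence

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume",
    "MidsagittalImage",
    "CCMask",
    "FeatureTable",
    "extract_midsagittal",
    "load_volume",
    "load_mask",
    "save_mask",
    "load_image",
    "save_image",
    "write_feature_table",
    "read_feature_table",
]

CONTRASTS = ("T1w", "T2w", "FLAIR", "synthetic")

#: axis codes naming the left-right anatomical axis
_LR_CODES = {"L", "R"}


class OrientationError(ValueError):
    """Volume orientation metadata is missing or lacks a left-right axis."""


class ShapeError(ValueError):
    """A grid has a degenerate (zero-length) axis or mismatched shape."""


class ValidationError(ValueError):
    """A container invariant is violated."""


@dataclasses.dataclass
class Volume:
    """A 3D intensity grid assumed already rigidly registered to MNI space.

    ``orientation`` gives one anatomical axis code per array axis, e.g.
    ``("R", "A", "S")`` (nibabel convention: the code names the direction
    of increasing index).
    """

    intensities: np.ndarray
    voxel_spacing: tuple[float, float, float]
    orientation: tuple[str, str, str]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ShapeError("volume must be a 3D grid")
        if min(self.intensities.shape) == 0:
            raise ShapeError("volume has a zero-length axis")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValidationError("voxel spacing must be positive")


@dataclasses.dataclass
class MidsagittalImage:
    """A single 2D midsagittal grayscale slice."""

    intensities: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    contrast: str = "synthetic"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2 or min(self.intensities.shape) == 0:
            raise ShapeError("image must be a non-empty 2D grid")
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("image intensities must be finite")
        if any(s <= 0 for s in self.pixel_spacing):
            raise ValidationError("pixel spacing must be positive")
        if self.contrast not in CONTRASTS:
            raise ValidationError(f"unknown contrast {self.contrast!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


@dataclasses.dataclass
class CCMask:
    """A binary midCC mask on the same grid as its source image."""

    labels: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2 or min(labels.shape) == 0:
            raise ShapeError("mask must be a non-empty 2D grid")
        uniq = np.unique(labels)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValidationError(f"mask values must be 0/1, got {uniq[:10]}")
        self.labels = labels.astype(np.uint8)
        if any(s <= 0 for s in self.pixel_spacing):
            raise ValidationError("pixel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def pixel_area(self) -> float:
        return float(self.pixel_spacing[0] * self.pixel_spacing[1])

    def count(self) -> int:
        return int(self.labels.sum())


class FeatureTable:
    """One row of named, finite metric values per scan, keyed by a unique id.

    Thin wrapper around a :class:`pandas.DataFrame` that enforces unique
    ids and finite metric values.
    """

    ID_COLUMN = "scan_id"

    def __init__(self, frame: pd.DataFrame):
        if self.ID_COLUMN not in frame.columns:
            raise ValidationError(f"missing id column {self.ID_COLUMN!r}")
        if frame.columns.duplicated().any():
            raise ValidationError("duplicate column names")
        if frame[self.ID_COLUMN].duplicated().any():
            raise ValidationError("duplicate scan ids")
        metric_cols = [c for c in frame.columns if c != self.ID_COLUMN]
        if len(frame) and metric_cols:
            vals = frame[metric_cols].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValidationError("non-finite metric values")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_records(cls, ids: Sequence, records: Sequence[dict]) -> "FeatureTable":
        frame = pd.DataFrame(list(records))
        frame.insert(0, cls.ID_COLUMN, list(ids))
        return cls(frame)

    @property
    def metric_names(self) -> list[str]:
        return [c for c in self.frame.columns if c != self.ID_COLUMN]

    def values(self) -> np.ndarray:
        """Metric matrix (n_scans, n_metrics) as float."""
        return self.frame[self.metric_names].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureTable) and self.frame.equals(other.frame)


def extract_midsagittal(volume: Volume, contrast: str = "T1w") -> MidsagittalImage:
    """Extract the midline sagittal slice of an MNI-registered volume.

    The left-right axis is located from the orientation codes and sliced
    at index ``floor(n / 2)`` (0-based).  In-plane pixel spacing is
    carried over from the two remaining axes.
    """
    codes = [str(c).upper() for c in volume.orientation]
    lr_axes = [i for i, c in enumerate(codes) if c in _LR_CODES]
    if len(lr_axes) != 1:
        raise OrientationError(
            f"orientation {volume.orientation} does not identify a unique left-right axis"
        )
    axis = lr_axes[0]
    n = volume.intensities.shape[axis]
    if n == 0:
        raise ShapeError("left-right axis has zero length")
    mid = n // 2
    sl = np.take(volume.intensities, mid, axis=axis)
    spacing = tuple(s for i, s in enumerate(volume.voxel_spacing) if i != axis)
    return MidsagittalImage(
        intensities=np.asarray(sl, dtype=float),
        pixel_spacing=spacing,
        contrast=contrast if contrast in CONTRASTS else "synthetic",
        provenance=f"midsagittal slice {mid}/{n} along axis {axis}",
    )


def load_volume(path: str | os.PathLike) -> Volume:
    """Read a NIfTI volume; orientation and spacing come from the affine."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ShapeError(f"expected 3D NIfTI, got {data.ndim}D")
    orientation = nib.aff2axcodes(img.affine)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(intensities=data, voxel_spacing=spacing, orientation=orientation)


def _is_nifti(path: str) -> bool:
    return path.endswith(".nii") or path.endswith(".nii.gz")


def save_mask(mask: CCMask, path: str | os.PathLike) -> None:
    """Write a binary mask as single-slice NIfTI or PNG (0/255)."""
    path = str(path)
    if _is_nifti(path):
        affine = np.diag([mask.pixel_spacing[0], mask.pixel_spacing[1], 1.0, 1.0])
        nib.save(nib.Nifti1Image(mask.labels.astype(np.uint8), affine), path)
    else:
        iio.imwrite(path, (mask.labels * 255).astype(np.uint8))


def load_mask(path: str | os.PathLike, pixel_spacing: tuple[float, float] | None = None) -> CCMask:
    """Read a binary mask from NIfTI (values 0/1) or PNG (threshold > 127)."""
    path = str(path)
    if _is_nifti(path):
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
        data = np.squeeze(data)
        if data.ndim != 2:
            raise ShapeError("mask NIfTI is not a single slice")
        if pixel_spacing is None:
            pixel_spacing = tuple(float(z) for z in img.header.get_zooms()[:2])
        labels = data  # CCMask validates binarity
    else:
        data = np.asarray(iio.imread(path))
        if data.ndim == 3:  # RGB(A) PNG: use first channel
            data = data[..., 0]
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0, 255))):
            raise ValidationError(f"PNG mask must be 0/255, got values {uniq[:10]}")
        labels = data > 127
        if pixel_spacing is None:
            pixel_spacing = (1.0, 1.0)
    return CCMask(labels=np.asarray(labels), pixel_spacing=pixel_spacing)


def save_image(image: MidsagittalImage, path: str | os.PathLike) -> None:
    """Write an intensity image as 8-bit PNG (min-max scaled)."""
    arr = image.intensities
    lo, hi = float(arr.min()), float(arr.max())
    scaled = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
    iio.imwrite(str(path), (scaled * 255).round().astype(np.uint8))


def load_image(
    path: str | os.PathLike,
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
    contrast: str = "synthetic",
) -> MidsagittalImage:
    data = np.asarray(iio.imread(str(path)), dtype=float)
    if data.ndim == 3:
        data = data[..., 0]
    return MidsagittalImage(data, pixel_spacing=pixel_spacing, contrast=contrast)


def write_feature_table(table: FeatureTable, path: str | os.PathLike) -> None:
    """Write the table as UTF-8 CSV with a header row.

    Floats are written with full repr precision so a read-back reproduces
    them to at least 10 significant digits.
    """
    table.frame.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | os.PathLike) -> FeatureTable:
    return FeatureTable(pd.read_csv(path))
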