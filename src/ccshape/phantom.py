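"""Analytic corpus-callosum phantoms with closed-form shape truth.

Two generators:

* :func:`make_annulus_sector` — an exact annulus sector whose area,
  perimeter, medial length, thickness, curvature and chord length are
  known in closed form.  It is the oracle for the shape-metric engine.
* :func:`make_cc_phantom` — a CC-like arch (an annular band with a
  smoothly varying thickness profile, thicker at the genu/splenium
  analogues, thinner in the body) rendered into a multi-contrast MRI-like
  image, plus abnormal variants: uniformly thinned (hypoplasia-like),
  sinusoidally warped (dysplasia-like), both, or with the posterior
  portion deleted (agenesis-like).

All generation is a pure function of ``(seed, parameters)``.
Coordinates follow the package convention: column = posterior->anterior,
so the anterior (genu) tip is on the right.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage

from ccshape.imaging_io import CCMask, MidsagittalImage, ValidationError

__all__ = [
    "AnnulusSectorSpec",
    "PhantomTruth",
    "PhantomSample",
    "PHANTOM_CLASSES",
    "CORRUPTION_MODES",
    "make_annulus_sector",
    "make_cc_phantom",
    "make_dataset",
    "corrupt_mask",
]

PHANTOM_CLASSES = ("normal", "hypoplasia", "dysplasia", "hypoplasia_dysplasia", "agenesis")
CORRUPTION_MODES = ("box_delete", "dilate", "speckle")
_IMAGE_SHAPE = (256, 256)

#: foreground/background intensity pairs per MRI contrast (CC bright on
#: T1w, dark on T2w, intermediate on FLAIR)
_CONTRAST_LEVELS = {"T1w": (0.85, 0.30), "T2w": (0.20, 0.60), "FLAIR": (0.65, 0.35)}


class GeometryError(ValueError):
    """Requested phantom geometry does not fit the grid or is degenerate."""


@dataclasses.dataclass(frozen=True)
class AnnulusSectorSpec:
    """Annulus sector: radii in mm, subtended angle in radians.

    The sector is symmetric about the "up" direction (decreasing row),
    so its two tips point upward-left (posterior) and upward-right
    (anterior).
    """

    r_inner: float
    r_outer: float
    angle: float
    center: tuple[float, float]  # (row, col) in mm
    pixel_spacing: float = 0.5

    def __post_init__(self):
        if not 0 < self.r_inner < self.r_outer:
            raise ValidationError("need 0 < r_inner < r_outer")
        if not 0 < self.angle <= np.pi:
            raise ValidationError("need 0 < angle <= pi")
        if self.pixel_spacing <= 0:
            raise ValidationError("pixel spacing must be positive")


@dataclasses.dataclass(frozen=True)
class PhantomTruth:
    """Closed-form shape descriptors of a phantom.

    For an annulus sector (inner radius a, outer radius b, angle t):
    area = (t/2)(b^2 - a^2); medial length = t (a+b)/2; thickness = b - a;
    curvature = 2/(a+b); chord (Euclidean tip distance) = (a+b) sin(t/2);
    perimeter = 2(b - a) + t (a + b).

    For the CC arch with varying thickness, ``thickness`` is the mean of
    the thickness profile and the integrals are evaluated by quadrature
    of the same closed-form integrands.
    """

    area: float
    medial_length: float
    thickness: float
    curvature: float
    euclidean_distance: float
    perimeter: float

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValidationError(f"{f.name} must be positive")


@dataclasses.dataclass
class PhantomSample:
    image: MidsagittalImage
    mask: CCMask
    label: str
    truth: PhantomTruth | None = None


def _pixel_grid_mm(shape: tuple[int, int], spacing: float):
    rows = (np.arange(shape[0]) + 0.5) * spacing
    cols = (np.arange(shape[1]) + 0.5) * spacing
    return np.meshgrid(rows, cols, indexing="ij")


def make_annulus_sector(
    spec: AnnulusSectorSpec, grid_shape: tuple[int, int] = (256, 256)
) -> tuple[CCMask, PhantomTruth]:
    """Rasterize an annulus sector by the pixel-center membership rule.

    A pixel belongs to the mask iff its center lies inside the sector
    (no anti-aliasing), so exhaustive pixel counting is an unambiguous
    area oracle.
    """
    s = spec.pixel_spacing
    if spec.angle * spec.r_outer < s:
        raise GeometryError("sector arc shorter than one pixel")
    extent_r = grid_shape[0] * s
    extent_c = grid_shape[1] * s
    cr, cc = spec.center
    # bounding check: sector lies within distance r_outer of the center
    if (cr - spec.r_outer < 0 or cc - spec.r_outer < 0
            or cr + spec.r_outer > extent_r or cc + spec.r_outer > extent_c):
        raise GeometryError("sector exceeds the grid")
    rr, cols = _pixel_grid_mm(grid_shape, s)
    dr = rr - cr
    dc = cols - cc
    r = np.hypot(dr, dc)
    # phi = 0 points "up" (decreasing row); positive toward anterior (right)
    phi = np.arctan2(dc, -dr)
    inside = (r >= spec.r_inner) & (r <= spec.r_outer) & (np.abs(phi) <= spec.angle / 2)
    a, b, t = spec.r_inner, spec.r_outer, spec.angle
    truth = PhantomTruth(
        area=(t / 2) * (b**2 - a**2),
        medial_length=t * (a + b) / 2,
        thickness=b - a,
        curvature=2 / (a + b),
        euclidean_distance=(a + b) * np.sin(t / 2),
        perimeter=2 * (b - a) + t * (a + b),
    )
    return CCMask(inside.astype(np.uint8), pixel_spacing=(s, s)), truth


# ---------------------------------------------------------------------------
# CC arch phantom


@dataclasses.dataclass(frozen=True)
class _ArchParams:
    """Sampled geometry of one CC arch phantom (all lengths mm)."""

    radius: float
    span: float            # total subtended angle, radians
    tilt: float            # rotation of the arch about its center
    center: tuple[float, float]
    t_mid: float           # body thickness
    t_genu: float          # anterior end thickness
    t_splenium: float      # posterior end thickness
    thin_factor: float = 1.0      # hypoplasia scaling
    warp_amp: float = 0.0         # dysplasia radial displacement, mm
    warp_freq: float = 0.0        # cycles over the span
    warp_phase: float = 0.0
    cut_fraction: float = 0.0     # agenesis: posterior fraction removed


def _sample_arch(rng: np.random.Generator, label: str) -> _ArchParams:
    radius = float(np.clip(rng.normal(25.0, 2.0), 20.0, 31.0))
    span = float(np.clip(rng.normal(2.4, 0.12), 2.0, 2.8))
    tilt = float(rng.normal(0.0, 0.06))
    center = (140.0 + rng.uniform(-4, 4), 128.0 + rng.uniform(-4, 4))
    t_mid = float(np.clip(rng.normal(5.5, 0.5), 4.0, 7.0))
    t_genu = float(np.clip(rng.normal(9.0, 0.7), 7.0, 11.0))
    t_spl = float(np.clip(rng.normal(10.5, 0.7), 8.5, 12.5))
    kw = dict(radius=radius, span=span, tilt=tilt, center=center,
              t_mid=t_mid, t_genu=t_genu, t_splenium=t_spl)
    if label in ("hypoplasia", "hypoplasia_dysplasia"):
        kw["thin_factor"] = float(rng.uniform(0.4, 0.6))
    if label in ("dysplasia", "hypoplasia_dysplasia"):
        kw["warp_amp"] = float(rng.uniform(3.0, 5.5))
        kw["warp_freq"] = float(rng.choice([1.5, 2.0, 2.5]))
        kw["warp_phase"] = float(rng.uniform(0, 2 * np.pi))
    if label == "agenesis":
        kw["cut_fraction"] = float(rng.uniform(0.3, 0.7))
    return _ArchParams(**kw)


def _thickness_at(p: _ArchParams, q: np.ndarray) -> np.ndarray:
    """Thickness profile over normalized angle q in [-1, 1] (posterior -> anterior).

    Quadratic blend: body thickness in the middle rising smoothly to the
    genu (q = +1) and splenium (q = -1) end thicknesses.
    """
    end = np.where(q > 0, p.t_genu, p.t_splenium)
    return (p.t_mid + (end - p.t_mid) * q**2) * p.thin_factor


def _radius_at(p: _ArchParams, q: np.ndarray) -> np.ndarray:
    r = np.full_like(np.asarray(q, dtype=float), p.radius)
    if p.warp_amp > 0:
        r = r + p.warp_amp * np.sin(np.pi * p.warp_freq * (q + 1) + p.warp_phase)
    return r


def _rasterize_arch(p: _ArchParams, shape: tuple[int, int], spacing: float) -> np.ndarray:
    rr, cc = _pixel_grid_mm(shape, spacing)
    dr = rr - p.center[0]
    dc = cc - p.center[1]
    r = np.hypot(dr, dc)
    phi = np.arctan2(dc, -dr) - p.tilt
    half = p.span / 2
    q = np.clip(phi / half, -1.0, 1.0)
    band = np.abs(r - _radius_at(p, q)) <= _thickness_at(p, q) / 2
    inside = band & (np.abs(phi) <= half)
    if p.cut_fraction > 0:
        # remove the posterior (negative-phi) fraction of the span
        cut_edge = -half + p.cut_fraction * p.span
        inside &= phi >= cut_edge
    return inside.astype(np.uint8)


def _arch_truth(p: _ArchParams) -> PhantomTruth:
    """Quadrature truth for an unwarped arch.

    Uses the exact annular identities: d(area) = R t(phi) d(phi),
    medial length = R * span; boundary arcs integrate
    sqrt((R +- t/2)^2 + (t'/2)^2) d(phi).
    """
    half = p.span / 2
    lo = -half + p.cut_fraction * p.span
    phi = np.linspace(lo, half, 4001)
    q = phi / half
    t = _thickness_at(p, q)
    R = p.radius
    area = float(np.trapezoid(R * t, phi))
    medial_length = float(R * (phi[-1] - phi[0]))
    dt_dphi = np.gradient(t, phi)
    outer = np.sqrt((R + t / 2) ** 2 + (dt_dphi / 2) ** 2)
    inner = np.sqrt((R - t / 2) ** 2 + (dt_dphi / 2) ** 2)
    perimeter = float(np.trapezoid(outer + inner, phi) + t[0] + t[-1])
    chord = float(2 * R * np.sin((phi[-1] - phi[0]) / 2))
    return PhantomTruth(
        area=area,
        medial_length=medial_length,
        thickness=float(np.trapezoid(t, phi) / (phi[-1] - phi[0])),
        curvature=1 / R,
        euclidean_distance=chord,
        perimeter=perimeter,
    )


def _render(mask: np.ndarray, contrast: str, rng: np.random.Generator) -> np.ndarray:
    fg, bg = _CONTRAST_LEVELS[contrast]
    soft = ndimage.gaussian_filter(mask.astype(float), 0.8)
    img = bg + (fg - bg) * soft
    # smooth background texture (other structures / tissue heterogeneity)
    texture = ndimage.gaussian_filter(rng.standard_normal(mask.shape), 6.0)
    texture /= max(np.abs(texture).max(), 1e-9)
    img += 0.08 * abs(fg - bg) * texture
    # multiplicative smooth bias field
    bias = ndimage.gaussian_filter(rng.standard_normal(mask.shape), 40.0)
    bias /= max(np.abs(bias).max(), 1e-9)
    img *= 1.0 + 0.10 * bias
    img += rng.normal(0.0, 0.05 * abs(fg - bg), mask.shape)
    return img


def make_cc_phantom(
    seed: int,
    label: str = "normal",
    contrast: str = "T1w",
    spacing: float = 1.0,
    shape: tuple[int, int] = _IMAGE_SHAPE,
) -> PhantomSample:
    """Generate one CC-like phantom image/mask pair.

    ``truth`` is populated only for classes whose medial curve is an
    un-warped circular arc (normal, hypoplasia, agenesis); the sinusoidal
    warp of the dysplasia classes has no closed-form descriptors.
    """
    if label not in PHANTOM_CLASSES:
        raise ValidationError(f"unknown phantom class {label!r}")
    if contrast not in _CONTRAST_LEVELS:
        raise ValidationError(f"unknown contrast {contrast!r}")
    rng = np.random.default_rng(seed)
    params = _sample_arch(rng, label)
    mask = _rasterize_arch(params, shape, spacing)
    img = _render(mask, contrast, rng)
    truth = _arch_truth(params) if params.warp_amp == 0 else None
    return PhantomSample(
        image=MidsagittalImage(img, pixel_spacing=(spacing, spacing), contrast=contrast,
                               provenance=f"phantom seed={seed} class={label}"),
        mask=CCMask(mask, pixel_spacing=(spacing, spacing)),
        label=label,
        truth=truth,
    )


def make_dataset(
    n: int,
    class_mix: dict[str, float] | None = None,
    seed: int = 0,
    contrast: str = "T1w",
) -> list[PhantomSample]:
    """Generate a reproducible labeled phantom collection.

    Per-class counts follow the mix by largest-remainder rounding so they
    sum to exactly ``n``.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if class_mix is None:
        class_mix = {"normal": 1.0}
    unknown = set(class_mix) - set(PHANTOM_CLASSES)
    if unknown:
        raise ValidationError(f"unknown classes in mix: {sorted(unknown)}")
    total = sum(class_mix.values())
    if abs(total - 1.0) > 1e-6:
        raise ValidationError(f"class mix must sum to 1, got {total}")
    classes = [c for c in PHANTOM_CLASSES if c in class_mix]
    exact = np.array([class_mix[c] * n for c in classes])
    counts = np.floor(exact).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(exact - counts))
    for i in range(remainder):
        counts[order[i % len(classes)]] += 1
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)
    samples = []
    k = 0
    for cls, cnt in zip(classes, counts):
        for _ in range(cnt):
            samples.append(make_cc_phantom(int(child_seeds[k]), cls, contrast))
            k += 1
    return samples


def corrupt_mask(mask: CCMask, mode: str, rng: np.random.Generator) -> CCMask:
    """Produce a deliberately failed segmentation from a good mask.

    Modes: ``box_delete`` removes a random rectangle overlapping the
    structure, ``dilate`` grows the mask by 3 binary dilations, and
    ``speckle`` randomly flips pixels in a narrow band around the
    boundary, leaving a ragged contour.  (Isolated far-field specks
    would be erased by the pipeline's largest-component cleanup, so the
    speckle mode concentrates on the boundary where it survives.)
    """
    if mode not in CORRUPTION_MODES:
        raise ValidationError(f"unknown corruption mode {mode!r}")
    lab = mask.labels.copy()
    if mode == "box_delete":
        fg = np.argwhere(lab)
        if len(fg) == 0:
            raise ValidationError("cannot corrupt an empty mask")
        r0, c0 = fg[rng.integers(len(fg))]
        h = int(rng.integers(10, 30))
        w = int(rng.integers(10, 30))
        lab[max(0, r0 - h // 2): r0 + h // 2, max(0, c0 - w // 2): c0 + w // 2] = 0
    elif mode == "dilate":
        lab = ndimage.binary_dilation(lab, iterations=3).astype(np.uint8)
    else:
        inner = ndimage.binary_erosion(lab, iterations=2)
        outer = ndimage.binary_dilation(lab, iterations=2)
        band = np.logical_and(outer, ~inner)
        flips = band & (rng.random(lab.shape) < 0.4)
        lab = np.logical_xor(lab, flips).astype(np.uint8)
    return CCMask(lab, pixel_spacing=mask.pixel_spacing)
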