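# ccshape

Automated shape analysis of the midsagittal corpus callosum (midCC).

The corpus callosum is the brain's largest white-matter tract, and the
shape of its midsagittal cross-section — area, thickness along the
structure, curvature, regional morphology of the genu, body and
splenium — varies with development, degeneration, and a range of
congenital malformations (hypoplasia: uniformly thin; dysplasia:
distorted overall shape; agenesis: partially or fully absent).
`ccshape` is a tool for researchers who want those measurements from
large MRI collections without manual tracing. It provides:

* **Segmentation** — a UNet trained on midsagittal slices (any of
  T1w / T2w / FLAIR contrast), with an augmentation pipeline emulating
  clinical image quality: through-plane resolution loss, contrast
  alteration by histogram matching, rotation sweeps, and random
  occluding boxes.
* **Shape metrics** — 12 global descriptors plus genu/body/splenium
  regional ones, built around a sub-pixel *medial curve* through the
  structure:
  - Total Area, Total Perimeter
  - Total MedialCurveLength, Total EuclideanDist (tip-to-tip chord)
  - thickness statistics (mean/std/max/min of the inscribed-disk
    diameter 2·EDT along the curve)
  - curvature statistics (mean/std/max of |κ|) and Total Curve, the
    total absolute turning ∫|κ| ds in radians
* **Automatic quality control** — pass/fail classification of
  segmentations from their shape metrics (neural-network and
  five-member voting-ensemble families).
* **Abnormality classification** — a two-stage model (metric-based
  score network → XGBoost on metrics + scores) over the five classes
  normal / hypoplasia / dysplasia / combined / agenesis.
* **Reliability** — Dice overlap and ICC(2,1) test-retest reliability
  of every metric across repeated sessions.
* **Phantoms** — an analytic generator (annulus sectors with closed-form
  truth; CC-like arches with abnormal variants in three MRI contrasts)
  so the whole pipeline is testable without any data downloads.

## Worked example

```python
import numpy as np
from ccshape.phantom import AnnulusSectorSpec, make_annulus_sector
from ccshape.shape_metrics import compute_all_metrics

# an annulus sector: mean radius 25 mm, quarter turn, 10 mm thick
spec = AnnulusSectorSpec(r_inner=20, r_outer=30, angle=np.pi / 2,
                         center=(64, 64), pixel_spacing=0.5)
mask, truth = make_annulus_sector(spec, (256, 256))
m = compute_all_metrics(mask)
print(f"area      {m.total_area:8.1f} mm^2   (closed form {truth.area:8.1f})")
print(f"length    {m.total_medial_curve_length:8.2f} mm     (closed form {truth.medial_length:8.2f})")
print(f"thickness {m.total_mean_thick:8.2f} mm     (closed form {truth.thickness:8.2f})")
print(f"curvature {m.total_mean_curve:8.4f} /mm    (closed form {truth.curvature:8.4f})")
print(f"turning   {m.total_curve:8.3f} rad    (sector angle {spec.angle:8.3f})")
```

prints

```
area         396.0 mm^2   (closed form    392.7)
length       39.44 mm     (closed form    39.27)
thickness     9.99 mm     (closed form    10.00)
curvature   0.0382 /mm    (closed form   0.0400)
turning      1.547 rad    (sector angle    1.571)
```

— the rasterized sector's measurements land within a few percent of the
closed forms (the pixel-count area of this particular raster is itself
396.0 mm²; curvature is the hardest quantity to recover from a binary
grid and sits within 5% here).

The same engine runs on segmented MRI: `ccshape segment` produces a
mask from a trained checkpoint, `ccshape metrics` writes the metric
CSV, and `ccshape qc predict` / `ccshape classify predict` screen and
classify it. `ccshape --help` lists the full command set.

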