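# Methods

`ccshape` measures the shape of the corpus callosum's midsagittal
cross-section (midCC) from binary masks, segments the midCC on 2D
midsagittal MRI slices, screens segmentations automatically, classifies
callosal shape abnormalities, and quantifies test-retest reliability.
This note records the models, the estimators, the parameters that
matter, and the choices made where the design was genuinely open.

## Phantoms and what they do (and do not) emulate

All quantitative claims in the test suite rest on synthetic phantoms
with analytically known geometry.

**Annulus sectors.** A sector of an annulus (inner radius *a*, outer
radius *b*, angle *θ*) has closed-form area *θ(b²−a²)/2*, medial length
*θ(a+b)/2*, thickness *b−a*, midline curvature *2/(a+b)*, tip chord
*(a+b)·sin(θ/2)* and perimeter *2(b−a)+θ(a+b)*. Sectors are rasterized
by pixel-center membership (no anti-aliasing) so exhaustive pixel
counting is an unambiguous oracle. The accuracy suite uses a fixed
design of 20 sectors: angles uniformly spanning [π/6, π/2], mean radii
sweeping 35 → 15 → 35 mm, and thickness ramping 4 → 12 mm with arc
length, capped at arc/2.8 — ribbon thickness and midline curvature are
only identifiable for elongated bands, so stubby sectors (arc
comparable to thickness) are excluded by design.

**CC arches.** The CC-like phantom is an annular band with a smooth
quadratic thickness profile — thicker at the anterior (genu analogue,
~9 mm) and posterior (splenium analogue, ~10.5 mm) ends, thinner in the
body (~5.5 mm) — on a 256×256, 1 mm grid, rendered bright on T1w-like,
dark on T2w-like and intermediate on FLAIR-like backgrounds with
Gaussian noise (σ = 5% of the foreground–background contrast), a smooth
multiplicative bias field (±10%) and low-frequency background texture.
Abnormal variants: hypoplasia scales the thickness profile by
U(0.4, 0.6); dysplasia displaces the medial radius by a low-frequency
sinusoid (amplitude 3–5.5 mm, 1.5–2.5 cycles); the combined class
applies both; agenesis deletes a posterior fraction U(0.3, 0.7) of the
arch. Geometry parameters are drawn per phantom from narrow Gaussian
ranges around anatomically plausible values; every phantom is a pure
function of its seed.

Phantoms do **not** emulate partial-volume effects, scanner-specific
noise spectra, neighbouring structures with CC-like intensity (fornix,
septum), or registration error. Passing the phantom studies therefore
demonstrates the internal consistency and accuracy of the machinery,
not clinical performance on real MRI.

**Corruption modes for QC.** Deliberately failed segmentations are
produced by deleting a random rectangle, dilating the mask three times,
or randomly flipping 40% of pixels in a ±2-pixel band around the
boundary (ragged contour). Uniform sparse speckle was rejected as a
fail mode: the pipeline's own largest-component/hole-fill cleanup
erases it, making it undetectable *in principle* by any feature-based
QC.

## The medial curve

Everything length-, thickness- and curvature-related derives from a
medial curve through the structure, anterior tip first. Discrete
skeletons proved unusable here: thinning sits up to a pixel off the
true midline, and on thick bands the skeleton grows long diagonal
corner branches at the tips which a longest-path criterion *prefers*.
The construction used instead:

1. **Geodesic parametrization.** Two in-mask geodesic sweeps (Dijkstra
   on the 8-connected pixel graph) locate the two tip pixels; each
   pixel is parametrized by half the difference of its geodesic
   distances to the tips — monotone along the band and immune to
   branch artifacts.
2. **Bin centroids.** Centroids of ~1 mm parameter bins give an
   ordered raw midline; bins within half a local thickness of the tips
   (where cross-sections bend around the tip caps) are dropped.
   Centroid noise scales as spacing/√(pixels per bin) and weights the
   smoothing spline accordingly.
3. **Sub-pixel recentering.** Each point moves to the midpoint of the
   two 0.5-level crossings of the lightly smoothed mask (Gaussian,
   σ = 0.7 px) along its normal. The smoothed iso-contour localizes
   the boundary to a few hundredths of a millimetre, far below the
   pixel quantization of the distance-transform ridge.
4. **Tip completion.** Each end is extended along the circle fitted
   (Taubin) to the adjacent 12 mm of curve until the path exits the
   mask. The refined endpoints themselves are discarded first
   (one-sided gradients make them unreliable).
5. The curve is resampled at 1 point/mm; anterior = larger column
   index under the package's coordinate convention (rows
   inferior→superior, columns posterior→anterior).

## Metric estimators

* **Area**: pixel count × pixel area.
* **Perimeter**: marching-squares contour at iso-level 0.5 of the
  σ = 0.7 px Gaussian-smoothed mask. The raw mid-crack polygon of a
  binary staircase overestimates smooth boundaries by 4–6%; the
  smoothed field restores sub-pixel placement (disk +1.4%, sectors
  <1% at 0.5 mm) at the cost of rounding sharp raster corners by about
  a pixel (an axis-aligned 10×4 px rectangle reads ≈25.7 mm instead of
  28 mm).
* **Thickness**: the span between the two boundary crossings along the
  local normal — at a midline point this equals the inscribed-disk
  diameter (2× the distance transform) but avoids the half-pixel EDT
  quantization that exceeds 5% for 4 mm structures at 0.5 mm spacing.
  EDT ridge maxima (on a 3× upsampled grid) fill in near tip caps.
  Summary statistics exclude points closer to a tip than one local
  thickness (never less than 5% of arclength), where the profile
  reflects the caps, not the band width.
* **Curvature**: the default estimator fits a local circular-band
  model (center offset, heading, curvature, thickness) to the raw
  in/out pixel labels in a 14 mm sliding window (the whole curve for
  structures under ~25 mm), minimizing a squared-hinge
  misclassification loss; because rasterization records exact
  pixel-center membership, the labels confine the band to a fraction
  of a pixel. The parameters consistent with the labels form an
  interval in curvature; the reported value is the interval midpoint
  (any single feasible point can sit at either edge). Fits run every
  ~4 mm and interpolate between. A fast curve-only mode (Taubin circle
  fits through curve points) is used for batch feature extraction,
  where ranking rather than absolute accuracy matters. Differentiating
  a smoothed midline was rejected: boundary-quantization "waves"
  correlated over several millimetres bias curvature by 10–50% on
  short flat arcs.
* **Total Curve** is the total absolute turning ∫|κ|ds in radians —
  the only reading distinct from both the medial length and the mean
  curvature among the global metric set.
* **Regions**: the curve splits at arclength fractions 1/4 and 3/4
  (genu / body / splenium — an arclength stand-in for the JHU
  ICBM-DTI-81 partition, removing any atlas-file dependency); each
  mask pixel takes the region of its nearest curve point, so regional
  areas partition the total exactly.

Measured accuracy on the 20-sector design at 0.5 mm spacing: area,
perimeter, medial length, thickness and chord all within 3%
worst-case; mean curvature and total turning within 5% for 18 of 20
sectors, with the two flattest thin bands at 5–7.5% — at or near the
information limit of a binarized 0.5 mm grid (the feasible-interval
width itself reaches ±10% there).

## Segmentation

A standard UNet (default depth 4, 16 base channels doubling per level,
two 3×3 conv + batch-norm + ReLU blocks per level, 2×2 max pooling,
nearest-neighbour upsampling with skip concatenation, 1×1 sigmoid
head), implemented in a compact numpy layer kit (im2col convolutions on
BLAS, float32) and trained with Adam on a soft-Dice + binary
cross-entropy loss. The loss choice is this package's: only the IOU
monitoring metric is prescribed by the protocol it follows. Training
monitors mean thresholded IOU on a held-out 20% split and stops at the
first epoch whose IOU fails to improve on the previous one's by at
least 1×10⁻⁴ — standard early stopping with a minimum delta and
patience one, evaluated per *epoch* (per-batch IOU noise would trigger
any tolerance immediately) — or at 250 epochs. Defaults follow the
full-scale protocol (learning rate 1×10⁻⁴, batch 8, 256×256 inputs).

The desk-scale training study uses 200 phantoms (70% normal, 10% each
hypoplasia / dysplasia / agenesis) on a 128×128 working grid with
learning rate 1×10⁻³ and batch 4: it runs ~250× fewer optimizer steps
than the full protocol, which scales the step size up and the grid
down; all other protocol elements (split, monitoring, stopping rule)
are unchanged. Inference thresholds the probability map at 0.5, keeps
the largest 8-connected component, and resamples to the input grid; an
all-background map yields an empty mask for downstream QC to flag.

## Quality control

Pass/fail classification from the shape-metric vector, z-scored on the
training split only. Families: a 42/22/11 sequential network, an
80/80/80/40/40/40 network, and a five-member ensemble (XGBoost, KNN,
SVC, logistic regression, random forest) combined by hard majority
vote — odd membership excludes ties. The ensemble's AUC uses averaged
member probabilities (hard votes give no ranking); both the voted
label and the continuous score are reported because they can disagree
near the boundary. Small narrow MLPs occasionally start in a dead
basin; training retries up to three initializations and keeps the best
fit. Feature importance is permutation importance on held-out data.
When a corrupted mask defeats medial-curve extraction entirely, the
feature extractor reports the metrics that cannot fail (area,
perimeter) and zeros the curve-derived ones — extraction failure is
itself a strong fail signal.

## Abnormality classification

Two stages: a small network (hidden layers 32/16, softmax over the
five classes) trained on the shape metrics emits per-class probability
scores; XGBoost (200 trees, depth 4, learning rate 0.1) trains on the
metrics plus those scores. Stage two sees *out-of-fold* stage-one
scores (5-fold): in-sample scores are nearly one-hot and would let the
booster ignore the metrics entirely. Minority classes are oversampled
with replacement to configured target counts, on the training split
only — the simplest scheme consistent with integer targets. In the
phantom study the top importances are the stage-one scores with
Total Perimeter, and Total MinThickness immediately after: the scores
subsume the thickness signal they were trained on. Agenesis with only
a handful of training examples cannot be meaningfully learned; phantom
experiments use at least 50 per class.

## Reliability

Dice = 2|A∩B|/(|A|+|B|), defined as 1 when both masks are empty.
ICC here is the Shrout–Fleiss ICC(2,1) — two-way random effects,
absolute agreement, single measurement — computed from the two-way
ANOVA mean squares; the "2,1" reading was chosen because common
tooling labels the average-measure variant ICC2k. One ICC per metric
across all subjects jointly (the standard estimand for a complete
subjects × sessions design); incomplete designs are rejected rather
than imputed, which would silently change the estimand. The ANOVA
implementation matches an independent brute-force oracle to 1e-10 and
pingouin's absolute-agreement single-measure row to 1e-8.

## Numerical and policy choices

* Midline index of an even left-right axis: floor(n/2), 0-based — the
  protocol this follows does not state the tie-break.
* Contrast alteration is realized as histogram matching to a reference
  image (monotone remapping, rank-preserving); the referenced
  procedure is not specified in detail, so this stand-in is the
  package's choice.
* Rotation sweeps rotate clockwise about the grid center, fill
  out-of-frame pixels with the image minimum, and re-binarize masks at
  0.5; occluding boxes use the image minimum rather than literal zero
  to be robust to background offsets.
* The ShapeMetrics invariant perimeter ≥ 2 × tip distance is enforced
  with 5% slack: the contour estimator smooths ragged boundaries that
  genuinely violate the bound at estimator level.
* Masks round-trip losslessly through PNG (0/255, threshold >127 on
  load) and single-slice NIfTI; feature tables are CSV with 17
  significant digits.

## Problem sizes

The reference experiments use 20 sectors (metric accuracy), 200
training pairs at 128×128 (segmentation), 120 phantoms → 240 masks
(QC), 300 phantoms (abnormality), and 100 replicates of 100×10
matrices (ICC recovery). These sizes were chosen so the full suite
reruns comfortably on a single CPU core while leaving each study's
discrimination or accuracy target clearly resolvable.
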