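# Methods

## Scope and model

`stomatakit` implements the measurement and statistics layers of a
stomatal phenotyping pipeline for maize abaxial epidermis imagery. The
object of study is the stomatal complex: a roughly elliptical unit
consisting of the central guard-cell pair and pore (GCP) flanked by two
subsidiary cells. A pipeline run takes a calibrated grayscale field of
view, produces stomatal bounding boxes (count → density), two semantic
masks (intact complex; GCP), fuses them, extracts per-stoma instances
by connectivity, and measures eleven traits per stoma; trait tables
then feed correlation, ANOVA/letter-display, PCA and heterosis
analyses.

Learned detectors and segmenters are intentionally out of the library's
core: they are hardware- and training-data-specific, so the pipeline
defines them as protocols (`Detector`: image → scored boxes;
`Segmenter`: image → mask pair) and ships deterministic classical
reference implementations that are exact on imagery obeying the
synthetic generator's intensity contract. This keeps every downstream
stage executable and testable at desk scale.

## Calibration

Physical scale is derived from the microscope's printed field sizes:
a 350× frame covers 767 µm × 767 µm and a 900× frame 298 µm × 298 µm,
both at 1024 px natively, giving 0.749 and 0.291 µm/px. No µm/px
constant is hard-wired beyond this table; an explicit override is
always available, and resizing rescales µm/px so that the physical
field (and hence any density) is conserved. Boxes are 0-based and
half-open on their upper edges so pixel areas are exactly
(x1−x0)(y1−y0).

## Synthetic epidermis generator

The generator emulates the file-wise arrangement of maize stomata:
candidate centres lie on jittered parallel rows (default spacing
90 µm), with the long axis along the row direction plus Gaussian
orientation jitter (sd 6°), and rejection sampling forbids
bounding-box overlap (6 µm clearance). Each stoma is an ellipse with
length ~ N(95, 5²) µm and width ~ N(55.5, 1.8²) µm; the GCP region is a
concentric, co-oriented ellipse scaled so its area fraction is
~ N(0.50, 0.025²). These defaults sit inside the realistic ranges for
the material (length 85–105 µm, width 52–59 µm, density 70–95 mm⁻²,
GCP fraction 0.45–0.55). Intensities are three flat levels —
background 200, subsidiary 120, GCP 40 — plus clipped additive Gaussian
noise (default sd 4 gray levels); levels must stay ≥ 20 gray levels
apart so the reference segmenter's banding contract is well defined.

The requested count is round(density × field area); if rejection
sampling cannot place that many without overlap the maximum placeable
is kept and a warning logged — the scene's `achieved_density` is always
the exact bookkeeping count/area. All randomness comes from one
`numpy` generator seeded per scene, so identical parameters give
bit-identical scenes. Stomata are wholly inside the frame by default;
a flag allows border-clipped stomata for exercising the border policy.

Because the generative shapes are ellipses, every trait has a closed
form (SA = πab, SP = 4aE(1−(b/a)²), SE = √(1−(b/a)²), …), giving exact
per-stoma ground truth. What the generator does **not** emulate:
SEM texture, charging artifacts, uneven illumination, touching or
partially collapsed stomata, and the irregular lobed outline of real
complexes. Consequently a passing recovery test bounds the
*discretisation and algorithmic* error of the measurement chain, not
its robustness to real-world segmentation noise; note also that ideal
ellipses at these aspect ratios have SR ≈ 0.9, higher than the ≈ 0.6
printed for real stomata, whose boundaries are more convoluted.

## Reference detector and segmenter

Detection: pixels darker than a threshold (default 160, the
background/subsidiary midpoint) are closed morphologically (8-connected
structuring element, 1 iteration), hole-filled, labelled with
8-connectivity and filtered to physical areas within
[1 000, 20 000] µm²; each survivor yields a tight box with confidence
1.0. Segmentation: pixels are classified into non-overlapping
half-open intensity bands with boundaries at the midpoints between
adjacent levels; the complex mask is the union of the subsidiary and
GCP bands, the GCP mask the GCP band, each followed by hole-filling.
With the default levels the band half-width is 40 gray levels = 5σ at
noise sd 8, so misclassified pixels are vanishingly rare; a small
minimum-instance-area filter (default 16 px in the pipeline helper)
absorbs any stray specks.

Counting includes border-touching detections — density is a per-area
count and partial stomata still occupy the frame — while size/shape
traits exclude border-truncated instances by default (their geometry is
clipped); they are reported with a `border_touching` flag and a
`keep` policy is available.

## Mask fusion and instance extraction

The two semantic masks are fused by pixelwise union: the masks are
binary, so union is the only idempotent reading of "summing" them into
a refined structure mask, and it can only add pixels (monotone), never
remove them. Instances are 8-connected components of the fused mask
(the choice is isolated in one parameter; 4-connectivity would split
diagonal touches); each instance carries the intersection of its pixel
set with the GCP mask, so GCPA ≤ SA by construction.

## Trait measurement: numerical choices

* **Areas** are pixel counts × (µm/px)²; SCA = SA − GCPA exactly, hence
  the partition identities SCA + GCPA = SA and PGCPA + PSCA = 1 hold to
  machine precision.
* **Perimeter** is the length of the outer marching-squares contour
  (level 0.5 on the padded binary grid) after a circular moving average
  of its vertices (window 5). Raw marching-squares polygons
  overestimate smooth perimeters by ~5% (staircase), which alone would
  bias SR = 4πSA/SP² down by ~10%; boundary-pixel counting is worse
  still. The smoothed contour measures a rasterised circle's SR within
  1% of 1 and ellipse perimeters to ~0.3%. The outer contour is the
  loop enclosing the largest area; ties (possible only on fragmented
  masks) break deterministically on vertex count, then lowest vertex.
* **SL/SW** are the side lengths of the minimum-area rotated rectangle
  of that same smoothed contour. Using the sub-pixel contour rather
  than a pixel-corner hull removes a ~1 px inflation of the short axis
  (pixel corners protrude beyond the underlying smooth boundary), which
  matters at width ≈ 74 px where 1 px is 1.4%.
* **SE** uses the eigenvalues of the second central moment matrix of
  the pixel set, with the per-pixel 1/12 variance added to the diagonal
  so single-pixel-wide shapes stay finite; for an ideal ellipse this
  reproduces √(1−(b/a)²).
* Traits are computed per stoma first and averaged afterwards (mean of
  ratios), so a grouped mean SR is not exactly 4π·mean(SA)/mean(SP)² —
  the roundness consistency check on published grouped means is
  approximate by Jensen's inequality (it agrees at the printed 2-dp
  precision).

Validity domain: the smoothed-contour estimators are accurate for
blob axes ≳ 20 px; below that, discretisation dominates and the stated
recovery bounds do not apply.

## Evaluation metrics

Precision and recall are implemented in their universal forms
P = TP/(TP+FP), R = TP/(TP+FN). (Printed formula sheets occasionally
transpose FP and FN between the two; since both orientations are
obtainable by swapping arguments, the standard forms are the only
defensible implementation and the convention is fixed here.)
Undefined denominators return NaN with an explicit warning rather than
a silent zero. Matching is greedy in descending confidence with each
truth box consumed at most once (ties: higher IoU, then lower truth
index); AP50 is the all-point interpolated area under the P-R curve
(the 101-point variant is available behind a flag and differs
negligibly). R² of the reliability fit is the OLS coefficient of
determination (≡ squared Pearson r for a simple regression); RMSE is
taken on the raw automated-vs-manual pairs, not the fit residuals.
Two empty masks score Dice = IoU = 1 with a warning: perfect agreement
on absence.

## Statistics

Correlation p-values come from the t distribution with n−2 df, with
per-pair complete-case handling and no multiplicity correction
(reported raw). The post-hoc test behind the letter display is Tukey
HSD at α = 0.05 — the standard companion of a one-way ANOVA letter
display — and letters are assigned by the insert-and-absorb algorithm
with groups ordered by descending mean (top group gets "a"); the
display never joins a significant pair and never separates a
non-significant one. PCA z-scores use the sample SD (ddof = 1),
eigendecomposes the correlation matrix, fixes each component's sign so
its largest-magnitude loading is positive, and reports eigenvalues as
percent variance contributions (summing to 100). Heterosis is emitted
in all three conventions — mid-parent, over-high-parent,
over-low-parent — because published "super parental" rates do not
always state which parent anchors the comparison; all three are
scale-invariant.

## Problem sizes

Tests and the acceptance script run on full 1024² frames (≈ 47 stomata
at 80 mm⁻²) for end-to-end recovery, 256² frames for unit-level
checks, 500-row synthetic trait tables for the statistics layer, and
≥ 1000 random mask pairs / 300 random box sets for the fuzzed metric
identities. These sizes put every estimator well inside its validity
domain while keeping a full run in the order of seconds.

## Known limitations

* The reference detector/segmenter assume the generator's three-band
  intensity contract; on real SEM imagery they are only a baseline and
  a learned model should be plugged in through the protocols.
* Touching stomata are not split (the generator guarantees separation;
  no watershed stage is included).
* Pore aperture (open/closed state) is not measured; traits describe
  the complex and the GCP region as planar areas.
* The compact letter display depends on the chosen post-hoc test;
  switching from Tukey HSD changes letters, not means.
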