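# Methods

`cxrline` implements the mask-level reasoning stages of a right internal
jugular line (RIJL) segmentation pipeline for portable AP chest radiographs:
anatomically guided search-region cropping, reconnection of fragmented CNN
predictions (Bidirectional Connect), catheter tip localization, and
boundary-distance evaluation. The CNN segmenter itself is an external
interface — any program that maps a cropped image to a binary mask of the
same shape — so every stage here is deterministic geometry on binary masks.

## Coordinate and mask model

Masks live on a 2-D pixel lattice with per-axis spacing in mm. Coordinates
are 0-based `(row, col)`; row 0 is the superior image edge and rows increase
inferiorly; the physical position of a pixel is `index × spacing`. Under
standard AP display the patient's right maps to decreasing column indices.
Connected-component analysis defaults to 8-adjacency: catheters are thin,
near-vertical strokes whose diagonal runs would artificially fragment under
4-adjacency. PNG files carry no spacing, so spacing must be supplied
explicitly for them (an error, never a silent 1 mm assumption); NIfTI
spacing comes from the header.

## Trachea-guided search region

The trachea landmark mask is reduced to its largest connected component and
its centroid taken as the anchor. The RIJL search box is 300 mm tall by
150 mm wide in physical units, converted to pixels by rounding
`extent / spacing` (≤ half a pixel of rounding error per edge; 300×150 px at
1.0 mm spacing, 2000×1000 px at 0.15 mm). Two anchoring choices were
genuinely open and are exposed as parameters:

* **Vertical** (`vertical_anchor_fraction`, default 1/3): the top edge sits
  one third of the box height above the trachea centroid. The catheter
  enters at the neck and descends toward the superior vena cava, i.e. mostly
  inferior to mid-trachea, so the box extends twice as far down as up.
* **Horizontal**: the medial box edge sits at the centroid column and the
  box extends laterally toward the patient's right. RIJLs approach the
  midline inferiorly, so the midline column itself is included.

Boxes are clipped to the grid, and the clipped geometry — upper-right
vertex, box dimensions, original shape, spacing — is stored in a JSON crop
footprint, which makes restoration to original coordinates exact even at
image borders. Cropping is implemented as subimage extraction; restore
embeds the cropped mask back and zero-fills the complement, so
`restore(crop(M, b))` equals `M` masked to `b` bit-exactly.

## Bidirectional Connect

The postprocessing premise is that the catheter produces the largest
connected component of the prediction, with the remaining fragments lying
roughly along its continuation. The algorithm:

1. Anchor on the largest component (size ties broken by the
   lexicographically smallest member pixel) and skeletonize it.
2. Take the skeleton's superior (min-row) and inferior (max-row) endpoints,
   ties broken by smaller column. Both endpoints are searched by default;
   a flag restricts the search to one.
3. At an endpoint, estimate the outward tangent as the unit vector from the
   skeleton pixel at geodesic lookback distance (default 10 px along the
   skeleton, BFS hop metric) to the endpoint. Using a lookback rather than
   the immediate neighbor keeps the direction from quantizing to multiples
   of 45°.
4. March along the tangent in steps of `step_fraction × scan_radius`
   (default 5 mm), sweeping a forward half-disk (radius 10 mm, half-aperture
   90°) at each position. Candidates are ranked by angular deviation, then
   distance, then `(row, col)` — all ties specified, so runs are
   deterministic.
5. On a hit, the whole hit component is absorbed: its skeleton joins the
   evolving curve, bridged by a Bresenham digital straight segment from the
   nearest pixel of the current curve to the nearest skeleton pixel of the
   fragment (nearest-to-nearest, to avoid doubling back). The march resumes
   from the fragment's far endpoint (most distal in the walk direction)
   with a re-estimated tangent.
6. The search from one endpoint stops when the cumulative empty-space
   travel exceeds `max_gap_mm` (default 40 mm) or the march leaves the
   image. Budget accounting: each bridged gap is charged its true length,
   which *replaces* the marching distance spent approaching that fragment
   (they cover the same space); traversal along absorbed fragments is free.
   Charging both march and bridge would double-count and starve legitimate
   multi-gap chains.
7. The union of anchor skeleton, absorbed skeletons and bridges is dilated
   with a Euclidean disk to restore a consistent stroke width. The default
   radius is half the anchor's median stroke width, estimated as the mean
   distance-to-background over anchor pixels, floored at 1 px.

The defaults (10 mm scan radius, 40 mm budget) make typical fragmentation
gaps on a chest radiograph — up to a few cm — bridgeable, while structures
several cm off-trajectory (e.g. a contralateral line ≥ 60 mm away) are
provably out of reach: the search envelope extends at most
`max_gap + scan_radius` = 50 mm from the catheter trajectory. No
line-likeness filter is applied to candidates; exclusion is purely
geometric. Guaranteed invariants: the output is a single connected
component; the anchor skeleton is preserved; every output pixel lies within
the dilation radius of an input skeleton or bridge pixel.

## Evaluation metrics

Boundaries are foreground pixels with at least one background 4-neighbor,
the image border counting as background (for 1-px-wide structures the
boundary is the whole structure). The average symmetric surface distance is

    ASSD(B1, B2) = [ Σ_{x∈B1} d(x, B2) + Σ_{y∈B2} d(y, B1) ] / (|B1| + |B2|)

with Euclidean distances in mm (indices scaled by spacing). It is computed
via the exact Euclidean distance transform and cross-checked in the test
suite against an independent brute-force double loop to 1e-9 mm. Empty
masks raise rather than scoring zero — silently scoring an empty prediction
would fake perfection; the evaluation report lists such samples as
failures.

The tip is the most inferior foreground pixel; when several pixels share
the maximal row the median column is taken (stable against stroke
thickness). Tip distance is the spacing-adjusted Euclidean distance between
predicted and true tips. Dice is provided for comparability with
overlap-based literature. Summaries report mean, sample SD (n−1) and a
normal-approximation 95% CI (`mean ± 1.96·SD/√n`), computed over sorted
values so they are bitwise order-invariant.

## Synthetic phantoms

Clinical data for this problem are not redistributable, so the generator
builds mask-level phantoms with the same structural challenges, fully
deterministic given a seed. On a default 512×512 grid at 1 mm spacing:

* **Trachea**: a vertical ellipse at the column midline (small seeded
  jitter), upper half of the image.
* **Ground-truth catheter**: a smooth, monotonically descending curve from
  a superior-lateral start on the patient-right side, curving medially to a
  tip inferior to the trachea centroid; a smoothstep medial drift plus a
  few random-phase low-frequency sinusoids (`curve_wobble`, relative
  amplitude 0.15) model course variability; rasterized with Bresenham
  segments and dilated to a 3 px stroke.
* **Degraded prediction**: the ground truth cut by `n_gaps` (default 2)
  gaps of 5–20 px, placed without overlap along the skeleton's geodesic
  parametrization; pixels are removed by nearest-skeleton-position, cutting
  the stroke perpendicular to the course. The first 5% of the curve is
  never cut, nor the last 5% while `protect_tip` holds, so the tip fragment
  survives (tip-amputating CNN failures are reachable via
  `protect_tip=False` for robustness experiments, not the default study
  condition).
* **Distractors** (default 1): short near-vertical tube segments on the
  contralateral side, ≥ 60 mm from the catheter trajectory (verified with
  a distance transform, so envelope-exclusion tests are well-posed),
  crossing the catheter's tip latitude. They emulate a *partial* CNN
  response to another line: smaller than any catheter fragment — the
  largest-component premise both postprocessing variants rest on — but
  inferior enough that a naive most-inferior-point tip lands on them,
  which is exactly the failure mode tip localization suffers on real
  radiographs with multiple tubes.

What the phantoms do **not** model: image intensities seen by a CNN
(grayscale rendering is decorative), nnU-Net's error statistics, patient
rotation, overlapping/superimposed catheters, or tip amputation under the
default settings. Passing phantom tests therefore demonstrates the
geometric correctness of cropping, reconnection and evaluation — not
end-to-end clinical performance, which depends on the external segmenter.

## Numerical choices and degenerate inputs

* Dilation is exact Euclidean (distance transform ≤ radius + 1e-9), so a
  unit radius yields the 4-neighborhood cross.
* Skeletonization delegates to scikit-image thinning and is specified by
  postconditions (subset of input, one pixel wide, component count
  preserved) rather than a named algorithm.
* Single-pixel anchors return the dilated anchor with a warning (no
  tangent exists); single-pixel skeletons raise `DirectionUndefinedError`
  inside the march and that endpoint is skipped.
* All randomness flows through `numpy.random.default_rng(seed)`; phantom
  sets derive per-sample seeds as `base + index` and record them in the
  manifest, so any sample regenerates bit-exactly.

## Problem sizes

The comparison harness defaults to 50 phantoms; the reconnection and tip
recovery properties are checked over 100 phantoms at 512×512 px — set sizes
chosen to give stable rates and means for a seeded, deterministic generator.
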