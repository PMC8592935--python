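# Methods

## The localization procedure and its assumptions

The pipeline assumes a single bud hanging from a single slender axis, imaged
roughly frontally, with the bud's hue in the wrap-around red/magenta band and
the axis both brighter (in HSV value) than the leafy background and slightly
lower in hue than the background's green bulk. It further assumes the bud is
bilaterally symmetric about its long axis, so that the line through the
upper- and lower-half centroids estimates that axis, and that the
inflorescence axis is straight enough over the region of interest to be
summarized by one line segment.

Under those assumptions the stages are: hue-fold → Otsu → opening/closing →
largest component (bud mask); bounding-box mid-height split and
first-moment centroids (centerline, tilt δ); equalized V − H difference →
phase inversion → Otsu → contour filtering → closing → largest-area-ratio
component (axis mask); probabilistic Hough on the mask boundary with
collinear merging and boundary pairing (axis segments); minimum
perpendicular distance to the bud centroid (segment selection); segment
midpoint (cutting point). When no segment survives, the cutting point falls
back to the intersection of the bud centerline with the top edge of the
bud's minimum rotated bounding rectangle and is flagged as a fallback, so a
caller can treat it as lower-confidence rather than a hard failure.

## Parameters that matter

| parameter | default | unit | role |
|---|---|---|---|
| `open_radius` | 2 | px | disk radius of the opening; removes specks of diameter < ~5 px |
| `close_radius` | 3 | px | disk radius of the closing; fills holes of diameter < ~7 px |
| `area_threshold` | 50 | px² | contours/holes below this are flipped in the axis pipeline |
| `hue_rotation` | 0 | 8-bit levels | re-centers the hue fold for non-magenta targets |
| `min_mean_redness` | 160 | 8-bit levels | gate that rejects an Otsu foreground outside the red band (no-bud images) |
| `min_length_frac` | 0.3 | of mask bbox height | minimum Hough segment length |
| `merge_angle_tol` / `merge_dist_tol` | 5 / 5 | ° / px | collinear fragment merging |
| `pair_max_separation` | 18 | px | opposite-boundary pairing into a midline; should exceed the axis width |
| `success_threshold` | 15 | px | the actuator's working tolerance for a usable cut point |

The boundary-pairing step exists because Hough on an edge map returns the
two boundary lines of a strip, each offset by half the strip width from the
true midline; averaging a near-parallel pair recovers the midline, which is
what the selection rule and the downstream midpoint actually need.

## What the synthetic generator emulates — and what it does not

A scene is a leafy green background (elliptical clutter blobs), a bright
greenish axis strip of width 9 px and length 90 px at tilt δ, and a magenta
bud rendered as a superellipse (exponent 3, length 120 px, maximum width
34 px) hanging from the axis, in a 320×320 frame. Backlighting is modeled
as a global value gain of 0.55 plus a +0.30 background lift, which degrades
the axis/background brightness contrast the way shooting into the light
does. Speck noise (1–4 px bud-colored blocks outside the bud) and hole
noise (1–6 px background-colored blocks strictly inside the bud interior)
perturb the image but not the ground-truth masks. All randomness flows from
one seed; re-rendering is bit-identical.

Two generator choices are deliberate separability constructions rather than
botanical fact, and are documented as such:

* the axis hue sits just below the background-hue bulk, so the equalized
  V − H difference isolates the axis by hue rank as well as brightness;
* within the leaf clutter, each leaf's brightness and hue derive from one
  shared shade draw, so the equalized V and H ranks of leaf pixels track
  each other and their V − H difference cancels. Without this coupling,
  rank-based equalization hands the brightest leaves a V rank close to the
  axis's regardless of raw contrast, which no threshold can undo.

Consequently, passing tests show the pipeline is correct and robust to the
modeled degradations (tilt, lighting gain, speck/hole noise, clutter); they
do not show robustness to occlusion, specular highlights, hue-shifted
illumination, motion blur, or multiple buds, none of which the generator
produces.

The bud silhouette's width/length ratio (≈0.28) was chosen from an analytic
property of the centerline estimator: the half-centroids of a convex shape
split by a horizontal line lie on the diameter conjugate to the horizontal
direction, not on the major axis, so the recovered tilt is biased low by an
amount growing with the width/length ratio and with δ. For an exponent-3
superellipse at ratio 0.28 the bias stays below ~1.7° up to δ = 25°, within
the ±2° recovery tolerance the tests assert; wider silhouettes (ratio 0.5)
would bias by 5° or more at δ = 25° and would need an explicit shape-based
correction that the minimal estimator does not attempt.

## Numerical choices

* **Otsu** — exhaustive maximization of between-class variance over the 256
  levels, classes {≤ t} vs {> t}, smallest maximizing t returned; a constant
  image yields threshold 0 and an empty mask with a warning.
* **Connectivity** — 8-connected foreground, 4-connected background (the
  complementary pair), everywhere.
* **Component ties** — equal-area components break toward the one containing
  the smallest raster-order pixel.
* **Segment selection ties** — equal distances break toward the longer
  segment (more midline evidence), then lexicographic endpoint order.
* **Rounding** — pixel outputs round half away from zero; the overall error
  `e` is the rounded Euclidean norm of the component errors.
* **Hue convention** — internal hue in [0, 1), quantized to 0–255 for
  channel images; the fold `255 − 2·min(h, 256−h)` makes the circular red
  band contiguous and bright so a `> t` mask can select it.
* **Cross-entropy clamping** — predicted probabilities clamp to
  [1e−7, 1−1e−7], so the loss is finite everywhere and zero only at
  clamped-perfect prediction.
* **Anchor k-means** — distance 1 − IoU of corner-aligned boxes, per-cluster
  median update, empty clusters re-seeded from the farthest box. The median
  update does not guarantee a monotone objective, so each run tracks it and
  reverts to the best centroids if it ever rises; 10 seeded k-means++-style
  restarts are run and the best objective kept, which removes the occasional
  bad-init collapse a single run exhibits.
* **Hough determinism** — the probabilistic line transform is given a fixed
  internal seed (configurable), making every CLI command deterministic given
  (inputs, config, seed).

## Design decisions that were genuinely open

* The axis pipeline's inversion-vs-threshold order is unspecified in the
  procedure this implements; inverting first and taking the dark side of the
  inverted image was fixed as the convention.
* The detection-loss scale factor uses the product form (2 − w·h) with
  normalized box dimensions, the standard small-box up-weighting; weights
  default to λ_cobox = 5, λ_obj = 1, λ_noobj = 0.5, λ_class = 1.
* AP uses all-points interpolation with greedy score-ordered one-to-one
  matching at IoU ≥ 0.5; undefined metrics (no truths, no predicted
  positives) return NaN with a warning rather than raising, and MCC returns
  0 when a denominator factor vanishes.
* The end-to-end experiment and the acceptance script use 30 scenes per
  lighting condition with tilt uniform in [0°, 25°] and the standard noise
  regime (20 specks, 10 holes); unit tests use single fixed-seed scenes.
  These sizes keep the whole suite under half a minute while leaving the
  success-rate estimate a resolution of ~3 percentage points.

## Known limitations

* The centerline tilt is a biased estimator for wide buds (see above).
* The axis must be the dominant component of the V − H candidate mask above
  the bud; a bright, low-hue structure touching the axis can still merge
  into it and shift the detected midline.
* The fallback cutting point assumes the axis continues the bud centerline,
  which is exactly the situation (δ ≠ 0, curved junction) where the
  segment-based estimate was preferred in the first place; it is a
  last-resort output and flagged as such.
* Only single-bud scenes are supported; no 3D or depth reasoning is
  attempted.
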