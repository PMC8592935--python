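# budcut

Cutting-point localization for banana flower buds.

In banana cultivation the terminal flower bud (the "bell") must be cut off
the inflorescence axis — the slender stalk connecting bud and fruit bunch —
at mid fruit development. A bud-cutting robot needs the pixel location of
that cut. `budcut` implements the classical-vision half of that problem:
given an RGB region containing a bud and its axis, it segments both organs,
derives the bud's centerline geometry, and returns the cutting point on the
axis, together with the evaluation mathematics used to score such a system
and the detector-side utilities (anchor clustering, multi-part loss) that
accompany a one-stage detector front end.

It is aimed at agricultural-robotics and plant-phenotyping researchers who
want a dependency-light, fully testable reference pipeline. Because no public
image set exists for this task, the package ships a seedable synthetic-scene
generator with exact ground truth; every stage is validated against it.

## Method

1. **Bud mask** — the bud's hue sits in the wrap-around red/magenta band.
   The hue axis is folded (`255 − 2·min(h, 256−h)`) so redness becomes one
   bright score, then Otsu's threshold, an opening/closing morphology filter
   and largest-connected-component extraction give the bud mask.
2. **Centerline** — the mask is split at the mid-height of its bounding box;
   each half's first-moment centroid

   `x_c = Σ x·f(x,y) / Σ f(x,y)`, `y_c = Σ y·f(x,y) / Σ f(x,y)`

   is computed, and the line through the two centroids is the bud centerline
   with tilt δ = arctan(|Δx|/|Δy|) from vertical.
3. **Axis mask** — V and H channels are histogram-equalized, their clipped
   difference is phase-inverted and thresholded by Otsu; small contours are
   flipped, a closing smooths the strip, and the component with the largest
   area ratio inside the working rectangle above the bud is kept.
4. **Cutting point** — line segments are detected on the axis mask's edge map
   (probabilistic Hough transform), collinear fragments merged and opposite
   strip boundaries paired into midlines. For each candidate segment with
   endpoints (x₁,y₁), (x₂,y₂) the perpendicular distance to the bud centroid

   `S = |(x_c−x₁)(y₂−y₁) − (y_c−y₁)(x₂−x₁)| / √((y₂−y₁)² + (x₂−x₁)²)`

   is evaluated; the segment minimizing S is the axis line, and its midpoint
   is the cutting point Q.

Positioning quality is reported as component errors `e_x = |X−x|`,
`e_y = |Y−y|` against a reference point, their rounded Euclidean norm `e`,
and the percentage of images with `e` below 15 px. Detection quality uses
precision, recall, F1, MCC and average precision (area under the
all-points-interpolated PR curve with greedy IoU matching).

## Worked example

```python
from budcut import SceneParams, generate_scene, locate_cutting_point, positioning_error

params = SceneParams(tilt_delta=18.0, noise_speck_count=20,
                     noise_hole_count=10, seed=7)
truth = generate_scene(params)
res = locate_cutting_point(truth.image)
print("true cut     :", (truth.true_cut_point.x, truth.true_cut_point.y))
print("computed cut :", (res.cut_point.x, res.cut_point.y))
print("delta (deg)  :", round(res.centerline_angle_delta, 2))
err = positioning_error(truth.true_cut_point, res.cut_point)
print("e_x, e_y, e  :", (err.e_x, err.e_y, err.e))
```

prints

```
true cut     : (192, 90)
computed cut : (194, 87)
delta (deg)  : 16.81
e_x, e_y, e  : (2, 3, 4)
```

i.e. on a back-leaning scene tilted 18° with the standard speck/hole noise,
the computed cutting point lands 4 px from the true midpoint of the axis and
the centerline tilt is recovered within 1.2°, well inside the 15-px working
tolerance of the cutting actuator.

The same pipeline is scriptable from the shell:

```sh
budcut generate --n 30 --lighting front --tilt-range 0:25 --seed 42 --out scenes/
budcut locate scenes/scene_front_0000.png --out result.json
budcut demo --seed 1          # full generate → locate → evaluate experiment
budcut anchors boxes.json --k 9 --seed 7 --out anchors.json
```

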