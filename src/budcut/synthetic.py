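"""Seedable synthetic scenes of a banana bell hanging from its inflorescence axis.

A scene is a leafy green background, a slender bright greenish axis strip at a
tilt δ from vertical, and a dark magenta, bilaterally symmetric bud (rendered
as a superellipse) hanging from the axis. Lighting is either front (full
value gain) or back (global value gain 0.55 with raised background
brightness, which degrades the axis/background contrast). Speck and hole
noise perturb the rendered image but not the ground-truth masks.

The generator is the test bed for every downstream stage: each scene carries
its clean bud/axis masks, the axis midline endpoints and the true cutting
point (the midpoint of the rendered axis midline), all reproducible
bit-for-bit from the stored parameters and seed.

Color-band choices are made for separability, not photographic fidelity: the
bud hue sits in the wrap-around red/magenta band and the axis hue sits just
below the background-hue bulk, so the hue-fold bud pipeline and the
equalized V − H axis pipeline are both realizable by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.color import hsv2rgb

from .evaluation import DetectionSet
from .geometry import PixelPoint
from .yolo import Box

__all__ = [
    "SceneParams",
    "SceneTruth",
    "ParameterError",
    "generate_scene",
    "generate_box_set",
    "generate_detection_fixture",
    "superellipse_area",
    "BUD_SHAPE_EXPONENT",
]

#: silhouette exponent of the bud superellipse; together with the default
#: width/length ratio (~0.28) it keeps the half-centroid centerline bias
#: below ~1.7 degrees over tilts up to 25 degrees
BUD_SHAPE_EXPONENT = 3.0

_BUD_HUE = 0.93  # 8-bit ≈ 237, wrap-around magenta band
_AXIS_HUE = 0.27  # just below the background hue bulk
_BASE_HUE = 0.30
_LEAF_HUE_RANGE = (0.31, 0.38)
_BACK_GAIN = 0.55
_BACK_BG_LIFT = 0.30


class ParameterError(ValueError):
    """Scene parameters violate an invariant or the geometry leaves the frame."""


@dataclass(frozen=True)
class SceneParams:
    """Everything needed to re-render a scene deterministically."""

    image_width: int = 320
    image_height: int = 320
    bud_center: tuple[float, float] = (160.0, 190.0)  # (x, y)
    bud_length: float = 120.0
    bud_max_width: float = 34.0
    axis_length: float = 90.0
    axis_width: float = 9.0
    tilt_delta: float = 0.0  # degrees from vertical
    lighting: str = "front"  # "front" | "back"
    noise_speck_count: int = 0
    noise_hole_count: int = 0
    leaf_clutter: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if not (self.bud_length > self.bud_max_width > 0):
            raise ParameterError("need bud_length > bud_max_width > 0")
        if not (0 <= self.tilt_delta < 90):
            raise ParameterError("tilt_delta must lie in [0, 90)")
        if not (0 < self.axis_width < self.bud_max_width):
            raise ParameterError("axis_width must be in (0, bud_max_width)")
        if self.lighting not in ("front", "back"):
            raise ParameterError(f"unknown lighting {self.lighting!r}")
        if not (0.0 <= self.leaf_clutter <= 1.0):
            raise ParameterError("leaf_clutter must lie in [0, 1]")
        if min(self.noise_speck_count, self.noise_hole_count) < 0:
            raise ParameterError("noise counts must be >= 0")
        d = math.radians(self.tilt_delta)
        ux, uy = math.sin(d), -math.cos(d)
        cx, cy = self.bud_center
        half = self.bud_length / 2.0
        extremes = [
            (cx + ux * half, cy + uy * half),
            (cx - ux * half, cy - uy * half),
            (
                cx + ux * (half + self.axis_length),
                cy + uy * (half + self.axis_length),
            ),
        ]
        margin = self.bud_max_width / 2.0 + 1
        for x, y in extremes:
            if not (
                margin <= x <= self.image_width - 1 - margin
                and 0 <= y <= self.image_height - 1
            ):
                raise ParameterError("scene geometry does not fit inside the frame")

    def axis_direction(self) -> tuple[float, float]:
        """Unit vector from the bud toward the axis ("up", tilted by δ)."""
        d = math.radians(self.tilt_delta)
        return math.sin(d), -math.cos(d)

    def bud_apex(self) -> tuple[float, float]:
        ux, uy = self.axis_direction()
        return (
            self.bud_center[0] + ux * self.bud_length / 2.0,
            self.bud_center[1] + uy * self.bud_length / 2.0,
        )

    def axis_endpoints(self) -> tuple[tuple[float, float], tuple[float, float]]:
        ux, uy = self.axis_direction()
        p0 = self.bud_apex()
        return p0, (p0[0] + ux * self.axis_length, p0[1] + uy * self.axis_length)

    def true_cut_xy(self) -> tuple[float, float]:
        """Analytic midpoint of the axis midline (before pixel rounding)."""
        (x0, y0), (x1, y1) = self.axis_endpoints()
        return (x0 + x1) / 2.0, (y0 + y1) / 2.0


@dataclass
class SceneTruth:
    """A rendered scene plus its ground truth."""

    image: np.ndarray  # H×W×3 uint8
    bud_mask: np.ndarray  # H×W uint8 {0,1}
    axis_mask: np.ndarray
    true_cut_point: PixelPoint
    centerline_endpoints: tuple[PixelPoint, PixelPoint]
    params: SceneParams


def superellipse_area(length: float, width: float, n: float = BUD_SHAPE_EXPONENT) -> float:
    """Analytic area of the bud silhouette |u/a|^n + |v/b|^n <= 1."""
    from scipy.special import gamma

    a, b = length / 2.0, width / 2.0
    return 4.0 * a * b * gamma(1 + 1 / n) ** 2 / gamma(1 + 2 / n)


def _coordinate_frames(params: SceneParams):
    yy, xx = np.mgrid[0 : params.image_height, 0 : params.image_width].astype(float)
    return xx, yy


def _bud_mask(params: SceneParams, xx, yy) -> np.ndarray:
    ux, uy = params.axis_direction()
    vx, vy = -uy, ux  # perpendicular
    cx, cy = params.bud_center
    a = params.bud_length / 2.0
    b = params.bud_max_width / 2.0
    u = (xx - cx) * ux + (yy - cy) * uy
    v = (xx - cx) * vx + (yy - cy) * vy
    n = BUD_SHAPE_EXPONENT
    return (np.abs(u / a) ** n + np.abs(v / b) ** n) <= 1.0


def _axis_mask(params: SceneParams, xx, yy, bud: np.ndarray) -> np.ndarray:
    (x0, y0), (x1, y1) = params.axis_endpoints()
    dx, dy = x1 - x0, y1 - y0
    t = np.clip(((xx - x0) * dx + (yy - y0) * dy) / (dx * dx + dy * dy), 0.0, 1.0)
    dist = np.hypot(xx - (x0 + t * dx), yy - (y0 + t * dy))
    return (dist <= params.axis_width / 2.0) & ~bud


def generate_scene(params: SceneParams) -> SceneTruth:
    """Render a scene and its ground truth, deterministically per seed."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    xx, yy = _coordinate_frames(params)
    bud = _bud_mask(params, xx, yy)
    axis = _axis_mask(params, xx, yy, bud)

    # per-pixel noise lives in V (lighting); hue is piecewise constant per region
    h = np.full(bud.shape, _BASE_HUE)
    s = np.full(bud.shape, 0.60)
    v = np.full(bud.shape, 0.35) + rng.uniform(-0.02, 0.02, bud.shape)

    # leafy clutter: random ellipses in the green band, dimmer than the axis;
    # per-leaf brightness and hue share one draw (brighter leaves sit higher
    # in the green band) so V and H ranks move together over the clutter
    n_leaves = int(round(params.leaf_clutter * 25))
    for _ in range(n_leaves):
        lx = rng.uniform(0, params.image_width)
        ly = rng.uniform(0, params.image_height)
        rx = rng.uniform(8, 30)
        ry = rng.uniform(8, 30)
        ang = rng.uniform(0, math.pi)
        ca, sa = math.cos(ang), math.sin(ang)
        u = (xx - lx) * ca + (yy - ly) * sa
        w = -(xx - lx) * sa + (yy - ly) * ca
        blob = (u / rx) ** 2 + (w / ry) ** 2 <= 1.0
        shade = rng.uniform()
        lo, hi = _LEAF_HUE_RANGE
        h[blob] = lo + (hi - lo) * shade
        s[blob] = rng.uniform(0.5, 0.9)
        v[blob] = 0.40 + 0.15 * shade

    h[axis] = _AXIS_HUE + rng.uniform(-0.004, 0.004)
    s[axis] = 0.55
    v[axis] = 0.92

    h[bud] = _BUD_HUE + rng.uniform(-0.01, 0.01)
    s[bud] = 0.85
    v[bud] = 0.60

    if params.lighting == "back":
        v = v * _BACK_GAIN
        background = ~(bud | axis)
        v[background] = np.clip(v[background] + _BACK_BG_LIFT, 0, 1)

    # speck noise: tiny bud-colored blocks outside the bud
    for _ in range(params.noise_speck_count):
        bw, bh = int(rng.integers(1, 3)), int(rng.integers(1, 3))  # area 1–4 px
        for _attempt in range(50):
            x = int(rng.integers(0, params.image_width - bw))
            y = int(rng.integers(0, params.image_height - bh))
            if not bud[y : y + bh, x : x + bw].any():
                h[y : y + bh, x : x + bw] = _BUD_HUE
                s[y : y + bh, x : x + bw] = 0.85
                v[y : y + bh, x : x + bw] = 0.60
                break

    # hole noise: tiny background-colored blocks strictly inside the bud
    # (away from the silhouette boundary, so they are true interior holes)
    from scipy.ndimage import binary_erosion

    interior = binary_erosion(bud, iterations=4)
    for _ in range(params.noise_hole_count):
        bw, bh = int(rng.integers(1, 4)), int(rng.integers(1, 3))  # area 1–6 px
        for _attempt in range(50):
            x = int(rng.integers(0, params.image_width - bw))
            y = int(rng.integers(0, params.image_height - bh))
            if interior[y : y + bh, x : x + bw].all():
                h[y : y + bh, x : x + bw] = _BASE_HUE
                s[y : y + bh, x : x + bw] = 0.60
                v[y : y + bh, x : x + bw] = 0.35
                break

    hsv = np.stack([h % 1.0, np.clip(s, 0, 1), np.clip(v, 0, 1)], axis=-1)
    image = np.round(hsv2rgb(hsv) * 255.0).astype(np.uint8)

    cut = PixelPoint(*params.true_cut_xy()).rounded()
    p0, p1 = params.axis_endpoints()
    return SceneTruth(
        image=image,
        bud_mask=bud.astype(np.uint8),
        axis_mask=axis.astype(np.uint8),
        true_cut_point=cut,
        centerline_endpoints=(
            PixelPoint(*p0).rounded(),
            PixelPoint(*p1).rounded(),
        ),
        params=params,
    )


def generate_box_set(
    n: int, cluster_spec: list[tuple[float, float, float]], seed: int = 0
) -> list[Box]:
    """``n`` (w, h) boxes sampled around cluster centers (w, h, spread).

    Boxes cycle through the clusters; dimensions are Gaussian around the
    center with the given spread, clamped to 1 px.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if any(spread < 0 for _, _, spread in cluster_spec):
        raise ValueError("spreads must be >= 0")
    rng = np.random.default_rng(seed)
    boxes = []
    for i in range(n):
        w0, h0, spread = cluster_spec[i % len(cluster_spec)]
        w = max(1.0, w0 + (rng.normal(0, spread) if spread > 0 else 0.0))
        hh = max(1.0, h0 + (rng.normal(0, spread) if spread > 0 else 0.0))
        boxes.append(Box(w=w, h=hh))
    return boxes


def generate_detection_fixture(
    n_true: int, n_false: int, score_seed: int = 0
) -> tuple[DetectionSet, list[Box]]:
    """A detection set with a known match structure.

    ``n_true`` ground-truth boxes on a disjoint grid, each copied as a
    correct prediction (IoU 1 with its truth); ``n_false`` additional
    predictions placed far from every truth (IoU 0). Scores are random but
    deterministic per seed.
    """
    if n_true + n_false < 1:
        raise ValueError("need at least one box")
    rng = np.random.default_rng(score_seed)
    truths = [
        Box(w=20, h=30, x=60.0 + 100.0 * i, y=60.0, label="bud") for i in range(n_true)
    ]
    preds: list[tuple[Box, float]] = []
    for t in truths:
        preds.append((t, float(rng.uniform(0.5, 1.0))))
    for j in range(n_false):
        preds.append(
            (
                Box(w=20, h=30, x=60.0 + 100.0 * j, y=300.0, label="bud"),
                float(rng.uniform(0.0, 1.0)),
            )
        )
    return DetectionSet(predictions=preds, truths=list(truths)), list(truths)
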