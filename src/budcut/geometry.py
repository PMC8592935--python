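"""Centroid, centerline, axis-line and cutting-point geometry.

The bud's binary mask is split at the mid-height of its bounding box; the
first-moment centroids of the two halves define the bud centerline and its
tilt δ from vertical. Line segments are detected on the edge map of the
axis mask with a probabilistic Hough transform, collinear fragments are
merged and opposite strip boundaries are paired into midline segments. The
segment minimizing the perpendicular point-to-line distance from the bud
centroid is selected, and its midpoint is the cutting point.

Coordinates are 0-based with x = column, y = row, origin at the top-left.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPoint

from .segmentation import SegmentationConfig, segment_axis, segment_bud

logger = logging.getLogger(__name__)

__all__ = [
    "PixelPoint",
    "CentroidPair",
    "LineSegment",
    "CutPointResult",
    "GeometryConfig",
    "EmptyRegionError",
    "NoBudError",
    "NoAxisError",
    "region_centroid",
    "split_upper_lower",
    "bud_centerline",
    "detect_axis_segments",
    "line_value",
    "point_segment_distance",
    "select_axis_segment",
    "cutting_point",
    "locate_cutting_point",
]


class EmptyRegionError(ValueError):
    """A mask without foreground where foreground is required."""


class NoBudError(EmptyRegionError):
    """No bud region could be segmented from the image."""


class NoAxisError(EmptyRegionError):
    """No axis line segment is available for cutting-point selection."""


@dataclass(frozen=True)
class PixelPoint:
    """A point in pixel coordinates, x = column, y = row, 0-based."""

    x: float
    y: float

    def rounded(self) -> "PixelPoint":
        return PixelPoint(_round_half_away(self.x), _round_half_away(self.y))

    def to_dict(self) -> dict:
        return {"x": self.x, "y": self.y}


@dataclass(frozen=True)
class CentroidPair:
    """Centroids of the upper and lower halves of the bud mask."""

    upper: PixelPoint
    lower: PixelPoint

    def __post_init__(self) -> None:
        if self.upper.y > self.lower.y:
            raise ValueError("upper centroid must not lie below the lower one")


@dataclass(frozen=True)
class LineSegment:
    p1: PixelPoint
    p2: PixelPoint

    def __post_init__(self) -> None:
        if self.length == 0:
            raise ValueError("degenerate zero-length segment")

    @property
    def length(self) -> float:
        return math.hypot(self.p2.x - self.p1.x, self.p2.y - self.p1.y)

    def to_dict(self) -> dict:
        return {"p1": self.p1.to_dict(), "p2": self.p2.to_dict(), "length": self.length}


@dataclass
class GeometryConfig:
    """Parameters of segment detection and selection."""

    hough_threshold: int = 10
    hough_line_gap: int = 10
    hough_seed: int = 0  # fixed; makes the probabilistic transform reproducible
    min_length_frac: float = 0.3  # of the axis-mask bounding-box height
    merge_angle_tol: float = 5.0  # degrees, collinear merge
    merge_dist_tol: float = 5.0  # px, collinear merge
    pair_max_separation: float = 18.0  # px, opposite-boundary pairing into a midline


@dataclass
class CutPointResult:
    """Everything the cutting-point pipeline derives from one image."""

    centroids: CentroidPair
    bud_centroid: PixelPoint
    centerline_angle_delta: float  # degrees from vertical
    bounding_rect: list[tuple[float, float]]  # 4 corners of the min-area rectangle
    selected_segment: LineSegment | None
    distance_s: float  # min point-to-line distance (NaN on fallback)
    cut_point: PixelPoint
    axis_height: float  # vertical extent of the selected segment (H_t)
    cut_distance: float  # distance from the cut point to the bud top point (H_Q)
    fallback: bool = False

    def to_dict(self) -> dict:
        return {
            "centroids": {
                "upper": self.centroids.upper.to_dict(),
                "lower": self.centroids.lower.to_dict(),
            },
            "bud_centroid": self.bud_centroid.to_dict(),
            "centerline_angle_delta": self.centerline_angle_delta,
            "bounding_rect": [list(c) for c in self.bounding_rect],
            "selected_segment": (
                self.selected_segment.to_dict() if self.selected_segment else None
            ),
            "distance_s": self.distance_s,
            "cut_point": self.cut_point.to_dict(),
            "axis_height": self.axis_height,
            "cut_distance": self.cut_distance,
            "fallback": self.fallback,
        }


def _round_half_away(v: float) -> int:
    return int(math.copysign(math.floor(abs(v) + 0.5), v))


def region_centroid(mask: np.ndarray) -> PixelPoint:
    """First-moment centroid of the foreground: Σx·f / Σf, Σy·f / Σf."""
    m = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(m)
    if len(xs) == 0:
        raise EmptyRegionError("cannot take the centroid of an empty region")
    return PixelPoint(float(xs.mean()), float(ys.mean()))


def split_upper_lower(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a mask at the mid-height row of its bounding box.

    The midpoint row goes to the upper part; the outputs partition the input.
    """
    m = np.asarray(mask, dtype=bool)
    ys, _ = np.nonzero(m)
    if len(ys) == 0:
        raise EmptyRegionError("cannot split an empty mask")
    rmin, rmax = int(ys.min()), int(ys.max())
    if rmin == rmax:
        logger.warning("split_upper_lower: single-row mask, lower part empty")
    mid = (rmin + rmax) // 2
    upper = m.copy()
    upper[mid + 1 :] = False
    lower = m & ~upper
    return upper.astype(np.uint8), lower.astype(np.uint8)


def bud_centerline(mask: np.ndarray) -> tuple[CentroidPair, float]:
    """Upper/lower half centroids and the centerline tilt δ (degrees).

    δ = arctan(|Δx| / |Δy|) between the two centroids; 0 when Δx = 0, 90 when
    the centroids share a row.
    """
    upper, lower = split_upper_lower(mask)
    if upper.sum() == 0 or lower.sum() == 0:
        raise EmptyRegionError("bud_centerline: one half of the mask is empty")
    cu = region_centroid(upper)
    cl = region_centroid(lower)
    dx, dy = abs(cl.x - cu.x), abs(cl.y - cu.y)
    delta = 0.0 if dx == 0 else math.degrees(math.atan2(dx, dy))
    return CentroidPair(upper=cu, lower=cl), delta


def line_value(segment: LineSegment, p: PixelPoint) -> float:
    """(x−x1)(y2−y1) − (y−y1)(x2−x1); zero iff p lies on the infinite line."""
    return (p.x - segment.p1.x) * (segment.p2.y - segment.p1.y) - (
        p.y - segment.p1.y
    ) * (segment.p2.x - segment.p1.x)


def point_segment_distance(c: PixelPoint, segment: LineSegment) -> float:
    """Perpendicular distance |line_value| / segment length."""
    return abs(line_value(segment, c)) / segment.length


def _normalize(seg: LineSegment) -> LineSegment:
    if (seg.p1.y, seg.p1.x) > (seg.p2.y, seg.p2.x):
        return LineSegment(seg.p2, seg.p1)
    return seg


def _sort_key(seg: LineSegment):
    return (seg.p1.y, seg.p1.x, seg.p2.y, seg.p2.x)


def _angle_deg(seg: LineSegment) -> float:
    """Orientation in [0, 180)."""
    a = math.degrees(math.atan2(seg.p2.y - seg.p1.y, seg.p2.x - seg.p1.x)) % 180.0
    return a


def _angle_diff(a: float, b: float) -> float:
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def _merge_group(group: list[LineSegment]) -> LineSegment:
    """Length-weighted mean line through a group; extent = extreme projections."""
    wsum = sum(s.length for s in group)
    cx = sum(s.length * (s.p1.x + s.p2.x) / 2 for s in group) / wsum
    cy = sum(s.length * (s.p1.y + s.p2.y) / 2 for s in group) / wsum
    # mean direction on the doubled-angle circle (orientation is mod 180°)
    sx = sum(s.length * math.cos(2 * math.radians(_angle_deg(s))) for s in group)
    sy = sum(s.length * math.sin(2 * math.radians(_angle_deg(s))) for s in group)
    theta = math.atan2(sy, sx) / 2.0
    ux, uy = math.cos(theta), math.sin(theta)
    ts = []
    for s in group:
        for p in (s.p1, s.p2):
            ts.append((p.x - cx) * ux + (p.y - cy) * uy)
    t0, t1 = min(ts), max(ts)
    return _normalize(
        LineSegment(
            PixelPoint(cx + t0 * ux, cy + t0 * uy), PixelPoint(cx + t1 * ux, cy + t1 * uy)
        )
    )


def _merge_pass(
    segments: list[LineSegment], angle_tol: float, dist_tol: float
) -> list[LineSegment]:
    """Greedily absorb segments that are near-parallel and near-collinear."""
    remaining = sorted(segments, key=lambda s: -s.length)
    out: list[LineSegment] = []
    while remaining:
        seed = remaining.pop(0)
        group = [seed]
        keep: list[LineSegment] = []
        for s in remaining:
            mid = PixelPoint((s.p1.x + s.p2.x) / 2, (s.p1.y + s.p2.y) / 2)
            if (
                _angle_diff(_angle_deg(seed), _angle_deg(s)) <= angle_tol
                and point_segment_distance(mid, seed) <= dist_tol
            ):
                group.append(s)
            else:
                keep.append(s)
        out.append(_merge_group(group) if len(group) > 1 else _normalize(seed))
        remaining = keep
    return out


def detect_axis_segments(
    axis_mask: np.ndarray, config: GeometryConfig | None = None
) -> list[LineSegment]:
    """Line segments of the axis strip, as midline candidates.

    Probabilistic Hough transform on the mask's boundary edge map, followed by
    a collinear merge and a pairing of opposite strip boundaries into their
    midline. Segments shorter than ``min_length_frac`` × the mask bounding-box
    height are dropped. The returned list is deterministically ordered by
    (p1.y, p1.x, p2.y, p2.x).
    """
    from skimage.transform import probabilistic_hough_line

    cfg = config or GeometryConfig()
    m = np.asarray(axis_mask, dtype=bool)
    ys, _ = np.nonzero(m)
    if len(ys) == 0:
        return []
    bbox_h = int(ys.max() - ys.min()) + 1
    min_len = max(5, int(round(cfg.min_length_frac * bbox_h)))
    edges = m & ~ndimage.binary_erosion(m, structure=np.ones((3, 3), dtype=bool))
    raw = probabilistic_hough_line(
        edges,
        threshold=cfg.hough_threshold,
        line_length=min_len,
        line_gap=cfg.hough_line_gap,
        rng=np.random.default_rng(cfg.hough_seed),
    )
    segments = [
        _normalize(LineSegment(PixelPoint(*p1), PixelPoint(*p2)))
        for p1, p2 in raw
        if p1 != p2
    ]
    if not segments:
        return []
    segments = _merge_pass(segments, cfg.merge_angle_tol, cfg.merge_dist_tol)
    segments = _merge_pass(segments, cfg.merge_angle_tol, cfg.pair_max_separation)
    segments = [s for s in segments if s.length >= min_len]
    return sorted(segments, key=_sort_key)


def select_axis_segment(
    segments: list[LineSegment], centroid: PixelPoint
) -> tuple[LineSegment, float]:
    """The segment minimizing the point-to-line distance to the centroid.

    Ties break toward the longer segment, then toward the deterministic
    (p1.y, p1.x, p2.y, p2.x) ordering.
    """
    if not segments:
        raise NoAxisError("no axis segments to select from")
    best = min(
        segments,
        key=lambda s: (point_segment_distance(centroid, s), -s.length, _sort_key(s)),
    )
    return best, point_segment_distance(centroid, best)


def cutting_point(segment: LineSegment) -> PixelPoint:
    """Midpoint of the segment, rounded half away from zero to integer pixels."""
    return PixelPoint(
        (segment.p1.x + segment.p2.x) / 2.0, (segment.p1.y + segment.p2.y) / 2.0
    ).rounded()


def _min_area_rect(mask: np.ndarray) -> list[tuple[float, float]]:
    ys, xs = np.nonzero(np.asarray(mask, dtype=bool))
    pts = MultiPoint(list(zip(xs.tolist(), ys.tolist())))
    rect = pts.minimum_rotated_rectangle
    coords = list(rect.exterior.coords)[:4] if rect.geom_type == "Polygon" else []
    if not coords:  # degenerate (collinear) region
        coords = [(float(xs.min()), float(ys.min())), (float(xs.max()), float(ys.max()))] * 2
    return [(float(x), float(y)) for x, y in coords]


def _rect_top_edge(rect: list[tuple[float, float]]):
    """The rectangle edge whose midpoint has the smallest y."""
    n = len(rect)
    edges = [(rect[i], rect[(i + 1) % n]) for i in range(n)]
    return min(edges, key=lambda e: (e[0][1] + e[1][1]) / 2.0)


def _centerline_top_intersection(
    pair: CentroidPair, rect: list[tuple[float, float]]
) -> PixelPoint:
    """Intersect the (infinite) bud centerline with the rectangle's top edge line."""
    (ax, ay), (bx, by) = _rect_top_edge(rect)
    px, py = pair.upper.x, pair.upper.y
    dx, dy = pair.lower.x - pair.upper.x, pair.lower.y - pair.upper.y
    ex, ey = bx - ax, by - ay
    denom = dx * ey - dy * ex
    if denom == 0 or (dx == 0 and dy == 0):
        return PixelPoint(px, ay)  # parallel/degenerate: drop onto the top edge level
    t = ((ax - px) * ey - (ay - py) * ex) / denom
    return PixelPoint(px + t * dx, py + t * dy)


def locate_cutting_point(
    image: np.ndarray,
    seg_config: SegmentationConfig | None = None,
    geo_config: GeometryConfig | None = None,
) -> CutPointResult:
    """Full pipeline: bud mask → centerline → axis mask → segments → cut point.

    Raises :class:`NoBudError` when no bud can be segmented. When no axis
    segment is found the cut point falls back to the intersection of the bud
    centerline with the top edge of the bud's minimum bounding rectangle and
    the result is flagged ``fallback=True``.
    """
    seg_cfg = seg_config or SegmentationConfig()
    geo_cfg = geo_config or GeometryConfig()

    bud = segment_bud(image, seg_cfg)
    if bud.sum() == 0:
        raise NoBudError("no bud region found in the image")
    pair, delta = bud_centerline(bud)
    centroid = region_centroid(bud)
    rect = _min_area_rect(bud)

    ys, xs = np.nonzero(bud.astype(bool))
    top_row = int(ys.min())
    top_xs = xs[ys == top_row]
    bud_top = PixelPoint(float(top_xs.min()), float(top_row))  # highest bud edge point

    # working rectangle: everything above the bud (the axis hangs the bud)
    h_img, w_img = bud.shape[:2]
    roi = (0, 0, w_img, min(top_row + 5, h_img))
    axis = segment_axis(image, seg_cfg, roi=roi)
    segments = detect_axis_segments(axis, geo_cfg)

    if segments:
        seg, dist = select_axis_segment(segments, centroid)
        cut = cutting_point(seg)
        axis_height = abs(seg.p2.y - seg.p1.y)
        fallback = False
    else:
        logger.info("locate_cutting_point: no axis segment, centerline fallback")
        seg, dist = None, float("nan")
        cut = _centerline_top_intersection(pair, rect).rounded()
        axis_height = float("nan")
        fallback = True

    return CutPointResult(
        centroids=pair,
        bud_centroid=centroid,
        centerline_angle_delta=delta,
        bounding_rect=rect,
        selected_segment=seg,
        distance_s=dist,
        cut_point=cut,
        axis_height=axis_height,
        cut_distance=math.hypot(cut.x - bud_top.x, cut.y - bud_top.y),
        fallback=fallback,
    )
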