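"""Binary-mask extraction of the flower bud and the inflorescence axis.

The bud is separated on the hue channel: banana bells sit in the wrap-around
red/magenta hue band, while leaves, stems and background are green. The hue
axis is folded so that proximity to red becomes a single bright score, then
Otsu's threshold, an opening/closing morphology filter and largest-component
extraction produce the bud mask.

The axis is separated on brightness: both V and H channels are histogram
equalized, their clipped difference is phase-inverted, Otsu's threshold
splits off the axis (dark side of the inverted image), small contours and
holes are flipped, and a closing plus largest-area-ratio component selection
yields the axis mask. The slender greenish axis is bright in V and sits below
the background hue bulk, which is what the V − H difference exploits.

Masks are uint8 arrays with values {0, 1}, 1 = foreground.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.exposure import equalize_hist
from skimage.morphology import closing, disk, opening

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationConfig",
    "split_hsv",
    "otsu_threshold",
    "morphology_filter",
    "max_connected_region",
    "remove_small_contours",
    "segment_bud",
    "segment_axis",
]

# 8-connectivity for foreground components, complementary 4-connectivity for
# the background when hunting enclosed holes
_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)


@dataclass
class SegmentationConfig:
    """Tunable parameters of the two mask pipelines."""

    open_radius: int = 2  # disk radius of the opening (speck removal)
    close_radius: int = 3  # disk radius of the closing (hole filling)
    area_threshold: int = 50  # px²; smaller contours/holes are flipped
    hue_rotation: int = 0  # 8-bit rotation applied to H before the redness fold
    channel_scale: int = 255  # full-scale value of the 8-bit channel images
    min_mean_redness: int = 160  # bud gate: mean folded hue of the candidate mask


def _as_mask(arr: np.ndarray) -> np.ndarray:
    return arr.astype(np.uint8)


def split_hsv(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """RGB → (H, S, V) channel images, each scaled to 0–255 uint8."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H×W×3 RGB image")
    hsv = rgb2hsv(image)
    chans = np.round(hsv * 255.0).astype(np.uint8)
    return chans[..., 0], chans[..., 1], chans[..., 2]


def otsu_threshold(gray: np.ndarray) -> tuple[int, np.ndarray]:
    """Otsu's global threshold over all 256 candidate levels.

    Returns ``(t, mask)`` with ``mask = gray > t``; ``t`` is the smallest level
    maximizing the between-class variance. A constant image yields threshold 0
    and an empty mask (warned).
    """
    gray = np.asarray(gray, dtype=np.uint8)
    if gray.size == 0:
        raise ValueError("empty image")
    if gray.min() == gray.max():
        logger.warning("otsu_threshold: constant image, returning empty mask")
        return 0, np.zeros_like(gray, dtype=np.uint8)
    hist = np.bincount(gray.ravel(), minlength=256).astype(float)
    n = hist.sum()
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(hist)  # pixels with value <= t
    m0 = np.cumsum(hist * levels)
    w1 = n - w0
    total_mean = m0[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (total_mean - m0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[(w0 == 0) | (w1 == 0)] = -1.0  # one class empty: not a valid split
    t = int(np.argmax(sigma_b))
    return t, _as_mask(gray > t)


def morphology_filter(
    mask: np.ndarray, open_radius: int = 2, close_radius: int = 3
) -> np.ndarray:
    """Opening with a disk of ``open_radius`` then closing with ``close_radius``.

    Radius 0 skips the corresponding operation.
    """
    if open_radius < 0 or close_radius < 0:
        raise ValueError("radii must be >= 0")
    out = np.asarray(mask, dtype=bool)
    if open_radius > 0:
        out = opening(out, disk(open_radius))
    if close_radius > 0:
        out = closing(out, disk(close_radius))
    return _as_mask(out)


def max_connected_region(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component.

    Area ties break toward the component containing the smallest raster-order
    pixel. An empty mask passes through with a warning.
    """
    m = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(m, structure=_STRUCT8)
    if n == 0:
        logger.warning("max_connected_region: empty mask")
        return np.zeros_like(m, dtype=np.uint8)
    areas = np.bincount(labels.ravel())[1:]
    best_area = areas.max()
    candidates = np.flatnonzero(areas == best_area) + 1
    if len(candidates) > 1:
        flat = labels.ravel()
        first = {lab: np.flatnonzero(flat == lab)[0] for lab in candidates}
        winner = min(candidates, key=lambda lab: first[lab])
    else:
        winner = candidates[0]
    return _as_mask(labels == winner)


def remove_small_contours(mask: np.ndarray, area_threshold: int = 50) -> np.ndarray:
    """Flip foreground specks and enclosed background holes below a pixel area.

    Foreground components (8-connected) smaller than ``area_threshold`` become
    background; enclosed background components (4-connected, not touching the
    image border) smaller than the threshold become foreground.
    """
    if area_threshold < 0:
        raise ValueError("area_threshold must be >= 0")
    m = np.asarray(mask, dtype=bool)
    if area_threshold == 0:
        return _as_mask(m)
    out = m.copy()

    labels, n = ndimage.label(m, structure=_STRUCT8)
    if n:
        areas = np.bincount(labels.ravel())
        small = np.flatnonzero(areas[1:] < area_threshold) + 1
        out[np.isin(labels, small)] = False

    bg_labels, nb = ndimage.label(~m, structure=_STRUCT4)
    if nb:
        border = np.unique(
            np.concatenate(
                [bg_labels[0], bg_labels[-1], bg_labels[:, 0], bg_labels[:, -1]]
            )
        )
        areas = np.bincount(bg_labels.ravel())
        small = [
            lab
            for lab in range(1, nb + 1)
            if areas[lab] < area_threshold and lab not in border
        ]
        out[np.isin(bg_labels, small)] = True
    return _as_mask(out)


def redness(h: np.ndarray, hue_rotation: int = 0) -> np.ndarray:
    """Fold the circular 8-bit hue axis so red/magenta maps high.

    255 − 2·min(h', 256 − h') with h' = (h + rotation) mod 256: exact red → 255,
    cyan (opposite) → 0; the wrap-around red band becomes contiguous and bright.
    """
    h16 = (np.asarray(h, dtype=np.int16) + hue_rotation) % 256
    r = 255 - 2 * np.minimum(h16, 256 - h16)
    return np.clip(r, 0, 255).astype(np.uint8)


def segment_bud(
    image: np.ndarray, config: SegmentationConfig | None = None
) -> np.ndarray:
    """Bud mask: hue fold → Otsu → morphology filter → largest component.

    Returns an empty mask (with a warning) when no red/magenta region exists,
    never raises for content reasons.
    """
    cfg = config or SegmentationConfig()
    h, _, _ = split_hsv(image)
    red = redness(h, cfg.hue_rotation)
    _, mask = otsu_threshold(red)
    if mask.sum() == 0:
        logger.warning("segment_bud: empty threshold result")
        return mask
    if float(red[mask.astype(bool)].mean()) < cfg.min_mean_redness:
        # the bright class is not actually in the red band: no bud in frame
        logger.warning("segment_bud: foreground hue outside the bud band, empty mask")
        return np.zeros_like(mask)
    mask = morphology_filter(mask, cfg.open_radius, cfg.close_radius)
    return max_connected_region(mask)


def _equalize255(chan: np.ndarray) -> np.ndarray:
    return np.round(equalize_hist(chan, nbins=256) * 255.0).astype(np.int16)


def segment_axis(
    image: np.ndarray,
    config: SegmentationConfig | None = None,
    roi: tuple[int, int, int, int] | None = None,
) -> np.ndarray:
    """Axis mask from the equalized V − H difference.

    Equalize V and H, clip V_eq − H_eq at 0, phase-invert (255 − value), Otsu;
    the axis is the dark side of the inverted image. Small contours are
    flipped, a dilate-then-erode closing smooths the strip, and the connected
    component with the largest area ratio inside the working rectangle
    ``roi = (x, y, w, h)`` (whole frame when None) is kept.
    """
    cfg = config or SegmentationConfig()
    h, _, v = split_hsv(image)
    diff = np.clip(_equalize255(v) - _equalize255(h), 0, 255).astype(np.uint8)
    inv = (255 - diff).astype(np.uint8)
    if inv.min() == inv.max():
        logger.warning("segment_axis: uniform difference image, empty mask")
        return np.zeros_like(inv)
    t, high = otsu_threshold(inv)
    cand = _as_mask(~high.astype(bool))  # dark side of the inverted image
    cand = remove_small_contours(cand, cfg.area_threshold)
    cand = morphology_filter(cand, open_radius=0, close_radius=cfg.close_radius)
    labels, n = ndimage.label(cand.astype(bool), structure=_STRUCT8)
    if n == 0:
        logger.warning("segment_axis: no candidate component, empty mask")
        return np.zeros_like(cand)
    if roi is None:
        roi_mask = np.ones_like(cand, dtype=bool)
    else:
        x, y, w_, h_ = roi
        roi_mask = np.zeros_like(cand, dtype=bool)
        roi_mask[max(y, 0) : y + h_, max(x, 0) : x + w_] = True
    best, best_key = 0, (-1.0, -1.0)
    for lab in range(1, n + 1):
        comp = labels == lab
        area = int(comp.sum())
        inside = int((comp & roi_mask).sum())
        key = (inside / area, float(inside))
        if key > best_key:
            best, best_key = lab, key
    if best_key[1] == 0:
        logger.warning("segment_axis: no component inside the working rectangle")
        return np.zeros_like(cand)
    return _as_mask(labels == best)
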