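"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — explicit loops, first-principles
formulas — and shares no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np


def otsu_brute_force(gray: np.ndarray) -> int:
    """Smallest t in 0..255 maximizing between-class variance of {<=t} vs {>t}."""
    g = gray.ravel().astype(float)
    n = len(g)
    best_t, best_var = 0, -1.0
    for t in range(256):
        lo = g[g <= t]
        hi = g[g > t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        w0, w1 = len(lo) / n, len(hi) / n
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t


def centroid_brute_force(mask: np.ndarray) -> tuple[float, float]:
    """Per-pixel summation of first moments."""
    sx = sy = area = 0
    h, w = mask.shape
    for y in range(h):
        for x in range(w):
            if mask[y, x]:
                sx += x
                sy += y
                area += 1
    return sx / area, sy / area


def point_line_distance_closed_form(px, py, x1, y1, x2, y2) -> float:
    """|ax + by + c| / sqrt(a² + b²) for the line through two points."""
    a = y2 - y1
    b = -(x2 - x1)
    c = -(a * x1 + b * y1)
    return abs(a * px + b * py + c) / math.hypot(a, b)


def flood_fill_components(mask: np.ndarray, connectivity: int = 8) -> list[set]:
    """BFS connected components of the foreground as sets of (y, x)."""
    h, w = mask.shape
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for y in range(h):
        for x in range(w):
            if mask[y, x] and not seen[y, x]:
                queue = [(y, x)]
                seen[y, x] = True
                comp = set()
                while queue:
                    cy, cx = queue.pop()
                    comp.add((cy, cx))
                    for dy, dx in nbrs:
                        ny, nx = cy + dy, cx + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            queue.append((ny, nx))
                comps.append(comp)
    return comps


def remove_small_brute_force(mask: np.ndarray, area_threshold: int) -> np.ndarray:
    """Label-then-filter on foreground specks and enclosed background holes."""
    out = mask.astype(bool).copy()
    for comp in flood_fill_components(mask.astype(bool), connectivity=8):
        if len(comp) < area_threshold:
            for y, x in comp:
                out[y, x] = False
    bg = ~mask.astype(bool)
    h, w = mask.shape
    for comp in flood_fill_components(bg, connectivity=4):
        touches_border = any(y in (0, h - 1) or x in (0, w - 1) for y, x in comp)
        if not touches_border and len(comp) < area_threshold:
            for y, x in comp:
                out[y, x] = True
    return out.astype(np.uint8)


def morphology_set_oracle(mask: np.ndarray, open_r: int, close_r: int) -> np.ndarray:
    """Opening then closing by explicit set-definition erosion/dilation."""
    disk_offsets = [
        (dy, dx)
        for dy in range(-max(open_r, close_r), max(open_r, close_r) + 1)
        for dx in range(-max(open_r, close_r), max(open_r, close_r) + 1)
    ]

    def _disk(r):
        return [(dy, dx) for dy, dx in disk_offsets if math.hypot(dy, dx) <= r]

    def erode(m, offs):
        # outside the frame counts as foreground (max padding)
        h, w = m.shape
        out = np.zeros_like(m)
        for y in range(h):
            for x in range(w):
                out[y, x] = all(
                    not (0 <= y + dy < h and 0 <= x + dx < w)
                    or m[y + dy, x + dx]
                    for dy, dx in offs
                )
        return out

    def dilate(m, offs):
        h, w = m.shape
        out = np.zeros_like(m)
        ys, xs = np.nonzero(m)
        for y, x in zip(ys, xs):
            for dy, dx in offs:
                ny, nx = y + dy, x + dx
                if 0 <= ny < h and 0 <= nx < w:
                    out[ny, nx] = True
        return out

    m = mask.astype(bool)
    if open_r > 0:
        offs = _disk(open_r)
        m = dilate(erode(m, offs), offs)
    if close_r > 0:
        offs = _disk(close_r)
        m = erode(dilate(m, offs), offs)
    return m.astype(np.uint8)


def ap_cutoff_enumeration(preds, truths, iou_threshold: float = 0.5) -> float:
    """AP (%) by enumerating every score cutoff as a PR point.

    At each cutoff the kept predictions are matched greedily by descending
    score to unmatched same-label truths at the IoU threshold; the resulting
    PR points are integrated with right-side max interpolation.
    """

    def iou(a, b):
        ax0, ay0 = a.x - a.w / 2, a.y - a.h / 2
        ax1, ay1 = a.x + a.w / 2, a.y + a.h / 2
        bx0, by0 = b.x - b.w / 2, b.y - b.h / 2
        bx1, by1 = b.x + b.w / 2, b.y + b.h / 2
        iw = min(ax1, bx1) - max(ax0, bx0)
        ih = min(ay1, by1) - max(ay0, by0)
        if iw <= 0 or ih <= 0:
            return 0.0
        inter = iw * ih
        return inter / (a.w * a.h + b.w * b.h - inter)

    def pr_at(cutoff):
        kept = sorted(
            [(b, s) for b, s in preds if s >= cutoff], key=lambda t: -t[1]
        )
        used = [False] * len(truths)
        tp = 0
        for b, _ in kept:
            best, best_iou = -1, iou_threshold
            for j, t in enumerate(truths):
                if used[j] or t.label != b.label:
                    continue
                v = iou(b, t)
                if v >= best_iou:
                    best, best_iou = j, v
            if best >= 0:
                used[best] = True
                tp += 1
        if not kept:
            return None
        return tp / len(kept), tp / len(truths)

    points = []
    for cutoff in sorted({s for _, s in preds}, reverse=True):
        pr = pr_at(cutoff)
        if pr is not None:
            points.append(pr)
    # sort by recall; integrate with precision = max over points at recall >= r
    points.sort(key=lambda t: t[1])
    ap = 0.0
    prev_r = 0.0
    for i, (_, r) in enumerate(points):
        p_max = max(p for p, rr in points if rr >= r)
        ap += (r - prev_r) * p_max
        prev_r = r
    return 100.0 * ap


def lloyd_iou_kmeans(wh: np.ndarray, init: np.ndarray, max_iter: int = 300):
    """Naive Lloyd loop under 1 − IoU with median updates, from a given init.

    Mirrors the update/stop rules (stable assignment, objective-increase
    revert, farthest-box reseed) with plain per-element loops.
    """

    def iou(a, b):
        inter = min(a[0], b[0]) * min(a[1], b[1])
        return inter / (a[0] * a[1] + b[0] * b[1] - inter)

    centroids = [list(c) for c in init]
    k = len(centroids)
    prev_assign = None
    prev_obj = math.inf
    prev_centroids = [list(c) for c in centroids]
    for _ in range(max_iter):
        assign = []
        dists = []
        for box in wh:
            ds = [1.0 - iou(box, c) for c in centroids]
            j = min(range(k), key=lambda i: (ds[i], i))
            assign.append(j)
            dists.append(ds[j])
        objective = sum(dists) / len(dists)
        if objective > prev_obj:
            centroids = prev_centroids
            break
        prev_obj = objective
        prev_centroids = [list(c) for c in centroids]
        if prev_assign is not None and assign == prev_assign:
            break
        prev_assign = assign
        new_centroids = []
        for j in range(k):
            members = [wh[i] for i in range(len(wh)) if assign[i] == j]
            if not members:
                far = max(range(len(wh)), key=lambda i: dists[i])
                new_centroids.append(list(wh[far]))
            else:
                ws = sorted(m[0] for m in members)
                hs = sorted(m[1] for m in members)
                new_centroids.append([_median(ws), _median(hs)])
        centroids = new_centroids

    best = []
    for box in wh:
        best.append(min(1.0 - iou(box, c) for c in centroids))
    return centroids, sum(best) / len(best)


def _median(sorted_vals):
    n = len(sorted_vals)
    mid = n // 2
    if n % 2:
        return sorted_vals[mid]
    return (sorted_vals[mid - 1] + sorted_vals[mid]) / 2.0
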