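"""Detector-side mathematics usable without any network.

Two standalone pieces of the one-stage detector toolchain:

* anchor priors by k-means over annotated box dimensions, with the
  1 − IoU distance that is standard for anchor clustering, and
* the multi-part detection loss (squared error on box coordinates,
  binary cross-entropy on objectness confidence and class probabilities)
  with a (2 − w·h) up-weighting of small boxes.

Everything here works on plain numbers and numpy arrays; no network,
no gradients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Box",
    "AnchorSet",
    "LossWeights",
    "GridTensors",
    "LossTerms",
    "sigmoid",
    "cross_entropy",
    "modified_loss",
    "kmeans_anchors",
]

#: clamp bound for predicted probabilities inside log()
EPS = 1e-7


@dataclass(frozen=True)
class Box:
    """A bounding box; ``w``/``h`` in pixels, optional center and class label."""

    w: float
    h: float
    x: float | None = None
    y: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"box dimensions must be positive, got {self.w}x{self.h}")

    @property
    def area(self) -> float:
        return self.w * self.h


@dataclass(frozen=True)
class AnchorSet:
    """``k`` anchor (w, h) priors, sorted ascending by area."""

    anchors: tuple[tuple[float, float], ...]
    k: int

    def __post_init__(self) -> None:
        if self.k < 1 or len(self.anchors) != self.k:
            raise ValueError("anchor count must match k >= 1")
        areas = [w * h for w, h in self.anchors]
        if any(a > b for a, b in zip(areas, areas[1:])):
            raise ValueError("anchors must be sorted ascending by area")


def sigmoid(x):
    """Logistic function 1 / (1 + exp(-x)), elementwise."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def _bce_elements(target, predicted, eps: float = EPS) -> np.ndarray:
    """Elementwise binary cross-entropy with predictions clamped to [eps, 1-eps]."""
    y = np.asarray(target, dtype=float)
    a = np.clip(np.asarray(predicted, dtype=float), eps, 1.0 - eps)
    return -(y * np.log(a) + (1.0 - y) * np.log(1.0 - a))


def cross_entropy(target, predicted, eps: float = EPS) -> float:
    """Mean binary cross-entropy −1/n Σ (y·ln a + (1−y)·ln(1−a)).

    ``target`` may be hard {0,1} or soft probabilities in [0,1]; ``predicted``
    is clamped to [eps, 1−eps] before the logs so the result is always finite.
    """
    return float(np.mean(_bce_elements(target, predicted, eps)))


@dataclass(frozen=True)
class LossWeights:
    """λ weights of the loss terms.

    ``cobox`` stabilizes the coordinate loss, ``obj``/``noobj`` trade off
    positive against (far more numerous) negative cells, ``cls`` scales the
    classification term.
    """

    cobox: float = 5.0
    obj: float = 1.0
    noobj: float = 0.5
    cls: float = 1.0


@dataclass
class GridTensors:
    """Per-cell targets or predictions on an S×S×B detection grid.

    boxes are (x, y, w, h) normalized to [0, 1]; ``obj`` marks which cells/boxes
    are responsible for a real target (the I_ij indicator on the target side;
    ignored on the prediction side).
    """

    obj: np.ndarray  # (S, S, B) bool
    boxes: np.ndarray  # (S, S, B, 4) float, xywh in [0, 1]
    conf: np.ndarray  # (S, S, B) float in [0, 1]
    class_probs: np.ndarray  # (S, S, B, C) float in [0, 1]

    def __post_init__(self) -> None:
        self.obj = np.asarray(self.obj, dtype=bool)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.conf = np.asarray(self.conf, dtype=float)
        self.class_probs = np.asarray(self.class_probs, dtype=float)
        s = self.obj.shape
        if self.boxes.shape != s + (4,) or self.conf.shape != s:
            raise ValueError("grid tensor shapes are inconsistent")
        if self.class_probs.shape[:3] != s:
            raise ValueError("class_probs shape inconsistent with grid")


@dataclass(frozen=True)
class LossTerms:
    """The three loss components and their sum."""

    l_box: float
    l_obj: float
    l_cls: float
    total: float
    weights: LossWeights = field(default_factory=LossWeights)


def modified_loss(
    truth: GridTensors, pred: GridTensors, weights: LossWeights | None = None
) -> LossTerms:
    """Three-term detection loss summed over an S×S×B grid.

    * location: λ_cobox Σ_obj (2 − w·h)(A_wh + A_xy), squared errors of the
      normalized box coordinates, small true boxes weighted up by 2 − w·h > 1;
    * confidence: λ_obj Σ_obj CE + λ_noobj Σ_noobj CE of the objectness score;
    * class: λ_cls Σ_obj Σ_c CE of the per-class probabilities.
    """
    if weights is None:
        weights = LossWeights()
    if truth.obj.shape != pred.obj.shape or truth.class_probs.shape != pred.class_probs.shape:
        raise ValueError("truth and prediction grids are not congruent")

    obj = truth.obj
    noobj = ~obj

    tb, pb = truth.boxes, pred.boxes
    a_xy = (tb[..., 0] - pb[..., 0]) ** 2 + (tb[..., 1] - pb[..., 1]) ** 2
    a_wh = (tb[..., 2] - pb[..., 2]) ** 2 + (tb[..., 3] - pb[..., 3]) ** 2
    scale = 2.0 - tb[..., 2] * tb[..., 3]  # w,h in [0,1] so scale in (1, 2]
    l_box = weights.cobox * float(np.sum(scale[obj] * (a_wh + a_xy)[obj]))

    ce_conf = _bce_elements(truth.conf, pred.conf)
    l_obj = weights.obj * float(np.sum(ce_conf[obj])) + weights.noobj * float(
        np.sum(ce_conf[noobj])
    )

    ce_cls = _bce_elements(truth.class_probs, pred.class_probs)
    l_cls = weights.cls * float(np.sum(ce_cls[obj]))

    return LossTerms(
        l_box=l_box, l_obj=l_obj, l_cls=l_cls, total=l_box + l_obj + l_cls, weights=weights
    )


def _pair_iou(wh: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """IoU of corner-aligned boxes, (n, 2) vs (k, 2) -> (n, k)."""
    inter = np.minimum(wh[:, None, 0], anchors[None, :, 0]) * np.minimum(
        wh[:, None, 1], anchors[None, :, 1]
    )
    union = wh[:, 0:1] * wh[:, 1:2] + (anchors[:, 0] * anchors[:, 1])[None, :] - inter
    return inter / union


def _kmeanspp_init(wh: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded k-means++-style init under the 1 − IoU distance."""
    n = wh.shape[0]
    centroids = [wh[rng.integers(n)]]
    for _ in range(1, k):
        d = 1.0 - _pair_iou(wh, np.asarray(centroids)).max(axis=1)
        total = d.sum()
        if total <= 0:  # all boxes already coincide with a centroid
            centroids.append(wh[rng.integers(n)])
            continue
        centroids.append(wh[rng.choice(n, p=d / total)])
    return np.asarray(centroids, dtype=float)


def _lloyd_run(
    wh: np.ndarray, init: np.ndarray, max_iter: int
) -> tuple[np.ndarray, float, list[float]]:
    """One Lloyd run from a given init; returns centroids, objective, history."""
    k = len(init)
    centroids = init.copy()
    prev_assign = None
    prev_obj = np.inf
    prev_centroids = centroids
    history: list[float] = []
    for _ in range(max_iter):
        dist = 1.0 - _pair_iou(wh, centroids)
        assign = dist.argmin(axis=1)
        objective = float(dist[np.arange(len(wh)), assign].mean())
        if objective > prev_obj:  # median update is not guaranteed monotone; keep best
            centroids = prev_centroids
            break
        history.append(objective)
        prev_obj, prev_centroids = objective, centroids.copy()
        if prev_assign is not None and np.array_equal(assign, prev_assign):
            break
        prev_assign = assign
        new_centroids = centroids.copy()
        for j in range(k):
            members = wh[assign == j]
            if len(members) == 0:
                far = int(dist.min(axis=1).argmax())
                new_centroids[j] = wh[far]
                logger.info("empty anchor cluster %d re-seeded from farthest box", j)
            else:
                new_centroids[j] = np.median(members, axis=0)
        centroids = new_centroids
    dist = 1.0 - _pair_iou(wh, centroids)
    return centroids, float(dist.min(axis=1).mean()), history


def kmeans_anchors(
    boxes: list[Box],
    k: int = 9,
    seed: int = 0,
    max_iter: int = 300,
    n_init: int = 10,
    history: list[float] | None = None,
) -> tuple[AnchorSet, float]:
    """Cluster box dimensions into ``k`` anchor priors.

    Lloyd iterations under d(box, anchor) = 1 − IoU of corner-aligned boxes;
    centroids update to the per-cluster median of (w, h); each run stops when
    assignments stabilize, the objective stops improving, or after
    ``max_iter`` rounds. ``n_init`` seeded k-means++-style restarts are run
    and the best objective kept. Returns the anchors sorted by area and the
    mean best IoU over the boxes. When ``history`` is given, the winning
    run's per-iteration objective (mean 1 − best IoU) is appended to it.
    """
    if len(boxes) < k:
        raise ValueError(f"need at least k={k} boxes, got {len(boxes)}")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    wh = np.array([[b.w, b.h] for b in boxes], dtype=float)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        init = _kmeanspp_init(wh, k, rng)
        run = _lloyd_run(wh, init, max_iter)
        if best is None or run[1] < best[1]:
            best = run
    centroids, objective, run_history = best
    if history is not None:
        history.extend(run_history)
    mean_iou = float(1.0 - objective)
    order = np.argsort(centroids[:, 0] * centroids[:, 1], kind="stable")
    anchors = tuple((float(w), float(h)) for w, h in centroids[order])
    return AnchorSet(anchors=anchors, k=k), mean_iou
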