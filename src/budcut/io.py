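"""Reading and writing images, masks and ground-truth sidecar JSON.

Masks travel either as single-channel PNG (0/255) or as run-length-encoded
JSON: row-major runs of foreground as [start, length] pairs over the
flattened array, with the shape stored alongside. Points are 0-based
{"x": column, "y": row}.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .geometry import PixelPoint
from .synthetic import SceneParams, SceneTruth

__all__ = [
    "read_rgb",
    "write_png",
    "write_mask_png",
    "mask_to_rle",
    "rle_to_mask",
    "write_truth",
    "read_truth",
]


def read_rgb(path) -> np.ndarray:
    """Read an image as H×W×3 uint8 RGB (grayscale/alpha are normalized away)."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[..., :3]
    return arr.astype(np.uint8)


def write_png(path, image: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8))


def write_mask_png(path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=np.uint8) * 255))


def mask_to_rle(mask: np.ndarray) -> dict:
    """Row-major [start, length] runs of foreground over the flattened mask."""
    m = np.asarray(mask, dtype=bool).ravel()
    padded = np.concatenate([[False], m, [False]])
    changes = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = changes[0::2], changes[1::2]
    return {
        "shape": list(mask.shape),
        "runs": [[int(s), int(e - s)] for s, e in zip(starts, ends)],
    }


def rle_to_mask(rle: dict) -> np.ndarray:
    flat = np.zeros(int(np.prod(rle["shape"])), dtype=np.uint8)
    for start, length in rle["runs"]:
        flat[start : start + length] = 1
    return flat.reshape(rle["shape"])


def _point_dict(p: PixelPoint) -> dict:
    return {"x": int(p.x), "y": int(p.y)}


def write_truth(path, truth: SceneTruth) -> None:
    """Sidecar `*.truth.json` with RLE masks, points and the scene parameters."""
    payload = {
        "params": dataclasses.asdict(truth.params),
        "true_cut_point": _point_dict(truth.true_cut_point),
        "centerline_endpoints": [
            _point_dict(truth.centerline_endpoints[0]),
            _point_dict(truth.centerline_endpoints[1]),
        ],
        "bud_mask": mask_to_rle(truth.bud_mask),
        "axis_mask": mask_to_rle(truth.axis_mask),
    }
    Path(path).write_text(json.dumps(payload))


def read_truth(path) -> dict:
    """Truth sidecar as a dict with masks decoded back to arrays."""
    payload = json.loads(Path(path).read_text())
    payload["bud_mask"] = rle_to_mask(payload["bud_mask"])
    payload["axis_mask"] = rle_to_mask(payload["axis_mask"])
    params = dict(payload["params"])
    params["bud_center"] = tuple(params["bud_center"])
    payload["params"] = SceneParams(**params)
    return payload
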