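"""Attention-guided object and part localization.

A convolutional feature stack summed over channels yields a 2-D attention
map whose high values mark where the network looks.  Thresholding the map
at its mean, keeping the largest connected region and scaling the tight
bounding box back to image pixels localizes the object without any box
supervision.  Sliding windows ranked by mean attention then propose key
part regions inside the object, with IoU-based suppression to spread the
windows over distinct parts.

All boxes are 0-based, half-open ``[x0, x1) x [y0, y1)`` with x right and
y down.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = [
    "BoundingBox",
    "PartWindow",
    "EmptyMaskError",
    "compute_attention_map",
    "attention_threshold",
    "binarize",
    "largest_component_bbox",
    "map_box_to_image",
    "crop_and_resize",
    "window_mean_attention",
    "iou",
    "propose_part_windows",
    "select_part_windows",
    "default_window_sizes",
    "localize_object",
    "locate_parts",
    "boxes_to_json",
    "boxes_from_json",
    "boxes_to_csv",
]


class EmptyMaskError(ValueError):
    """Raised when a binary mask contains no foreground cell."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned rectangle in 0-based, half-open pixel coordinates."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (0 <= self.x0 < self.x1 and 0 <= self.y0 < self.y1):
            raise ValueError(f"degenerate box {(self.x0, self.y0, self.x1, self.y1)}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x0, self.y0, self.x1, self.y1)


@dataclass(frozen=True)
class PartWindow:
    """Candidate part region scored by the mean attention inside its box."""

    box: BoundingBox
    mean_attention: float
    scale_id: int


def compute_attention_map(features: np.ndarray) -> np.ndarray:
    """Sum a (C, H, W) feature stack over channels into an (H, W) attention map.

    Every entry of the result is the channel sum of the activations at that
    spatial location; for post-ReLU stacks the map is nonnegative.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 3 or features.size == 0:
        raise ValueError(f"expected non-empty (C, H, W) stack, got shape {features.shape}")
    return features.sum(axis=0)


def attention_threshold(attn: np.ndarray) -> float:
    """Object/background threshold: the arithmetic mean of all map entries."""
    attn = np.asarray(attn, dtype=np.float64)
    if attn.size == 0:
        raise ValueError("empty attention map")
    return float(attn.mean())


def binarize(attn: np.ndarray, theta: float) -> np.ndarray:
    """Boolean mask, true exactly where the attention strictly exceeds theta."""
    if not math.isfinite(theta):
        raise ValueError("threshold must be finite")
    return np.asarray(attn, dtype=np.float64) > theta


def largest_component_bbox(mask: np.ndarray) -> BoundingBox:
    """Tight bounding box of the largest 8-connected foreground component.

    Smaller components (noise blobs) are discarded.  Raises
    :class:`EmptyMaskError` on an all-false mask; callers fall back to the
    full-image box.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("mask has no foreground cells")
    structure = np.ones((3, 3), dtype=bool)  # 8-connectivity
    labels, n = ndimage.label(mask, structure=structure)
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    winner = int(np.argmax(sizes)) + 1
    ys, xs = np.nonzero(labels == winner)
    return BoundingBox(int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)


def map_box_to_image(
    box: BoundingBox,
    map_shape: tuple[int, int],
    image_shape: tuple[int, int],
) -> BoundingBox:
    """Scale a box from attention-map cells to image pixels.

    Coordinates are multiplied by the per-axis ratio image_dim / map_dim,
    rounded outward (floor for the start, ceil for the end) and clipped, so
    the image box always covers the full extent of the map box.
    """
    mh, mw = map_shape
    ih, iw = image_shape
    if min(mh, mw, ih, iw) <= 0:
        raise ValueError("shapes must be positive")
    if box.x1 > mw or box.y1 > mh:
        raise ValueError(f"box {box.as_tuple()} exceeds map shape {map_shape}")
    sx = iw / mw
    sy = ih / mh
    return BoundingBox(
        max(0, math.floor(box.x0 * sx)),
        max(0, math.floor(box.y0 * sy)),
        min(iw, math.ceil(box.x1 * sx)),
        min(ih, math.ceil(box.y1 * sy)),
    )


def crop_and_resize(
    image: np.ndarray,
    box: BoundingBox,
    out_size: tuple[int, int],
    *,
    interpolation: str = "bilinear",
) -> np.ndarray:
    """Crop ``box`` from an (H, W[, C]) image and resample to ``out_size``.

    Bilinear by default; ``interpolation="nearest"`` gives exact pixel
    replication for tests.  Object crops conventionally use 448x448 and part
    crops 224x224 at full scale (64/32 with the tiny test backbone).
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    if box.x1 > w or box.y1 > h:
        raise ValueError(f"box {box.as_tuple()} exceeds image shape {(h, w)}")
    crop = image[box.y0 : box.y1, box.x0 : box.x1]
    oh, ow = out_size
    if crop.shape[:2] == (oh, ow):
        return crop.astype(np.float64, copy=True)
    order = {"bilinear": 1, "nearest": 0}[interpolation]
    out_shape = (oh, ow) + crop.shape[2:]
    return _sk_resize(
        crop.astype(np.float64), out_shape, order=order,
        mode="edge", anti_aliasing=False, preserve_range=True,
    )


def window_mean_attention(attn: np.ndarray, box: BoundingBox) -> float:
    """Mean attention inside a window: sum of in-window values / window area."""
    attn = np.asarray(attn, dtype=np.float64)
    h, w = attn.shape
    if box.x1 > w or box.y1 > h:
        raise ValueError(f"window {box.as_tuple()} exceeds map shape {(h, w)}")
    sub = attn[box.y0 : box.y1, box.x0 : box.x1]
    return float(sub.mean())


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes, in [0, 1]."""
    ix = max(0, min(a.x1, b.x1) - max(a.x0, b.x0))
    iy = max(0, min(a.y1, b.y1) - max(a.y0, b.y0))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union else 0.0


def default_window_sizes(map_shape: tuple[int, int]) -> list[tuple[int, int]]:
    """Square window sizes at 1/2, 1/3 and 1/4 of the shorter map side."""
    side = min(map_shape)
    sizes = []
    for frac in (2, 3, 4):
        s = max(1, side // frac)
        if (s, s) not in sizes:
            sizes.append((s, s))
    return sizes


def propose_part_windows(
    attn: np.ndarray,
    window_sizes: Sequence[tuple[int, int]],
    stride: int = 1,
) -> list[PartWindow]:
    """Exhaustively slide each window size over the map, scoring every placement.

    One candidate per valid placement per size; the score is the window's
    mean attention.  Summed-area tables keep this O(H*W) per size.
    """
    attn = np.asarray(attn, dtype=np.float64)
    h, w = attn.shape
    if stride < 1:
        raise ValueError("stride must be >= 1")
    # summed-area table with a zero border
    sat = np.zeros((h + 1, w + 1))
    sat[1:, 1:] = attn.cumsum(0).cumsum(1)
    out: list[PartWindow] = []
    for scale_id, (wh, ww) in enumerate(window_sizes):
        if wh > h or ww > w:
            raise ValueError(f"window {(wh, ww)} larger than map {(h, w)}")
        area = wh * ww
        for y0 in range(0, h - wh + 1, stride):
            for x0 in range(0, w - ww + 1, stride):
                y1, x1 = y0 + wh, x0 + ww
                total = sat[y1, x1] - sat[y0, x1] - sat[y1, x0] + sat[y0, x0]
                out.append(
                    PartWindow(BoundingBox(x0, y0, x1, y1), float(total / area), scale_id)
                )
    return out


def select_part_windows(
    candidates: Sequence[PartWindow],
    max_iou: float = 0.25,
    top_n: int = 2,
) -> list[PartWindow]:
    """Greedy non-maximum suppression by mean attention.

    Candidates are visited in descending score (ties broken by ascending
    (scale_id, y0, x0)); one is kept iff its IoU with every previously kept
    window is <= ``max_iou``.  Stops after ``top_n`` selections.
    """
    if not 0.0 <= max_iou <= 1.0:
        raise ValueError("max_iou must lie in [0, 1]")
    if top_n < 0:
        raise ValueError("top_n must be >= 0")
    ranked = sorted(
        candidates,
        key=lambda c: (-c.mean_attention, c.scale_id, c.box.y0, c.box.x0),
    )
    kept: list[PartWindow] = []
    for cand in ranked:
        if len(kept) >= top_n:
            break
        if all(iou(cand.box, k.box) <= max_iou for k in kept):
            kept.append(cand)
    return kept


def localize_object(image: np.ndarray, backbone) -> BoundingBox:
    """Attention-map pipeline: feature stack -> mean threshold -> mask ->
    largest component -> box scaled to image pixels.

    A degenerate (all-background) mask falls back to the full-image box so
    the pipeline never fails.
    """
    image = np.asarray(image)
    features = backbone.forward_features(image)
    attn = compute_attention_map(features)
    theta = attention_threshold(attn)
    mask = binarize(attn, theta)
    h, w = image.shape[:2]
    try:
        map_box = largest_component_bbox(mask)
    except EmptyMaskError:
        return BoundingBox(0, 0, w, h)
    return map_box_to_image(map_box, attn.shape, (h, w))


def locate_parts(
    attn: np.ndarray,
    window_sizes: Sequence[tuple[int, int]] | None = None,
    stride: int = 1,
    max_iou: float = 0.25,
    top_n: int = 2,
) -> list[PartWindow]:
    """Rank and suppress sliding windows on an attention map (per scale).

    Selection runs independently per window size, keeping ``top_n`` windows
    for each scale, mirroring the per-scale ranked windows of the method's
    visualizations.
    """
    if window_sizes is None:
        window_sizes = default_window_sizes(attn.shape)
    selected: list[PartWindow] = []
    for sid, size in enumerate(window_sizes):
        cands = propose_part_windows(attn, [size], stride)
        # restore global scale id on the per-scale candidates
        cands = [PartWindow(c.box, c.mean_attention, sid) for c in cands]
        selected.extend(select_part_windows(cands, max_iou=max_iou, top_n=top_n))
    return selected


# ---------------------------------------------------------------------------
# box export / import


def _box_record(image_id: str, kind: str, box: BoundingBox, score: float | None) -> dict:
    return {
        "image_id": image_id,
        "kind": kind,
        "x0": box.x0,
        "y0": box.y0,
        "x1": box.x1,
        "y1": box.y1,
        "score": score,
    }


def boxes_to_json(records: list[dict], path) -> None:
    with open(path, "w") as fh:
        json.dump(records, fh, indent=2)


def boxes_from_json(path) -> list[dict]:
    with open(path) as fh:
        return json.load(fh)


def boxes_to_csv(records: list[dict], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["image_id", "kind", "x0", "y0", "x1", "y1", "score"]
        )
        writer.writeheader()
        writer.writerows(records)


def make_box_record(
    image_id: str, kind: str, box: BoundingBox, score: float | None = None
) -> dict:
    """Record for the JSON/CSV box interchange format."""
    if kind not in ("object", "part"):
        raise ValueError("kind must be 'object' or 'part'")
    return _box_record(image_id, kind, box, score)
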