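"""Synthetic desk-scale fixtures: planted-object images and logit batches.

Real fine-grained bird data (one bird on a cluttered background, classes
distinguished by small part-level cues) is emulated by a controllable
generator: each image is Gaussian background noise plus one bright
textured ellipse (the "object") carrying a few high-contrast striped
patches (the "parts") whose stripe geometry and color encode the class
label.  Ground-truth object and part boxes are recorded, so localization
quality is measurable, and because the class cue lives in the parts rather
than in any global statistic, part-level cropping is genuinely
informative.

Everything is bit-reproducible from (params, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .attention import BoundingBox

__all__ = [
    "FixtureParams",
    "SyntheticSample",
    "gen_blob_image",
    "gen_dataset",
    "gen_logit_pairs",
    "export_cub_layout",
]


@dataclass(frozen=True)
class FixtureParams:
    """Generator knobs.

    ``signal_to_background`` is the ratio of the object's base intensity to
    the background mean; the localization acceptance condition is ratio 3,
    which is therefore the default.  ``object_area_fraction`` is the range
    of ellipse area as a fraction of the image.
    """

    image_size: int = 64
    n_classes: int = 5
    object_area_fraction: tuple[float, float] = (0.10, 0.30)
    signal_to_background: float = 3.0
    part_count: int = 3
    noise_sd: float = 0.05
    n_samples: int = 20
    seed: int = 0
    background_mean: float = 0.2

    def __post_init__(self) -> None:
        lo, hi = self.object_area_fraction
        if not (0 < lo <= hi < 1):
            raise ValueError("object_area_fraction range invalid")
        if self.signal_to_background < 1:
            raise ValueError("signal_to_background must be >= 1")
        if self.n_classes < 1 or self.n_samples < 1:
            raise ValueError("need at least one class and one sample")


@dataclass(frozen=True)
class SyntheticSample:
    """One generated image with its label and ground-truth geometry."""

    image: np.ndarray  # (H, W, 3) float64 in [0, 1]
    label: int
    object_box: BoundingBox
    part_boxes: tuple[BoundingBox, ...]
    seed: int


def _class_color(label: int, n_classes: int) -> np.ndarray:
    """Deterministic saturated RGB signature for a class."""
    ang = 2 * np.pi * label / max(n_classes, 1)
    rgb = 0.55 + 0.45 * np.cos(ang + np.array([0.0, 2.1, 4.2]))
    return np.clip(rgb, 0.1, 1.0)


def gen_blob_image(params: FixtureParams, seed: int, label: int | None = None) -> SyntheticSample:
    """One noisy image with a planted bright ellipse and class-coded parts.

    The object's tight bounding box (of the ellipse support) and every part
    patch box are returned as ground truth.  Raises if the sampled object
    cannot fit inside the image.
    """
    rng = np.random.default_rng([seed, params.seed])
    size = params.image_size
    if label is None:
        label = seed % params.n_classes
    bg = params.background_mean
    img = np.clip(
        bg + params.noise_sd * rng.standard_normal((size, size, 3)), 0.0, 1.0
    )

    # ellipse geometry
    frac = rng.uniform(*params.object_area_fraction)
    aspect = rng.uniform(0.7, 1.4)
    area = frac * size * size
    rx = np.sqrt(area / np.pi * aspect)
    ry = np.sqrt(area / np.pi / aspect)
    if 2 * rx >= size - 4 or 2 * ry >= size - 4:
        raise ValueError("object does not fit in the image; shrink object_area_fraction")
    cx = rng.uniform(rx + 2, size - rx - 2)
    cy = rng.uniform(ry + 2, size - ry - 2)
    yy, xx = np.mgrid[0:size, 0:size]
    inside = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
    if not inside.any():
        raise ValueError("degenerate object")

    # bright textured object
    obj_val = np.clip(bg * params.signal_to_background, 0.0, 1.0)
    texture = 1.0 + 0.12 * rng.standard_normal((size, size, 3))
    obj_img = np.clip(obj_val * texture, 0.0, 1.0)
    img = np.where(inside[..., None], obj_img, img)

    ys, xs = np.nonzero(inside)
    object_box = BoundingBox(int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)

    # class-coded striped part patches inside the ellipse
    color = _class_color(label, params.n_classes)
    period = 2 + label % 3
    horizontal = (label // 3) % 2 == 0
    half = max(2, int(0.35 * min(rx, ry)))
    base_angle = rng.uniform(0, 2 * np.pi)
    part_boxes: list[BoundingBox] = []
    for i in range(params.part_count):
        ang = base_angle + 2 * np.pi * i / max(params.part_count, 1)
        px = cx + 0.5 * rx * np.cos(ang)
        py = cy + 0.5 * ry * np.sin(ang)
        x0 = int(np.clip(px - half, object_box.x0, object_box.x1 - 2 * half))
        y0 = int(np.clip(py - half, object_box.y0, object_box.y1 - 2 * half))
        box = BoundingBox(x0, y0, x0 + 2 * half, y0 + 2 * half)
        sy, sx = np.mgrid[box.y0 : box.y1, box.x0 : box.x1]
        phase = (sy if horizontal else sx) // period % 2 == 0
        patch = np.where(phase[..., None], color, 0.15 * np.ones(3))
        img[box.y0 : box.y1, box.x0 : box.x1] = patch
        part_boxes.append(box)

    return SyntheticSample(img, int(label), object_box, tuple(part_boxes), seed)


def gen_dataset(params: FixtureParams) -> list[SyntheticSample]:
    """Class-balanced sample list, labels assigned round-robin.

    Exactly balanced when ``n_samples`` divides by ``n_classes``; per-sample
    seeds derive deterministically from ``params.seed``.
    """
    if params.n_samples < params.n_classes:
        raise ValueError("n_samples must be >= n_classes")
    samples = []
    for i in range(params.n_samples):
        child_seed = (params.seed * 1_000_003 + i) % (2**31)
        samples.append(gen_blob_image(params, child_seed, label=i % params.n_classes))
    return samples


def gen_logit_pairs(
    C: int,
    n: int,
    seed: int = 0,
    onehot_fraction: float = 0.25,
    scale: float = 3.0,
):
    """Random teacher/student logit pairs for distillation-identity tests.

    Logits are heavy-tailed (Student-t, df 3); a ``onehot_fraction`` of the
    teachers get their target logit boosted so the teacher target
    probability approaches 1 — the regime where classical distillation
    suppresses non-target knowledge.  Returns (z_teacher, z_student,
    target) tuples.
    """
    if C < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        z_t = scale * rng.standard_t(3, size=C)
        z_s = scale * rng.standard_t(3, size=C)
        t = int(rng.integers(C))
        if rng.random() < onehot_fraction:
            z_t[t] += rng.uniform(8.0, 15.0)
        out.append((z_t, z_s, t))
    return out


# ---------------------------------------------------------------------------
# CUB-style export


def export_cub_layout(
    samples: list[SyntheticSample],
    root,
    n_classes: int,
    train_fraction: float = 0.75,
) -> None:
    """Write samples in the CUB-200-2011 metadata dialect.

    ``images/<class>/<name>.jpg`` plus ``images.txt`` (1-based ids),
    ``image_class_labels.txt`` (1-based labels), ``train_test_split.txt``
    (1 = train, 0 = test, assigned deterministically by index) and
    ``boxes.json`` with the ground-truth geometry.
    """
    from PIL import Image

    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    images_lines, label_lines, split_lines, box_records = [], [], [], []
    period = max(2, round(1.0 / max(1e-9, 1.0 - train_fraction)))
    for i, s in enumerate(samples):
        cls_dir = root / "images" / f"{s.label + 1:03d}.class_{s.label:03d}"
        cls_dir.mkdir(exist_ok=True)
        name = f"img_{i:05d}.jpg"
        arr = (np.clip(s.image, 0, 1) * 255).astype(np.uint8)
        Image.fromarray(arr).save(cls_dir / name, quality=95)
        rel = f"images/{cls_dir.name}/{name}"
        img_id = i + 1
        images_lines.append(f"{img_id} {rel}")
        label_lines.append(f"{img_id} {s.label + 1}")
        split_lines.append(f"{img_id} {0 if i % period == period - 1 else 1}")
        box_records.append(
            {
                "image_id": rel,
                "kind": "object",
                "x0": s.object_box.x0, "y0": s.object_box.y0,
                "x1": s.object_box.x1, "y1": s.object_box.y1,
                "score": None,
            }
        )
        for pb in s.part_boxes:
            box_records.append(
                {
                    "image_id": rel, "kind": "part",
                    "x0": pb.x0, "y0": pb.y0, "x1": pb.x1, "y1": pb.y1,
                    "score": None,
                }
            )
    (root / "images.txt").write_text("\n".join(images_lines) + "\n")
    (root / "image_class_labels.txt").write_text("\n".join(label_lines) + "\n")
    (root / "train_test_split.txt").write_text("\n".join(split_lines) + "\n")
    with open(root / "boxes.json", "w") as fh:
        json.dump(box_records, fh, indent=2)
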