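"""Dataset readers, config files, checkpoints, run manifests, overlays.

Two dataset layouts are supported: the CUB-200-2011 metadata dialect
(``images.txt`` + ``image_class_labels.txt`` + ``train_test_split.txt``,
1-based ids, split 1 = train) and a plain class-per-folder tree.  Both
produce a :class:`DatasetIndex` with 0-based contiguous labels and a
deterministic record order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .attention import BoundingBox

__all__ = [
    "DatasetIndex",
    "DatasetRecord",
    "RunManifest",
    "read_cub_layout",
    "read_folder_layout",
    "load_image",
    "load_config",
    "save_config",
    "save_checkpoint",
    "load_checkpoint",
    "render_overlay",
    "setup_logging",
]

log = logging.getLogger("finebird")

_IMAGE_EXTS = {".jpg", ".jpeg", ".png", ".bmp"}


@dataclass(frozen=True)
class DatasetRecord:
    image_path: Path
    label: int
    split: str  # "train" | "test"


@dataclass
class DatasetIndex:
    records: list[DatasetRecord]
    class_names: list[str]

    def subset(self, split: str) -> list[DatasetRecord]:
        return [r for r in self.records if r.split == split]

    def __len__(self) -> int:
        return len(self.records)


def _read_id_file(path: Path) -> dict[int, str]:
    if not path.exists():
        raise FileNotFoundError(f"missing metadata file: {path}")
    out: dict[int, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"{path.name}:{lineno}: expected '<id> <value>', got {line!r}")
        try:
            out[int(parts[0])] = parts[1]
        except ValueError as exc:
            raise ValueError(f"{path.name}:{lineno}: bad id {parts[0]!r}") from exc
    return out


def read_cub_layout(root) -> DatasetIndex:
    """Join the three CUB metadata files into a dataset index.

    Labels are remapped from 1-based file ids to contiguous 0-based
    integers; split flag 1 means train, 0 means test.  Inconsistencies are
    reported with the offending file and id.
    """
    root = Path(root)
    images = _read_id_file(root / "images.txt")
    labels = _read_id_file(root / "image_class_labels.txt")
    splits = _read_id_file(root / "train_test_split.txt")
    for name, table in (("image_class_labels.txt", labels), ("train_test_split.txt", splits)):
        orphans = set(table) - set(images)
        if orphans:
            raise ValueError(f"{name}: ids {sorted(orphans)[:5]} absent from images.txt")
        missing = set(images) - set(table)
        if missing:
            raise ValueError(f"{name}: ids {sorted(missing)[:5]} have no entry")
    raw_labels = {i: int(v) for i, v in labels.items()}
    ordered_classes = sorted(set(raw_labels.values()))
    remap = {c: k for k, c in enumerate(ordered_classes)}
    records = []
    for img_id in sorted(images):
        path = root / images[img_id]
        if not path.exists():
            raise FileNotFoundError(f"images.txt: id {img_id}: {path} does not exist")
        split_flag = splits[img_id].strip()
        if split_flag not in ("0", "1"):
            raise ValueError(f"train_test_split.txt: id {img_id}: bad flag {split_flag!r}")
        records.append(
            DatasetRecord(path, remap[raw_labels[img_id]], "train" if split_flag == "1" else "test")
        )
    class_names = [str(c) for c in ordered_classes]
    return DatasetIndex(records, class_names)


def read_folder_layout(root, train_fraction: float = 1.0) -> DatasetIndex:
    """Class-per-folder reader: ``root/<class>/<image>``.

    Classes are labelled in lexicographic order and files listed sorted,
    so the index is identical regardless of OS listing order.  Non-image
    files are skipped with a warning.
    """
    root = Path(root)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"no class directories under {root}")
    records = []
    for label, cdir in enumerate(class_dirs):
        for f in sorted(cdir.rglob("*")):
            if not f.is_file():
                continue
            if f.suffix.lower() not in _IMAGE_EXTS:
                log.warning("skipping non-image file %s", f)
                continue
            records.append(DatasetRecord(f, label, "train"))
    if train_fraction < 1.0:
        period = max(2, round(1.0 / (1.0 - train_fraction)))
        records = [
            DatasetRecord(r.image_path, r.label, "test" if i % period == period - 1 else "train")
            for i, r in enumerate(records)
        ]
    return DatasetIndex(records, [d.name for d in class_dirs])


def load_image(path, size: int | None = None, interpolation: str = "bilinear") -> np.ndarray:
    """Decode to an (H, W, 3) float array in [0, 1], optionally resized."""
    from PIL import Image

    with Image.open(path) as im:
        im = im.convert("RGB")
        if size is not None:
            resample = Image.BILINEAR if interpolation == "bilinear" else Image.NEAREST
            im = im.resize((size, size), resample)
        return np.asarray(im, dtype=np.float64) / 255.0


def load_dataset_arrays(index: DatasetIndex, split: str, size: int):
    """Materialize (image, label) pairs for a split."""
    return [(load_image(r.image_path, size), r.label) for r in index.subset(split)]


# ---------------------------------------------------------------------------
# config / manifest / checkpoints


def load_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return data


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


@dataclass
class RunManifest:
    """Snapshot written before a run starts so it can be replayed exactly."""

    config: dict
    seed: int
    outputs: dict = field(default_factory=dict)
    code_version: str = "0.1.0"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "seed": self.seed,
                    "outputs": self.outputs,
                    "code_version": self.code_version,
                },
                fh,
                indent=2,
            )

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["config"], d["seed"], d.get("outputs", {}), d.get("code_version", ""))


def save_checkpoint(model, config: dict, epoch: int, path) -> None:
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    meta = json.dumps({"config": config, "epoch": epoch,
                       "num_classes": model.spec.num_classes})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path, model) -> dict:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
    model.load_state_dict(state)
    return meta


# ---------------------------------------------------------------------------
# overlay rendering


_PART_COLORS = [(255, 0, 0), (255, 215, 0), (0, 90, 255)]  # red, yellow, blue


def render_overlay(image: np.ndarray, object_box: BoundingBox | None,
                   part_windows, path) -> None:
    """Draw the object box (green) and ranked part windows (red/yellow/blue)
    on the image and save as PNG."""
    from PIL import Image, ImageDraw

    arr = (np.clip(np.asarray(image, dtype=np.float64), 0, 1) * 255).astype(np.uint8)
    im = Image.fromarray(arr)
    draw = ImageDraw.Draw(im)
    if object_box is not None:
        draw.rectangle(
            [object_box.x0, object_box.y0, object_box.x1 - 1, object_box.y1 - 1],
            outline=(0, 200, 0), width=2,
        )
    for rank, win in enumerate(part_windows):
        color = _PART_COLORS[min(rank, len(_PART_COLORS) - 1)]
        box = win.box if hasattr(win, "box") else win
        draw.rectangle([box.x0, box.y0, box.x1 - 1, box.y1 - 1], outline=color, width=1)
    im.save(path)


def setup_logging(verbose: bool = False, logfile=None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
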