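"""Training loops: three-branch teacher, five-stream distilled student,
and localization-recognition inference.

The teacher sees three streams per image — the raw image, the object crop
boxed by its own attention, and the top-ranked key-part crops — and sums
their cross-entropies.  The student sees five streams (raw, object+part
crops from the *teacher's* attention, object+part crops from its *own*
attention) and on every stream adds the decoupled distillation loss
against the frozen teacher's logits.  At test time only raw -> localize ->
object crop -> classify runs.

Optimization is SGD with momentum and weight decay; the learning rate
drops by ``lr_gamma`` at each milestone epoch.  Attention crops are a
non-differentiable spatial selection: gradients flow through crop
*contents*, never through box coordinates.  Everything is numpy and
seeded, so fixed-seed runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from . import attention as att
from . import losses as L

__all__ = [
    "TrainConfig",
    "EpochRecord",
    "SGDState",
    "lr_at",
    "augment_image",
    "attention_crops",
    "teacher_train_epoch",
    "student_distill_epoch",
    "train_teacher",
    "distill_student",
    "predict",
    "evaluate_model",
]


@dataclass(frozen=True)
class TrainConfig:
    """All training hyperparameters.

    Full-scale defaults follow the published schedule: 120 epochs, SGD
    momentum 0.9, weight decay 1e-4, learning rate cut to 0.1x at epochs
    60 and 100, temperature T = 4, DKD weight alpha = 2, raw/object crops
    448 and part crops 224.  ``tiny()`` scales everything to the 64x64
    synthetic task and the 3-block test CNN.
    """

    epochs: int = 120
    batch_size: int = 4
    lr0: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 1e-4
    lr_milestones: tuple[int, ...] = (60, 100)
    lr_gamma: float = 0.1
    T: float = 4.0
    alpha: float = 2.0
    raw_size: int = 448
    object_size: int = 448
    part_size: int = 224
    window_sizes: tuple[tuple[int, int], ...] | None = None
    stride: int = 1
    max_iou: float = 0.25
    top_n: int = 2
    seed: int = 0
    distill: str = "dkd"  # "dkd" | "kd" | "none"
    augment: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.lr0 <= 0:
            raise ValueError("epochs must be >= 1 and lr0 > 0")
        ms = list(self.lr_milestones)
        if ms != sorted(set(ms)) or any(m >= self.epochs or m < 1 for m in ms):
            raise ValueError("milestones must be strictly increasing and < epochs")
        if self.distill not in ("dkd", "kd", "none"):
            raise ValueError("distill must be 'dkd', 'kd' or 'none'")

    @classmethod
    def teacher_default(cls, **kw) -> "TrainConfig":
        return cls(batch_size=4, lr0=0.001, **kw)

    @classmethod
    def student_default(cls, **kw) -> "TrainConfig":
        return cls(batch_size=16, lr0=0.0001, **kw)

    @classmethod
    def tiny(cls, **kw) -> "TrainConfig":
        """Desk-scale config: 64x64 images, 32x32 part crops, single part
        window of half the 8x8 attention map, 30 epochs with a milestone
        at 20, and a from-scratch learning rate of 0.02."""
        defaults = dict(
            epochs=30, batch_size=4, lr0=0.02, lr_milestones=(20,),
            raw_size=64, object_size=64, part_size=32,
            window_sizes=((4, 4),), top_n=1,
        )
        defaults.update(kw)
        return cls(**defaults)

    @classmethod
    def student_tiny(cls, **kw) -> "TrainConfig":
        """Desk-scale distillation config.  The student trains at one tenth
        of the teacher's learning rate, mirroring the full-scale schedule
        (0.001 vs 0.0001): its loss sums hard and soft terms over five
        streams, so the same step size that suits the teacher overshoots."""
        kw.setdefault("lr0", 0.002)
        return cls.tiny(**kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["window_sizes"] is not None:
            d["window_sizes"] = [list(s) for s in d["window_sizes"]]
        d["lr_milestones"] = list(d["lr_milestones"])
        return d


@dataclass
class EpochRecord:
    """Per-epoch log entry: losses, the lr actually used, train accuracy,
    and (for DKD runs) mean TCKD/NCKD/teacher-target-probability."""

    epoch: int
    losses: object
    lr: float
    train_accuracy: float
    diagnostics: dict = field(default_factory=dict)


@dataclass
class SGDState:
    """Momentum buffers, one per parameter tensor."""

    velocity: dict = field(default_factory=dict)


def lr_at(config: TrainConfig, epoch: int) -> float:
    """lr(epoch) = lr0 * gamma^(number of milestones passed)."""
    passed = sum(1 for m in config.lr_milestones if epoch >= m)
    return config.lr0 * config.lr_gamma**passed


def _sgd_step(model, state: SGDState, lr: float, config: TrainConfig) -> None:
    for name, p in model.params.items():
        g = model.grads[name] + config.weight_decay * p
        v = state.velocity.get(name)
        if v is None:
            v = np.zeros_like(p)
        v = config.momentum * v + g
        state.velocity[name] = v
        p -= lr * v


def augment_image(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random horizontal flip plus brightness/contrast jitter."""
    img = np.asarray(image, dtype=np.float64)
    if rng.random() < 0.5:
        img = img[:, ::-1].copy()
    contrast = rng.uniform(0.8, 1.2)
    brightness = rng.uniform(-0.1, 0.1)
    return np.clip((img - 0.5) * contrast + 0.5 + brightness, 0.0, 1.0)


def _object_box_from_features(features: np.ndarray, image_shape) -> att.BoundingBox:
    attn = att.compute_attention_map(features)
    theta = att.attention_threshold(attn)
    mask = att.binarize(attn, theta)
    h, w = image_shape
    try:
        map_box = att.largest_component_bbox(mask)
    except att.EmptyMaskError:
        return att.BoundingBox(0, 0, w, h)
    return att.map_box_to_image(map_box, attn.shape, (h, w))


def attention_crops(model, images: np.ndarray, config: TrainConfig):
    """Object and key-part crops for a batch, from the model's own attention.

    Returns (object_batch, part_batches) where ``part_batches`` is a list
    of per-rank (N, p, p, 3) arrays so each part rank forms one stream.
    A second forward pass on the object crops supplies the part attention.
    """
    n = images.shape[0]
    feats = model.forward_features(images)  # (N, C, h, w)
    obj = np.stack(
        [
            att.crop_and_resize(
                images[i],
                _object_box_from_features(feats[i], images[i].shape[:2]),
                (config.object_size, config.object_size),
            )
            for i in range(n)
        ]
    )
    if config.top_n == 0:
        return obj, []
    obj_feats = model.forward_features(obj)
    part_lists = []
    for i in range(n):
        attn2 = att.compute_attention_map(obj_feats[i])
        wins = att.locate_parts(
            attn2,
            window_sizes=config.window_sizes,
            stride=config.stride,
            max_iou=config.max_iou,
            top_n=config.top_n,
        )
        crops = [
            att.crop_and_resize(
                obj[i],
                att.map_box_to_image(w_.box, attn2.shape, obj[i].shape[:2]),
                (config.part_size, config.part_size),
            )
            for w_ in wins
        ]
        part_lists.append(crops)
    n_parts = min(len(pl) for pl in part_lists)
    part_batches = [
        np.stack([part_lists[i][k] for i in range(n)]) for k in range(n_parts)
    ]
    return obj, part_batches


def _iter_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _prepare(dataset):
    images = np.stack([np.asarray(im, dtype=np.float64) for im, _ in dataset])
    labels = np.asarray([lab for _, lab in dataset], dtype=np.int64)
    return images, labels


def teacher_train_epoch(model, dataset, config: TrainConfig, epoch: int = 0,
                        opt_state: SGDState | None = None) -> tuple[EpochRecord, SGDState]:
    """One epoch of three-branch teacher training.

    Per batch: forward the raw images, box the object from the model's own
    attention, crop object and parts, forward each branch, sum the branch
    cross-entropies (L_total = L_r + L_o + L_p) and take one SGD step.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    opt_state = opt_state or SGDState()
    lr = lr_at(config, epoch)
    rng = np.random.default_rng([config.seed, epoch, 17])
    images, labels = _prepare(dataset)
    tot = np.zeros(3)
    n_seen = correct = 0
    for idx in _iter_batches(len(dataset), config.batch_size, rng):
        batch = images[idx]
        y = labels[idx]
        if config.augment:
            batch = np.stack([augment_image(b, rng) for b in batch])
        nb = len(idx)
        model.zero_grad()
        obj, part_batches = attention_crops(model, batch, config)
        l_r = l_o = l_p = 0.0
        for si, stream in enumerate([batch, obj, *part_batches]):
            z, cache = model.forward(stream, train=True)
            ce = float(np.mean(L.cross_entropy_from_logits(z, y)))
            model.backward(L.ce_grad_from_logits(z, y) / nb, cache)
            if si == 0:
                l_r = ce
            elif si == 1:
                l_o = ce
                correct += int(np.sum(np.argmax(z, axis=1) == y))
            else:
                l_p += ce
        _sgd_step(model, opt_state, lr, config)
        tot += np.array([l_r, l_o, l_p]) * nb
        n_seen += nb
    l_r, l_o, l_p = tot / n_seen
    bundle = L.TeacherLossBundle(l_r, l_o, l_p, l_r + l_o + l_p)
    return EpochRecord(epoch, bundle, lr, correct / n_seen), opt_state


def _soft_grad_and_loss(z_t, z_s, y, config: TrainConfig):
    """(soft loss, gradient, diagnostics) for one stream under the
    configured distillation mode."""
    if config.distill == "none":
        return 0.0, None, None
    if config.distill == "kd":
        return (float(np.mean(L.kd_loss(z_t, z_s, config.T))),
                L.kd_grad(z_t, z_s, config.T), None)
    t_val, n_val, pt = L.dkd_components(z_t, z_s, y, config.T)
    loss = float(np.mean(t_val + config.alpha * n_val))
    diag = (float(np.mean(t_val)), float(np.mean(n_val)), float(np.mean(pt)))
    return loss, L.dkd_grad(z_t, z_s, y, config.T, config.alpha), diag


def student_distill_epoch(student, teacher, dataset, config: TrainConfig, epoch: int = 0,
                          opt_state: SGDState | None = None) -> tuple[EpochRecord, SGDState]:
    """One epoch of five-stream student distillation.

    Streams: raw image; object and part crops from the *teacher's*
    attention; object and part crops from the *student's* attention (the
    two backbones attend differently, so the crops differ).  Each stream
    contributes a hard cross-entropy and, unless distillation is off, a
    soft loss against the frozen teacher's logits on the same images.
    Only the student's parameters move.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if student.spec.num_classes != teacher.spec.num_classes:
        raise ValueError("teacher and student class counts differ")
    opt_state = opt_state or SGDState()
    lr = lr_at(config, epoch)
    rng = np.random.default_rng([config.seed, epoch, 29])
    images, labels = _prepare(dataset)
    tot_hard = tot_soft = 0.0
    n_seen = correct = 0
    diag_sums = np.zeros(3)
    diag_count = 0
    for idx in _iter_batches(len(dataset), config.batch_size, rng):
        batch = images[idx]
        y = labels[idx]
        if config.augment:
            batch = np.stack([augment_image(b, rng) for b in batch])
        nb = len(idx)
        obj_t, parts_t = attention_crops(teacher, batch, config)
        obj_s, parts_s = attention_crops(student, batch, config)
        streams = [batch, obj_t, *parts_t, obj_s, *parts_s]
        student.zero_grad()
        l_hard = l_soft = 0.0
        for si, stream in enumerate(streams):
            z_s, cache = student.forward(stream, train=True)
            z_t, _ = teacher.forward(stream, train=False)
            l_hard += float(np.mean(L.cross_entropy_from_logits(z_s, y)))
            dlogits = L.ce_grad_from_logits(z_s, y)
            soft, soft_grad, diag = _soft_grad_and_loss(z_t, z_s, y, config)
            l_soft += soft
            if diag is not None:
                diag_sums += diag
                diag_count += 1
            if soft_grad is not None:
                dlogits = dlogits + soft_grad
            student.backward(dlogits / nb, cache)
            if si == len(parts_t) + 2:  # student-attention object stream
                correct += int(np.sum(np.argmax(z_s, axis=1) == y))
        _sgd_step(student, opt_state, lr, config)
        tot_hard += l_hard * nb
        tot_soft += l_soft * nb
        n_seen += nb
    bundle = L.StudentLossBundle(tot_hard / n_seen, tot_soft / n_seen,
                                 (tot_hard + tot_soft) / n_seen)
    diagnostics = {}
    if diag_count:
        diagnostics = dict(
            zip(("tckd_mean", "nckd_mean", "teacher_pt_mean"), diag_sums / diag_count)
        )
    return EpochRecord(epoch, bundle, lr, correct / n_seen, diagnostics), opt_state


def train_teacher(model, dataset, config: TrainConfig, callback=None) -> list[EpochRecord]:
    """Run the full teacher schedule; returns the per-epoch records."""
    records, state = [], None
    for epoch in range(config.epochs):
        rec, state = teacher_train_epoch(model, dataset, config, epoch, state)
        records.append(rec)
        if callback:
            callback(rec)
    return records


def distill_student(student, teacher, dataset, config: TrainConfig,
                    callback=None) -> list[EpochRecord]:
    """Run the full distillation schedule; the teacher stays frozen."""
    records, state = [], None
    for epoch in range(config.epochs):
        rec, state = student_distill_epoch(student, teacher, dataset, config, epoch, state)
        records.append(rec)
        if callback:
            callback(rec)
    return records


def predict(model, image: np.ndarray, config: TrainConfig | None = None):
    """Localization-recognition inference: classify the attention-boxed crop.

    Forward the raw image, box the object from the attention map, crop and
    resize to ``object_size``, classify the crop.  Part branches are a
    training-only augmentation and play no role here.  Returns
    (predicted label, probability vector).
    """
    config = config or TrainConfig.tiny()
    image = np.asarray(image, dtype=np.float64)
    feats = model.forward_features(image)
    box = _object_box_from_features(feats, image.shape[:2])
    crop = att.crop_and_resize(image, box, (config.object_size, config.object_size))
    logits = model.classify(crop)
    probs = L.softmax_t(logits, 1.0)
    return int(np.argmax(logits)), probs


def evaluate_model(model, dataset, config: TrainConfig | None = None):
    """Labels and localization-recognition predictions over a dataset."""
    labels, preds = [], []
    for image, label in dataset:
        pred, _ = predict(model, image, config)
        labels.append(label)
        preds.append(pred)
    return labels, preds
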