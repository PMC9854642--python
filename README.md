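# finebird

Attention-guided fine-grained bird classification with decoupled
knowledge distillation.

Fine-grained species classification (e.g. the 200 bird classes of
CUB-200-2011) fights two problems at once: the cues that separate species
are tiny part-level details, and the models strong enough to find them
are too heavy for the field devices ecologists actually deploy.
`finebird` implements both halves of a weakly supervised answer:

- **Attention localization.** Summing a backbone's final convolutional
  feature stack over channels gives an attention map
  `A(y,x) = Σ_c f_c(y,x)`. Thresholding `A` at its mean, boxing the
  largest connected region, and mapping the box back to pixels localizes
  the object with no box annotations; sliding windows ranked by mean
  attention (with IoU suppression) propose key-part regions. Object and
  part crops augment training, and at test time the object crop — not the
  raw image — is classified (localization–recognition).
- **Decoupled knowledge distillation.** Tempered logit distillation
  factors exactly as `KD = TCKD + (1 − p_t^T)·NCKD`: a target/non-target
  binary term plus a non-target term whose weight vanishes as the teacher
  grows confident. DKD decouples them, `DKD = TCKD + α·NCKD` (default
  `α = 2`, `T = 4`), preserving the non-target knowledge that
  distinguishes near-identical species while compressing a DenseNet121
  teacher into a ShuffleNetV2 student with 67% fewer parameters.

The library is pure scientific Python (numpy/scipy/scikit-image); the
desk-scale backbone, training loops and profiler are self-contained, so
every pipeline runs end-to-end on synthetic fixtures in seconds to
minutes on one CPU.

## Worked example

```python
import numpy as np
from finebird import (FixtureParams, gen_blob_image, IdentityBackbone,
                      localize_object, iou, dkd_loss, kd_loss, binary_split)

# 1. localize a planted object from intensity attention
s = gen_blob_image(FixtureParams(seed=0), seed=3)
box = localize_object(s.image, IdentityBackbone())
print(box.as_tuple(), s.object_box.as_tuple(), round(iou(box, s.object_box), 3))
# (18, 20, 52, 45) (19, 20, 52, 45) 0.971

# 2. decompose a distillation loss for one teacher/student logit pair
z_t = np.array([6.0, 1.5, 1.0, 0.5])   # teacher logits, target class 0
z_s = np.array([2.0, 1.0, 1.5, 0.2])   # student logits
b = dkd_loss(z_t, z_s, target=0, T=4.0, alpha=2.0)
print(f"TCKD={b.tckd:.4f} NCKD={b.nckd:.4f} pt={b.teacher_pt:.4f} DKD={b.total:.4f}")
# TCKD=0.1173 NCKD=0.0061 pt=0.5365 DKD=0.1295

pt, _ = binary_split(z_t, 0, 4.0)
print(f"KD={kd_loss(z_t, z_s, 4.0):.4f} == TCKD+(1-pt)NCKD={b.tckd + (1-pt)*b.nckd:.4f}")
# KD=0.1201 == TCKD+(1-pt)NCKD=0.1201
```

The attention box recovers the planted object at IoU 0.97, and the
factorization shows why DKD matters: classical KD weights the non-target
term by `1 − p_t = 0.46` here, and by nearly zero for a confident
teacher, while DKD fixes the weight at `α`.

A command-line surface wraps the same library:

```bash
finebird fixtures --out data --n-samples 20 --n-classes 5 --seed 0
finebird train-teacher --data data --out runs/teacher --seed 1 --epochs 30
finebird distill --data data --teacher runs/teacher/model.npz --out runs/student --seed 2
finebird evaluate --data data --checkpoint runs/student/model.npz --split test
finebird localize --data data --out runs/boxes      # boxes.json/csv + overlay PNGs
finebird profile --model student                    # {"params": 2278604, ...}
```

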