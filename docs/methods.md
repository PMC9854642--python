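# Methods

## Problem and approach

Fine-grained bird classification must separate species that differ only in
small part-level cues (head pattern, beak shape) while individuals of one
species vary widely in pose and background. `finebird` implements a
weakly supervised pipeline that needs only image-level labels:

1. **Attention localization.** The channel sum of the backbone's final
   post-activation convolutional stack gives a 2-D attention map
   `A(y, x) = Σ_c f_c(y, x)`. Thresholding `A` at its global mean, keeping
   the largest 8-connected foreground component, and scaling the
   component's tight bounding box to pixel coordinates yields an object
   box with no box supervision. Sliding windows over the object crop's
   attention map, ranked by mean attention with greedy IoU suppression,
   yield key-part windows.
2. **Attention-guided augmentation and inference.** The teacher trains on
   three streams per image (raw, object crop, part crops) with summed
   cross-entropies `L = L_r + L_o + L_p`. At test time the model
   classifies the object crop of the raw image (localization–recognition);
   part branches are training-only.
3. **Decoupled knowledge distillation (DKD).** Classical logit
   distillation, `KD = KL(P^T ‖ P^S)` with both softmaxes tempered by `T`,
   factors exactly as `KD = TCKD + (1 − p_t^T)·NCKD`, where TCKD is the KL
   between the binary (target, non-target) splits and NCKD the KL between
   the renormalized non-target distributions. A confident teacher
   (`p_t^T → 1`) therefore suppresses non-target knowledge — precisely the
   knowledge that distinguishes near-identical species. DKD replaces the
   coupled weight with a constant: `DKD = TCKD + α·NCKD`, default `α = 2`.
   The student trains on five streams (raw; object+parts from teacher
   attention; object+parts from its own attention) with
   `L = L_hard + L_soft` per stream.

## Key numerical and design choices

- **Threshold.** θ is the arithmetic mean of all H×W attention entries;
  the mask uses a strict `A > θ` comparison, so a constant map yields an
  empty mask and the pipeline falls back to the full-image box.
- **Temperature everywhere.** `p_t`, `p_∖t` and the non-target
  distribution all use the same temperature as the full softmax. This is
  the only choice under which the factorization identity holds at every
  `T`; the test suite asserts it to 1e-9 over 30 000 random pair/
  temperature combinations, including teachers with `p_t > 0.99`. All
  probability work is done in log space (log-sum-exp), which is why the
  identity holds to ~1e-13 rather than ~1e-7.
- **No T² rescaling** of soft losses; batch reduction is the mean over
  samples, stream combination the sum over streams.
- **Suppression.** "Too much overlap" between part windows is IoU > 0.25
  (configurable); windows are ranked per scale and the top 2 per scale are
  kept by default. Window sizes default to squares of 1/2, 1/3 and 1/4 of
  the attention-map side at stride 1. None of these values is forced by
  the method; they are exposed on `TrainConfig`.
- **Boxes** are 0-based half-open, x right / y down. Map→image scaling
  rounds outward (floor start, ceil end), so the image box always covers
  the map box.
- **Gradients do not flow through box coordinates.** Cropping is treated
  as image-space data augmentation; gradients flow through crop contents
  only.
- **Optimization** is SGD with momentum 0.9 and weight decay 1e-4; the
  learning rate drops ×0.1 at the configured milestone epochs (full-scale
  defaults: epochs 60 and 100 of 120).

## Reference architectures and the profiler

The full-scale teacher is DenseNet121 (stride 32, 1024 channels) and the
student ShuffleNetV2 ×1.0. Neither is instantiated here; both exist as
exact layer enumerations that the profiler walks to count trainable
parameters and MACs (one MAC per multiply-add in conv/linear layers only;
batch norm, pooling and activations count zero — stated explicitly because
"FLOPs" conventions vary). The enumerations reproduce the published
counts: 2,278,604 parameters for ShuffleNetV2 ×1.0 with its stock
1000-class head and 6,953,856 for the DenseNet121 trunk, a 67% reduction.
The trunk and head are profiled separately because published DenseNet121
counts sometimes exclude the classifier.

## The desk-scale backbone

All runnable experiments use `TinyCNN`, a 3-block numpy CNN: three
(conv3×3 → instance norm → ReLU → 2×2 average-pool) blocks of width 16
(output stride 8), global average pooling and a linear head. Without
normalization the from-scratch network does not optimize at this scale —
activations shrink to ~1e-2 through the stack and SGD stalls at the
uniform-prediction plateau. Instance norm (per sample and channel over
space, affine-less) was chosen over batch norm deliberately: the shared
trunk sees raw images, object crops and part crops — streams with very
different activation statistics — so batch running statistics are biased
by whichever mixture of streams they were accumulated on, opening a
train/eval gap that corrupts both predictions and attention maps at
inference. Instance norm makes the network a pure function of its input:
no running state, bit-identical outputs for batched and single-image
forwards. Forward and backward passes are plain numpy (im2col
convolutions); gradients are verified against central finite differences
in the test suite. Everything is float64 and single-threaded, so
fixed-seed runs are bit-reproducible.

## Synthetic fixtures

The generator emulates the structure of fine-grained bird data, not its
appearance: each 64×64 image is Gaussian background noise (mean 0.2,
sd 0.05) plus one bright textured ellipse (the object, intensity 3× the
background mean — the ratio at which localization is evaluated) carrying
three striped patches (the parts) whose stripe period, orientation and
color encode the class. Ground-truth object and part boxes are recorded.
Because the class cue lives only in the parts, part crops are provably
more informative than background crops, which the tests verify with a
linear probe.

What the fixtures do **not** capture: natural image statistics, pose and
scale variation of real birds, occlusion, class counts in the hundreds,
and the gap between a planted intensity blob and learned attention.
Passing the localization and distillation checks therefore demonstrates
that the algorithms are implemented correctly and behave in the right
direction at small scale, not that full-scale accuracy numbers transfer.

## Scaled-down experiment sizes

The distillation-direction experiment uses 20 images across 5 classes,
the 30-epoch tiny schedule (milestone at epoch 20), and 5 student seeds
per arm; localization recovery uses 200 seeded images. The teacher trains
at lr 0.02; students train at lr 0.002. The 1/10 ratio mirrors the
full-scale schedule (0.001 vs 0.0001), and for the same reason: the
student's loss sums hard and soft terms over five streams, so the step
size that suits the three-stream teacher overshoots for the student. At
the student learning rate the 30-epoch budget leaves the students
genuinely short of saturation, which is what makes the comparison
informative: the soft losses add gradient signal aligned with the (fully
trained) teacher, so per seed the final train accuracy orders
no-KD ≤ KD ≤ DKD, with DKD's decoupled non-target term providing the
largest acceleration — the same direction the full-scale ablations
report.

## Known limitations

- The numpy backbone is CPU-bound and meant for 64×64 fixtures; the
  full-scale 448×448 / 224×224 crop sizes are supported by the geometry
  code but impractical to train here.
- ImageNet-pretrained weights (used by the published full-scale runs) are
  supported only as a checkpoint path; no download or conversion is
  provided.
- Attention maps are neither smoothed nor normalized before thresholding;
  on real backbones light smoothing may help small-object masks.
- The degenerate all-background mask falls back to the full-image box
  rather than failing; callers who need to detect this can test the mask
  directly.
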