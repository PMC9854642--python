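"""Backbone contract, desk-scale CNN, and a params/MACs profiler.

At full scale the method pairs a DenseNet121 teacher (stride 32, 1024
feature channels) with a ShuffleNetV2 x1.0 student.  Here those two
architectures exist as layer enumerations for the profiler, while all
runnable experiments use :class:`TinyCNN` — a 3-block numpy CNN (stride 8,
16 channels) small enough to train on 64x64 synthetic images in seconds —
and :class:`IdentityBackbone`, whose attention map is simply the image
intensity.

The profiler convention: one MAC per multiply-add in convolution and
linear layers only; normalization, pooling and activations count zero
MACs.  Trainable parameters include conv/linear weights and biases and,
for the reference architectures, the two affine batch-norm vectors
(running statistics are buffers, not parameters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "BackboneSpec",
    "ModelProfile",
    "TinyCNN",
    "IdentityBackbone",
    "profile_model",
    "profile_layers",
    "densenet121_layers",
    "shufflenetv2_layers",
]


@dataclass(frozen=True)
class BackboneSpec:
    """Feature-extractor contract: channels, stride and head width."""

    name: str
    feature_channels: int
    output_stride: int
    num_classes: int

    def __post_init__(self) -> None:
        if self.output_stride & (self.output_stride - 1):
            raise ValueError("output_stride must be a power of 2")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")


@dataclass(frozen=True)
class ModelProfile:
    """Trainable-parameter and multiply-accumulate counts at one input size."""

    name: str
    param_count: int
    mac_count: int
    input_size: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "params": self.param_count,
            "macs": self.mac_count,
            "input_size": list(self.input_size),
        }


# ---------------------------------------------------------------------------
# numpy layers for the tiny backbone


def _conv3x3_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """'same' 3x3 convolution on NCHW input via an im2col matmul."""
    n, cin, h, wd = x.shape
    cout = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    # (N, Cin, H, W, 3, 3) view over the padded input
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h, wd, cin * 9)
    wmat = w.reshape(cout, cin * 9)
    out = cols @ wmat.T + b
    return out.transpose(0, 3, 1, 2), cols


def _conv3x3_backward(dout: np.ndarray, cols: np.ndarray, w: np.ndarray, in_shape):
    n, cin, h, wd = in_shape
    cout = w.shape[0]
    d = dout.transpose(0, 2, 3, 1)  # (N, H, W, Cout)
    dw = np.einsum("nhwo,nhwk->ok", d, cols).reshape(w.shape)
    db = d.sum(axis=(0, 1, 2))
    dcols = (d @ w.reshape(cout, cin * 9)).reshape(n, h, wd, cin, 3, 3)
    dxp = np.zeros((n, cin, h + 2, wd + 2))
    for ki in range(3):
        for kj in range(3):
            dxp[:, :, ki : ki + h, kj : kj + wd] += dcols[:, :, :, :, ki, kj].transpose(
                0, 3, 1, 2
            )
    return dxp[:, :, 1:-1, 1:-1], dw, db


def _avgpool2(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def _avgpool2_backward(dout: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) / 4.0


class TinyCNN:
    """3-block CNN (conv3x3 -> instance norm -> ReLU -> 2x2 avg-pool) + GAP + FC.

    Output stride 8 with 16 feature channels, so a 64x64 image yields an
    8x8 attention map.  Normalization is per-sample instance norm, so the
    network is a pure function of its input: no running statistics, no
    train/eval gap, bit-identical outputs for batched and single-image
    forwards.  Forward and backward passes are plain numpy; gradients
    accumulate in :attr:`grads` until :meth:`zero_grad`.
    """

    def __init__(self, num_classes: int, in_channels: int = 3, width: int = 16,
                 seed: int = 0, name: str = "tiny-cnn"):
        rng = np.random.default_rng(seed)
        self.spec = BackboneSpec(name, width, 8, num_classes)
        self.in_channels = in_channels
        self.width = width
        cs = [in_channels, width, width, width]
        self.params: dict[str, np.ndarray] = {}
        for i in range(3):
            fan_in = cs[i] * 9
            self.params[f"conv{i}.w"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(cs[i + 1], cs[i], 3, 3)
            )
            self.params[f"conv{i}.b"] = np.zeros(cs[i + 1])
        self.params["fc.w"] = rng.normal(0.0, np.sqrt(1.0 / width), size=(num_classes, width))
        self.params["fc.b"] = np.zeros(num_classes)
        self.grads: dict[str, np.ndarray] = {k: np.zeros_like(v) for k, v in self.params.items()}

    # -- forward -----------------------------------------------------------

    def _to_nchw(self, image: np.ndarray) -> tuple[np.ndarray, bool]:
        image = np.asarray(image, dtype=np.float64)
        if image.ndim == 3:  # single (H, W, C)
            return image.transpose(2, 0, 1)[None], True
        if image.ndim == 4:  # (N, H, W, C)
            return image.transpose(0, 3, 1, 2), False
        raise ValueError(f"expected (H, W, C) or (N, H, W, C), got {image.shape}")

    def forward(self, images: np.ndarray, train: bool = False):
        """Full pass on an (N, H, W, C) batch -> (logits, cache)."""
        x, _ = self._to_nchw(np.asarray(images))
        if x.shape[1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels")
        if x.shape[2] % 8 or x.shape[3] % 8:
            raise ValueError("input height/width must be divisible by 8")
        cache: dict = {"in_shapes": [], "cols": [], "relu": [], "norm": []}
        for i in range(3):
            cache["in_shapes"].append(x.shape)
            x, cols = _conv3x3_forward(x, self.params[f"conv{i}.w"], self.params[f"conv{i}.b"])
            cache["cols"].append(cols if train else None)
            # affine-less instance norm: per sample and channel over space.
            # Batch-independent, so there is no train/eval gap and the shared
            # trunk sees raw images, object crops and part crops — streams
            # with very different activation statistics — on equal footing.
            mu = x.mean(axis=(2, 3), keepdims=True)
            var = x.var(axis=(2, 3), keepdims=True)
            inv = 1.0 / np.sqrt(var + 1e-5)
            x = (x - mu) * inv
            cache["norm"].append((x.copy(), inv) if train else None)
            relu_mask = x > 0
            cache["relu"].append(relu_mask if train else None)
            x = x * relu_mask
            x = _avgpool2(x)
        cache["feat_shape"] = x.shape
        pooled = x.mean(axis=(2, 3))
        logits = pooled @ self.params["fc.w"].T + self.params["fc.b"]
        cache["pooled"] = pooled if train else None
        cache["features"] = x
        return logits, cache

    def forward_features(self, image: np.ndarray) -> np.ndarray:
        """Final post-activation (and pooled) conv stack: (C, h, w) for one image."""
        x, single = self._to_nchw(image)
        _, cache = self.forward(x.transpose(0, 2, 3, 1), train=False)
        feats = cache["features"]
        return feats[0] if single else feats

    def classify(self, image: np.ndarray) -> np.ndarray:
        """Logits: GAP of the feature stack through the FC head."""
        x, single = self._to_nchw(image)
        logits, _ = self.forward(x.transpose(0, 2, 3, 1), train=False)
        return logits[0] if single else logits

    # -- backward ----------------------------------------------------------

    def backward(self, dlogits: np.ndarray, cache: dict) -> None:
        """Accumulate parameter gradients for a forward pass run with train=True."""
        pooled = cache["pooled"]
        if pooled is None:
            raise RuntimeError("forward pass was not run with train=True")
        self.grads["fc.w"] += dlogits.T @ pooled
        self.grads["fc.b"] += dlogits.sum(axis=0)
        dpooled = dlogits @ self.params["fc.w"]
        n, c, fh, fw = cache["feat_shape"]
        dx = np.broadcast_to(dpooled[:, :, None, None], (n, c, fh, fw)) / (fh * fw)
        for i in reversed(range(3)):
            dx = _avgpool2_backward(dx)
            dx = dx * cache["relu"][i]
            xhat, inv = cache["norm"][i]
            # instance-norm backward (statistics over the spatial axes)
            dx = inv * (
                dx
                - dx.mean(axis=(2, 3), keepdims=True)
                - xhat * (dx * xhat).mean(axis=(2, 3), keepdims=True)
            )
            dx, dw, db = _conv3x3_backward(
                dx, cache["cols"][i], self.params[f"conv{i}.w"], cache["in_shapes"][i]
            )
            self.grads[f"conv{i}.w"] += dw
            self.grads[f"conv{i}.b"] += db

    def zero_grad(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0

    # -- bookkeeping -------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k][...] = v

    def layer_specs(self, input_size: tuple[int, int] | None = None) -> list[dict]:
        cs = [self.in_channels, self.width, self.width, self.width]
        layers: list[dict] = []
        for i in range(3):
            layers.append(dict(type="conv", cin=cs[i], cout=cs[i + 1], k=3, stride=1,
                               pad=1, groups=1, bias=True))
            layers.append(dict(type="pool", k=2, stride=2, pad=0))
        layers.append(dict(type="gap"))
        layers.append(dict(type="linear", fin=self.width, fout=self.spec.num_classes, bias=True))
        return layers


class IdentityBackbone:
    """Feature stack = the image's own channels (optionally average-pooled).

    The induced attention map is the per-pixel channel-intensity sum, which
    makes this the intensity oracle for localization tests: a bright object
    on a dim background is exactly what the attention pipeline should box.
    """

    def __init__(self, stride: int = 1):
        if stride < 1:
            raise ValueError("stride must be >= 1")
        self.stride = stride
        self.spec = BackboneSpec("identity", 3, max(1, stride), 2)

    def forward_features(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=np.float64)
        if image.ndim == 2:
            image = image[..., None]
        feats = image.transpose(2, 0, 1)
        s = self.stride
        if s > 1:
            c, h, w = feats.shape
            h2, w2 = h // s, w // s
            feats = feats[:, : h2 * s, : w2 * s].reshape(c, h2, s, w2, s).mean(axis=(2, 4))
        return feats


# ---------------------------------------------------------------------------
# profiler


def profile_layers(layers: list[dict], input_size: tuple[int, int],
                   name: str = "model") -> ModelProfile:
    """Walk an ordered layer enumeration, counting params and MACs.

    Spatial dimensions propagate sequentially through strided layers; for
    architectures with concatenation (DenseNet) each layer carries its own
    explicit input-channel count, so only the spatial size is tracked.
    """
    h, w = input_size
    params = 0
    macs = 0
    for layer in layers:
        t = layer["type"]
        if t == "conv":
            cin, cout, k = layer["cin"], layer["cout"], layer["k"]
            s, p, g = layer["stride"], layer["pad"], layer.get("groups", 1)
            params += cout * (cin // g) * k * k + (cout if layer.get("bias") else 0)
            h = (h + 2 * p - k) // s + 1
            w = (w + 2 * p - k) // s + 1
            macs += h * w * cout * (cin // g) * k * k
        elif t == "bn":
            params += 2 * layer["c"]
        elif t == "pool":
            k, s, p = layer["k"], layer["stride"], layer.get("pad", 0)
            h = (h + 2 * p - k) // s + 1
            w = (w + 2 * p - k) // s + 1
        elif t == "gap":
            h = w = 1
        elif t == "linear":
            params += layer["fin"] * layer["fout"] + (layer["fout"] if layer.get("bias", True) else 0)
            macs += layer["fin"] * layer["fout"]
        else:
            warnings.warn(f"layer type {t!r} not profiled; counted as 0 MACs")
    return ModelProfile(name, params, macs, tuple(input_size))


def profile_model(model, input_size: tuple[int, int]) -> ModelProfile:
    """Profile any object exposing ``layer_specs()`` (or a raw layer list)."""
    if isinstance(model, list):
        return profile_layers(model, input_size)
    layers = model.layer_specs()
    name = getattr(getattr(model, "spec", None), "name", type(model).__name__)
    prof = profile_layers(layers, input_size, name=name)
    if hasattr(model, "params"):
        # cross-check against a brute-force enumeration of trainable scalars
        brute = sum(v.size for v in model.params.values())
        if brute != prof.param_count:
            raise AssertionError(
                f"profiler param count {prof.param_count} != enumerated {brute}"
            )
    return prof


def _bn(c: int) -> dict:
    return dict(type="bn", c=c)


def _conv(cin, cout, k, stride=1, pad=0, groups=1, bias=False) -> dict:
    return dict(type="conv", cin=cin, cout=cout, k=k, stride=stride, pad=pad,
                groups=groups, bias=bias)


def densenet121_layers(num_classes: int = 1000, include_head: bool = True) -> list[dict]:
    """DenseNet121: growth 32, blocks (6, 12, 24, 16), bottleneck width 4x.

    ``include_head=False`` gives the convolutional trunk only (6.95 M
    parameters); the 1000-class head adds another ~1.03 M.
    """
    growth, bn_size = 32, 4
    layers = [_conv(3, 64, 7, stride=2, pad=3), _bn(64),
              dict(type="pool", k=3, stride=2, pad=1)]
    c = 64
    block_cfg = (6, 12, 24, 16)
    for bi, n_layers in enumerate(block_cfg):
        for i in range(n_layers):
            cin = c + i * growth
            layers += [_bn(cin), _conv(cin, bn_size * growth, 1),
                       _bn(bn_size * growth), _conv(bn_size * growth, growth, 3, pad=1)]
        c += n_layers * growth
        if bi != len(block_cfg) - 1:
            layers += [_bn(c), _conv(c, c // 2, 1), dict(type="pool", k=2, stride=2)]
            c //= 2
    layers.append(_bn(c))  # final norm, c = 1024
    if include_head:
        layers += [dict(type="gap"), dict(type="linear", fin=c, fout=num_classes, bias=True)]
    return layers


def shufflenetv2_layers(num_classes: int = 1000, include_head: bool = True) -> list[dict]:
    """ShuffleNetV2 x1.0: stages (116, 232, 464) x (4, 8, 4) units, conv5 1024.

    With the stock 1000-class head this is the 2.28 M-parameter network."""
    layers = [_conv(3, 24, 3, stride=2, pad=1), _bn(24),
              dict(type="pool", k=3, stride=2, pad=1)]
    cin = 24
    for c_out, repeats in ((116, 4), (232, 8), (464, 4)):
        bf = c_out // 2
        # Stride-2 unit, two parallel branches.  The flat list orders layers so
        # the sequential spatial tracker sees each conv at its true output
        # size: branch2's leading 1x1 runs at full resolution, one strided
        # depthwise conv halves the tracker, and the second depthwise conv is
        # listed with stride 1 because its output (what MACs depend on) is
        # already at the halved size.
        layers += [_conv(cin, bf, 1), _bn(bf)]                       # branch2 pw
        layers += [_conv(cin, cin, 3, stride=2, pad=1, groups=cin),  # branch1 dw
                   _bn(cin), _conv(cin, bf, 1), _bn(bf)]             # branch1 pw
        layers += [_conv(bf, bf, 3, stride=1, pad=1, groups=bf),     # branch2 dw
                   _bn(bf), _conv(bf, bf, 1), _bn(bf)]               # branch2 pw
        cin = c_out
        for _ in range(repeats - 1):
            layers += [_conv(bf, bf, 1), _bn(bf),
                       _conv(bf, bf, 3, stride=1, pad=1, groups=bf), _bn(bf),
                       _conv(bf, bf, 1), _bn(bf)]
    layers += [_conv(cin, 1024, 1), _bn(1024)]
    if include_head:
        layers += [dict(type="gap"), dict(type="linear", fin=1024, fout=num_classes, bias=True)]
    return layers
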