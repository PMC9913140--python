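"""Fire-module convolutional feature extractor.

The extractor follows the SqueezeNet idea: stacks of *fire modules*, each a
1x1 "squeeze" convolution feeding two parallel "expand" convolutions (1x1
and 3x3) whose outputs are channel-concatenated.  Because the squeeze layer
has fewer kernels than the combined expand layers (s < e1 + e3), and 3x3
kernels are partly replaced by 1x1 kernels (a nine-fold reduction per
substituted kernel), the parameter count stays small while spatial detail
is preserved.

The default topology is desk scale — a 32x32 grayscale input, an 8-channel
3x3 stem, three fire modules with max pooling after the first two, and
global average pooling to a 32-dimensional feature vector.  The full
SqueezeNet-v1.1 fire stack is available via
:meth:`ExtractorConfig.squeezenet_v11` for larger experiments.

Weights live in a flat ``dict[str, ndarray]`` so they serialize trivially
and plug straight into the Adamax optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import _nn
from .adamax import AdamaxOptimizer
from .errors import ParameterError, StructuralError

__all__ = [
    "FireConfig",
    "ExtractorConfig",
    "ParamCount",
    "conv_param_count",
    "count_parameters",
    "init_weights",
    "fire_forward",
    "extract_features",
    "train_extractor",
]


@dataclass(frozen=True)
class FireConfig:
    """Channel counts of one fire module.

    The squeeze layer must be narrower than the combined expand layers
    (``squeeze_1x1 < expand_1x1 + expand_3x3``) — that inequality is what
    makes the module a bottleneck.
    """

    squeeze_1x1: int
    expand_1x1: int
    expand_3x3: int

    def __post_init__(self):
        if min(self.squeeze_1x1, self.expand_1x1, self.expand_3x3) < 1:
            raise ParameterError("all fire-module channel counts must be >= 1")
        if self.squeeze_1x1 >= self.expand_1x1 + self.expand_3x3:
            raise ParameterError(
                f"squeeze channels ({self.squeeze_1x1}) must be < expand total "
                f"({self.expand_1x1 + self.expand_3x3})"
            )

    @property
    def out_channels(self) -> int:
        return self.expand_1x1 + self.expand_3x3


@dataclass(frozen=True)
class ExtractorConfig:
    """Topology of the feature extractor."""

    input_size: tuple[int, int, int] = (32, 32, 1)  # (H, W, channels)
    stem_channels: int = 8
    fire_configs: tuple[FireConfig, ...] = (
        FireConfig(4, 8, 8),
        FireConfig(8, 16, 16),
        FireConfig(8, 16, 16),
    )
    pool_positions: tuple[int, ...] = (0, 1)  # max-pool after these modules
    seed: int = 0

    def __post_init__(self):
        if not self.fire_configs:
            raise ParameterError("at least one fire module is required")
        for p in self.pool_positions:
            if p >= len(self.fire_configs):
                raise ParameterError(f"pool position {p} out of range")

    @property
    def feature_dim(self) -> int:
        """Output length: the last fire module's expand channel total."""
        return self.fire_configs[-1].out_channels

    @classmethod
    def squeezenet_v11(cls, input_size=(224, 224, 3), seed: int = 0) -> "ExtractorConfig":
        """The full v1.1 fire stack (64-channel stem, 8 fire modules)."""
        fires = (
            FireConfig(16, 64, 64),
            FireConfig(16, 64, 64),
            FireConfig(32, 128, 128),
            FireConfig(32, 128, 128),
            FireConfig(48, 192, 192),
            FireConfig(48, 192, 192),
            FireConfig(64, 256, 256),
            FireConfig(64, 256, 256),
        )
        return cls(
            input_size=input_size,
            stem_channels=64,
            fire_configs=fires,
            pool_positions=(1, 3),
            seed=seed,
        )


@dataclass(frozen=True)
class ParamCount:
    weights: int
    biases: int

    @property
    def total(self) -> int:
        return self.weights + self.biases


def conv_param_count(in_channels: int, out_channels: int, kernel: int, bias: bool = False) -> ParamCount:
    """Trainable parameters of a single ``kernel x kernel`` convolution."""
    return ParamCount(out_channels * in_channels * kernel * kernel, out_channels if bias else 0)


def count_parameters(config: ExtractorConfig, bias: bool = True) -> ParamCount:
    """Exact trainable-parameter count of the extractor (weights, biases)."""
    weights = biases = 0

    def add(c: ParamCount):
        nonlocal weights, biases
        weights += c.weights
        biases += c.biases

    in_ch = config.input_size[2]
    add(conv_param_count(in_ch, config.stem_channels, 3, bias))
    prev = config.stem_channels
    for fc in config.fire_configs:
        add(conv_param_count(prev, fc.squeeze_1x1, 1, bias))
        add(conv_param_count(fc.squeeze_1x1, fc.expand_1x1, 1, bias))
        add(conv_param_count(fc.squeeze_1x1, fc.expand_3x3, 3, bias))
        prev = fc.out_channels
    return ParamCount(weights, biases)


def init_weights(config: ExtractorConfig, rng: np.random.Generator | None = None) -> dict[str, np.ndarray]:
    """Seeded He-uniform initialization of every convolution; zero biases."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    w: dict[str, np.ndarray] = {}
    in_ch = config.input_size[2]
    w["stem_w"] = _nn.he_uniform((config.stem_channels, in_ch, 3, 3), in_ch * 9, rng)
    w["stem_b"] = np.zeros(config.stem_channels)
    prev = config.stem_channels
    for i, fc in enumerate(config.fire_configs):
        w[f"fire{i}_squeeze_w"] = _nn.he_uniform((fc.squeeze_1x1, prev, 1, 1), prev, rng)
        w[f"fire{i}_squeeze_b"] = np.zeros(fc.squeeze_1x1)
        w[f"fire{i}_e1_w"] = _nn.he_uniform((fc.expand_1x1, fc.squeeze_1x1, 1, 1), fc.squeeze_1x1, rng)
        w[f"fire{i}_e1_b"] = np.zeros(fc.expand_1x1)
        w[f"fire{i}_e3_w"] = _nn.he_uniform((fc.expand_3x3, fc.squeeze_1x1, 3, 3), fc.squeeze_1x1 * 9, rng)
        w[f"fire{i}_e3_b"] = np.zeros(fc.expand_3x3)
        prev = fc.out_channels
    return w


def fire_forward(x: np.ndarray, config: FireConfig, weights: dict[str, np.ndarray],
                 prefix: str = "", cache: dict | None = None) -> np.ndarray:
    """One fire module: squeeze (1x1, ReLU) -> parallel expand 1x1 / 3x3 -> concat -> ReLU.

    ``x`` is ``(N, C, H, W)`` or a single ``(C, H, W)`` activation.  Spatial
    size is preserved; output channels = ``expand_1x1 + expand_3x3``.
    """
    single = x.ndim == 3
    if single:
        x = x[None]
    sw, sb = weights[f"{prefix}squeeze_w"], weights[f"{prefix}squeeze_b"]
    e1w, e1b = weights[f"{prefix}e1_w"], weights[f"{prefix}e1_b"]
    e3w, e3b = weights[f"{prefix}e3_w"], weights[f"{prefix}e3_b"]
    if sw.shape[0] != config.squeeze_1x1 or e1w.shape[0] != config.expand_1x1 \
            or e3w.shape[0] != config.expand_3x3:
        raise StructuralError("fire weights inconsistent with FireConfig")
    sz = _nn.conv2d(x, sw, sb)
    sa = _nn.relu(sz)
    e1 = _nn.conv2d(sa, e1w, e1b)
    e3 = _nn.conv2d(sa, e3w, e3b)
    cz = np.concatenate([e1, e3], axis=1)
    out = _nn.relu(cz)
    if cache is not None:
        cache[prefix] = (x, sz, sa, cz)
    return out[0] if single else out


def _fire_backward(config, weights, prefix, cache, grad_out, grads):
    x, sz, sa, cz = cache[prefix]
    g = _nn.relu_backward(cz, grad_out)
    ge1, ge3 = g[:, : config.expand_1x1], g[:, config.expand_1x1:]
    gsa1, gw1, gb1 = _nn.conv2d_backward(sa, weights[f"{prefix}e1_w"], ge1)
    gsa3, gw3, gb3 = _nn.conv2d_backward(sa, weights[f"{prefix}e3_w"], ge3)
    grads[f"{prefix}e1_w"], grads[f"{prefix}e1_b"] = gw1, gb1
    grads[f"{prefix}e3_w"], grads[f"{prefix}e3_b"] = gw3, gb3
    gsz = _nn.relu_backward(sz, gsa1 + gsa3)
    gx, gws, gbs = _nn.conv2d_backward(x, weights[f"{prefix}squeeze_w"], gsz)
    grads[f"{prefix}squeeze_w"], grads[f"{prefix}squeeze_b"] = gws, gbs
    return gx


def _forward(x, config: ExtractorConfig, weights, cache: dict | None = None):
    """Full forward pass to pooled features; optionally records a cache."""
    sz = _nn.conv2d(x, weights["stem_w"], weights["stem_b"])
    a = _nn.relu(sz)
    if cache is not None:
        cache["stem"] = (x, sz)
        cache["pools"] = {}
    for i, fc in enumerate(config.fire_configs):
        a = fire_forward(a, fc, weights, prefix=f"fire{i}_", cache=cache)
        if i in config.pool_positions:
            if cache is not None:
                cache["pools"][i] = a
            a = _nn.maxpool2(a)
    if cache is not None:
        cache["pre_gap"] = a
    return _nn.global_avg_pool(a)


def _backward(config: ExtractorConfig, weights, cache, grad_feat):
    grads: dict[str, np.ndarray] = {}
    g = _nn.global_avg_pool_backward(cache["pre_gap"], grad_feat)
    for i in reversed(range(len(config.fire_configs))):
        if i in config.pool_positions:
            g = _nn.maxpool2_backward(cache["pools"][i], g)
        g = _fire_backward(config.fire_configs[i], weights, f"fire{i}_", cache, g, grads)
    x, sz = cache["stem"]
    g = _nn.relu_backward(sz, g)
    _, gw, gb = _nn.conv2d_backward(x, weights["stem_w"], g)
    grads["stem_w"], grads["stem_b"] = gw, gb
    return grads


def _stack_images(images, config: ExtractorConfig) -> np.ndarray:
    h, w, c = config.input_size
    arrs = []
    for im in images:
        a = np.asarray(im, dtype=np.float64)
        if a.ndim == 2:
            a = a[None]
        elif a.ndim == 3 and a.shape[2] in (1, 3):
            a = np.moveaxis(a, 2, 0)
        if a.shape != (c, h, w):
            raise StructuralError(
                f"image shape {a.shape} does not match extractor input {(c, h, w)}"
            )
        if a.max() > 1.0:
            a = a / 255.0
        arrs.append(a)
    return np.stack(arrs)


def extract_features(images, config: ExtractorConfig, weights) -> np.ndarray:
    """Map images to a ``(n_images, feature_dim)`` matrix.

    Deterministic for fixed weights; row ``i`` corresponds to image ``i``.
    Integer images are rescaled to [0, 1] before the stem.
    """
    x = _stack_images(images, config)
    feats = np.empty((x.shape[0], config.feature_dim))
    for start in range(0, x.shape[0], 64):  # bound peak memory
        feats[start:start + 64] = _forward(x[start:start + 64], config, weights)
    return feats


def train_extractor(
    images,
    labels,
    config: ExtractorConfig,
    epochs: int = 5,
    lr: float = 0.01,
    batch_size: int = 16,
    n_classes: int = 2,
    seed: int = 0,
    weights: dict[str, np.ndarray] | None = None,
    return_head: bool = False,
):
    """Supervised training with a temporary softmax head.

    By default the head is discarded after training and only the
    convolutional weights are returned (plus the per-epoch loss history);
    ``return_head=True`` additionally returns the head ``(W, b)`` so the
    caller can score held-out images.  Optimization uses the Adamax rule
    throughout.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=np.int64)
    x = _stack_images(images, config)
    if weights is None:
        weights = init_weights(config, rng)
    else:
        weights = {k: v.copy() for k, v in weights.items()}
    head_w = _nn.he_uniform((config.feature_dim, n_classes), config.feature_dim, rng)
    head_b = np.zeros(n_classes)
    params = dict(weights)
    params["head_w"], params["head_b"] = head_w, head_b
    opt = AdamaxOptimizer(params, lr=lr)
    losses = []
    n = x.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            cache: dict = {}
            feats = _forward(x[idx], config, params, cache)
            logits = feats @ params["head_w"] + params["head_b"]
            loss, glog = _nn.softmax_xent(logits, labels[idx])
            grads = _backward(config, params, cache, glog @ params["head_w"].T)
            grads["head_w"] = feats.T @ glog
            grads["head_b"] = glog.sum(axis=0)
            opt.step(params, grads)
            epoch_loss += loss * len(idx)
        losses.append(epoch_loss / n)
    conv = {k: v for k, v in params.items() if not k.startswith("head_")}
    if return_head:
        return conv, losses, (params["head_w"], params["head_b"])
    return conv, losses
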