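"""The lightweight five-level 3D Inception U-Net.

Each network level applies one Inception-style block: three parallel
convolutional towers with 1x1x1, 3x3x3 and 5x5x5 kernels whose outputs are
concatenated along channels, so every level sees fine, medium and coarse
spatial context at once. The 3x3x3 and 5x5x5 towers are preceded by 1x1x1
bottleneck reductions, which is what keeps the model light. The encoder
downsamples with 2x2x2 max-pooling between its five levels; the decoder
mirrors it with 2x upsampling, concatenates the matching encoder skip and
applies another Inception block; a 1x1x1 convolution plus per-voxel softmax
produces 4-class probabilities at full input resolution.

Every convolution is bias-free and followed by batch normalization and ReLU,
except the classification head (bias, softmax). The network is fully
convolutional: any spatial shape divisible by 2^(depth-1) works.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (Adam, BatchNorm3d, Conv3d, Layer, MaxPool3d, Parameter,
                 ReLU, Sequential, Softmax, Upsample3d)

#: Encoder block output widths, shallowest to deepest. Not published for the
#: original network; this schedule lands in the low millions of parameters.
DEFAULT_LEVEL_WIDTHS = (32, 64, 128, 256, 320)


@dataclass
class InceptionBlockConfig:
    """Tower widths of one Inception block.

    ``c1``/``c3``/``c5`` are the output channels of the 1x1x1, 3x3x3 and
    5x5x5 towers; ``reduce3``/``reduce5`` are the 1x1x1 bottleneck widths in
    front of the larger kernels.
    """

    c1: int
    c3: int
    c5: int
    reduce3: int
    reduce5: int

    def __post_init__(self):
        for name in ("c1", "c3", "c5", "reduce3", "reduce5"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @property
    def out_channels(self) -> int:
        return self.c1 + self.c3 + self.c5

    @classmethod
    def from_width(cls, out_channels: int) -> "InceptionBlockConfig":
        """Split a block width (1/4, 1/2, 1/4) among towers, with 1/4-width
        bottlenecks."""
        q = max(1, out_channels // 4)
        return cls(c1=q, c3=out_channels - 2 * q, c5=q, reduce3=q, reduce5=q)


def _default_blocks() -> list:
    return [InceptionBlockConfig.from_width(w) for w in DEFAULT_LEVEL_WIDTHS]


@dataclass
class ArchitectureConfig:
    """Depth-5 Inception U-Net description; all widths configurable."""

    level_blocks: list = field(default_factory=_default_blocks)
    n_classes: int = 4
    in_channels: int = 4
    upsample_mode: str = "nearest_conv"

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("need at least 2 levels")
        if self.upsample_mode not in ("nearest_conv", "transposed"):
            raise ValueError(f"unknown upsample_mode {self.upsample_mode!r}")

    @property
    def depth(self) -> int:
        return len(self.level_blocks)

    @property
    def downsample_factor(self) -> int:
        return 2 ** (self.depth - 1)

    @classmethod
    def from_widths(cls, widths, **kwargs) -> "ArchitectureConfig":
        return cls(level_blocks=[InceptionBlockConfig.from_width(w) for w in widths],
                   **kwargs)

    def to_dict(self) -> dict:
        return {
            "level_widths": [b.out_channels for b in self.level_blocks],
            "level_blocks": [vars(b).copy() for b in self.level_blocks],
            "n_classes": self.n_classes,
            "in_channels": self.in_channels,
            "upsample_mode": self.upsample_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureConfig":
        if "level_blocks" in d and d["level_blocks"] and isinstance(d["level_blocks"][0], dict):
            blocks = [InceptionBlockConfig(**b) for b in d["level_blocks"]]
        else:
            blocks = [InceptionBlockConfig.from_width(w) for w in d["level_widths"]]
        return cls(level_blocks=blocks,
                   n_classes=d.get("n_classes", 4),
                   in_channels=d.get("in_channels", 4),
                   upsample_mode=d.get("upsample_mode", "nearest_conv"))


def _conv_bn_relu(cin: int, cout: int, k: int, rng) -> Sequential:
    return Sequential(Conv3d(cin, cout, k, rng), BatchNorm3d(cout), ReLU())


class InceptionBlock(Layer):
    """Three parallel towers (1x, reduce+3x, reduce+5x) concatenated."""

    def __init__(self, cfg: InceptionBlockConfig, in_channels: int, rng):
        self.cfg = cfg
        self.in_channels = in_channels
        self.tower1 = _conv_bn_relu(in_channels, cfg.c1, 1, rng)
        self.tower3 = Sequential(
            *_conv_bn_relu(in_channels, cfg.reduce3, 1, rng).layers,
            *_conv_bn_relu(cfg.reduce3, cfg.c3, 3, rng).layers)
        self.tower5 = Sequential(
            *_conv_bn_relu(in_channels, cfg.reduce5, 1, rng).layers,
            *_conv_bn_relu(cfg.reduce5, cfg.c5, 5, rng).layers)

    @property
    def out_channels(self) -> int:
        return self.cfg.out_channels

    def parameters(self) -> list[Parameter]:
        return (self.tower1.parameters() + self.tower3.parameters()
                + self.tower5.parameters())

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return np.concatenate([self.tower1.forward(x, training),
                               self.tower3.forward(x, training),
                               self.tower5.forward(x, training)], axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        c1, c3 = self.cfg.c1, self.cfg.c3
        g1 = self.tower1.backward(np.ascontiguousarray(grad[..., :c1]))
        g3 = self.tower3.backward(np.ascontiguousarray(grad[..., c1:c1 + c3]))
        g5 = self.tower5.backward(np.ascontiguousarray(grad[..., c1 + c3:]))
        return g1 + g3 + g5


class PixelShuffleUpsample(Layer):
    """Transposed-convolution-equivalent 2x upsampling.

    A 1x1x1 convolution to ``out_channels * 8`` followed by rearranging the 8
    channel groups into a 2x2x2 spatial block — algebraically identical to a
    kernel-2 stride-2 transposed convolution.
    """

    def __init__(self, in_channels: int, out_channels: int, rng):
        self.out_channels = out_channels
        self.conv = Conv3d(in_channels, out_channels * 8, 1, rng)

    def parameters(self) -> list[Parameter]:
        return self.conv.parameters()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        y = self.conv.forward(x, training)
        n, d, h, w, _ = y.shape
        c = self.out_channels
        y = (y.reshape(n, d, h, w, 2, 2, 2, c)
              .transpose(0, 1, 4, 2, 5, 3, 6, 7)
              .reshape(n, 2 * d, 2 * h, 2 * w, c))
        return np.ascontiguousarray(y)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, d2, h2, w2, c = grad.shape
        d, h, w = d2 // 2, h2 // 2, w2 // 2
        g = (grad.reshape(n, d, 2, h, 2, w, 2, c)
                 .transpose(0, 1, 3, 5, 2, 4, 6, 7)
                 .reshape(n, d, h, w, 8 * c))
        return self.conv.backward(np.ascontiguousarray(g))


class LIUNet(Layer):
    """Five-level 3D Inception U-Net with softmax head."""

    def __init__(self, cfg: ArchitectureConfig | None = None, seed: int = 0):
        self.cfg = cfg if cfg is not None else ArchitectureConfig()
        rng = np.random.default_rng(seed)
        depth = self.cfg.depth
        widths = [b.out_channels for b in self.cfg.level_blocks]

        self.enc_blocks: list[InceptionBlock] = []
        cin = self.cfg.in_channels
        for lvl in range(depth):
            block = InceptionBlock(self.cfg.level_blocks[lvl], cin, rng)
            self.enc_blocks.append(block)
            cin = block.out_channels
        self.pools = [MaxPool3d() for _ in range(depth - 1)]

        # decoder level lvl (depth-2 .. 0): upsample deeper features to the
        # skip's width, concatenate, then one Inception block at that width
        self.ups: list[Sequential] = []
        self.dec_blocks: list[InceptionBlock] = []
        below = widths[-1]
        for lvl in range(depth - 2, -1, -1):
            target = widths[lvl]
            if self.cfg.upsample_mode == "transposed":
                up = Sequential(PixelShuffleUpsample(below, target, rng),
                                BatchNorm3d(target), ReLU())
            else:
                up = Sequential(Upsample3d(), Conv3d(below, target, 1, rng),
                                BatchNorm3d(target), ReLU())
            self.ups.append(up)
            block = InceptionBlock(self.cfg.level_blocks[lvl], 2 * target, rng)
            self.dec_blocks.append(block)
            below = block.out_channels

        self.head = Conv3d(below, self.cfg.n_classes, 1, rng, bias=True)
        self.softmax = Softmax()
        self._skip_widths = widths

    # -- plumbing ---------------------------------------------------------

    def _modules(self) -> list[Layer]:
        return (self.enc_blocks + self.pools + self.ups + self.dec_blocks
                + [self.head, self.softmax])

    def parameters(self) -> list[Parameter]:
        out = []
        for m in self.enc_blocks:
            out += m.parameters()
        for m in self.ups:
            out += m.parameters()
        for m in self.dec_blocks:
            out += m.parameters()
        out += self.head.parameters()
        return out

    def _batchnorms(self) -> list[BatchNorm3d]:
        bns = []

        def walk(layer):
            if isinstance(layer, BatchNorm3d):
                bns.append(layer)
            elif isinstance(layer, Sequential):
                for sub in layer.layers:
                    walk(sub)
            elif isinstance(layer, InceptionBlock):
                walk(layer.tower1)
                walk(layer.tower3)
                walk(layer.tower5)

        for m in self.enc_blocks + self.ups + self.dec_blocks:
            walk(m)
        return bns

    def state_arrays(self) -> dict:
        """Flat name->array mapping of all weights and BN running stats."""
        state = {f"param_{i:04d}": p.value for i, p in enumerate(self.parameters())}
        for i, bn in enumerate(self._batchnorms()):
            state[f"bnmean_{i:04d}"] = bn.running_mean
            state[f"bnvar_{i:04d}"] = bn.running_var
        return state

    def load_state_arrays(self, state: dict) -> None:
        for i, p in enumerate(self.parameters()):
            arr = np.asarray(state[f"param_{i:04d}"], dtype=np.float32)
            if arr.shape != p.value.shape:
                raise ValueError(
                    f"param_{i:04d}: shape {arr.shape} != expected {p.value.shape}")
            p.value = arr.copy()
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean = np.asarray(state[f"bnmean_{i:04d}"], dtype=np.float32).copy()
            bn.running_var = np.asarray(state[f"bnvar_{i:04d}"], dtype=np.float32).copy()

    # -- forward / backward ------------------------------------------------

    def _validate_input(self, x: np.ndarray) -> None:
        if x.ndim != 5:
            raise ValueError(f"expected (N,D,H,W,C) input, got {x.ndim}D")
        if x.shape[-1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} channels, got {x.shape[-1]}")
        f = self.cfg.downsample_factor
        if any(s % f for s in x.shape[1:4]):
            raise ValueError(
                f"spatial dims {x.shape[1:4]} must be divisible by {f} "
                f"for a depth-{self.cfg.depth} network")

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._validate_input(x)
        x = np.ascontiguousarray(x)
        if x.dtype not in (np.float32, np.float64):
            x = x.astype(np.float32)
        depth = self.cfg.depth
        skips = []
        for lvl in range(depth):
            x = self.enc_blocks[lvl].forward(x, training)
            if lvl < depth - 1:
                skips.append(x)
                x = self.pools[lvl].forward(x, training)
        for i, lvl in enumerate(range(depth - 2, -1, -1)):
            x = self.ups[i].forward(x, training)
            x = np.concatenate([skips[lvl], x], axis=-1)
            x = self.dec_blocks[i].forward(x, training)
        logits = self.head.forward(x, training)
        return self.softmax.forward(logits, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        depth = self.cfg.depth
        grad = self.head.backward(self.softmax.backward(grad))
        skip_grads: dict = {}
        for i in range(depth - 2, -1, -1):  # reverse of forward decoder order
            lvl = (depth - 2) - i
            grad = self.dec_blocks[i].backward(grad)
            w = self._skip_widths[lvl]
            skip_grads[lvl] = np.ascontiguousarray(grad[..., :w])
            grad = self.ups[i].backward(np.ascontiguousarray(grad[..., w:]))
        grad = self.enc_blocks[depth - 1].backward(grad)
        for lvl in range(depth - 2, -1, -1):
            grad = self.pools[lvl].backward(grad)
            grad = grad + skip_grads[lvl]
            grad = self.enc_blocks[lvl].backward(grad)
        return grad


def build_inception_block(cfg: InceptionBlockConfig, in_channels: int,
                          seed: int = 0) -> InceptionBlock:
    return InceptionBlock(cfg, in_channels, np.random.default_rng(seed))


def build_liunet(cfg: ArchitectureConfig | None = None, seed: int = 0) -> LIUNet:
    return LIUNet(cfg, seed=seed)


def count_parameters(network: Layer) -> int:
    """Exact count of trainable scalars (weights, biases, BN gamma/beta)."""
    return int(sum(p.size for p in network.parameters()))


@dataclass
class ModelSummary:
    param_count: int
    param_millions: float
    approx_gflops: float
    output_shape: tuple


def _conv_layers_with_scale(model: LIUNet):
    """Yield (conv, spatial_downsample_exponent) pairs in forward order."""
    depth = model.cfg.depth

    def convs_of(layer):
        if isinstance(layer, Conv3d):
            yield layer
        elif isinstance(layer, PixelShuffleUpsample):
            yield layer.conv
        elif isinstance(layer, Sequential):
            for sub in layer.layers:
                yield from convs_of(sub)
        elif isinstance(layer, InceptionBlock):
            for tower in (layer.tower1, layer.tower3, layer.tower5):
                yield from convs_of(tower)

    for lvl in range(depth):
        for c in convs_of(model.enc_blocks[lvl]):
            yield c, lvl
    for i, lvl in enumerate(range(depth - 2, -1, -1)):
        # the upsample path's conv runs at the coarser grid for pixel-shuffle,
        # at the finer grid for nearest+conv
        up_scale = lvl + 1 if model.cfg.upsample_mode == "transposed" else lvl
        for c in convs_of(model.ups[i]):
            yield c, up_scale
        for c in convs_of(model.dec_blocks[i]):
            yield c, lvl
    yield model.head, 0


def estimate_flops(model: LIUNet, input_shape=(128, 128, 128)) -> float:
    """Analytic forward-pass FLOPs in GFLOPs at the given spatial shape.

    Counts multiply-accumulates of all convolutions times two; batch norm,
    activations and pooling are ignored. The number is convention-dependent
    (frameworks disagree on what to count), so treat it as a scale indicator
    rather than an exact figure.
    """
    d, h, w = input_shape
    total = 0.0
    for conv, scale in _conv_layers_with_scale(model):
        voxels = (d >> scale) * (h >> scale) * (w >> scale)
        macs = voxels * conv.in_channels * conv.kernel_size ** 3 * conv.out_channels
        total += 2.0 * macs
    return total / 1e9


def summarize(cfg: ArchitectureConfig | None = None,
              input_shape=(128, 128, 128), seed: int = 0) -> ModelSummary:
    """Instantiate the architecture and report size/cost at ``input_shape``."""
    model = build_liunet(cfg, seed=seed)
    n = count_parameters(model)
    return ModelSummary(
        param_count=n,
        param_millions=n / 1e6,
        approx_gflops=estimate_flops(model, input_shape),
        output_shape=tuple(input_shape) + (model.cfg.n_classes,),
    )
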