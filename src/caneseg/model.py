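"""MDSC-DeepLabv3+ — a lightweight encoder-decoder segmentation network.

The encoder is a truncated MobileNetv2 (first 8 layers, up to the 320-channel
stage) whose deepest stages trade stride for dilation so the output stride
stays at 16, followed by an atrous spatial pyramid pooling head.  Two
optional enhancements give the full model its name:

* ``ASPP_DS`` — the pyramid uses compact dilation rates (4, 8, 12) with
  depthwise-separable branches, and adds a *strip pooling* branch whose
  1xW and Hx1 mean-pooling kernels capture long-range context along each
  spatial axis, fused into a sigmoid gate on the input.
* *Coordinate attention* — factorized global pooling along height and width
  produces two directional attention maps that re-weight features, applied
  after the ASPP fusion and/or before the decoder's low-level projection.

The decoder follows DeepLabv3+: the high-level features are upsampled x4,
concatenated with a 1x1-projected low-level (stride-4, 24-channel) feature
map, refined with a depthwise-separable 3x3 convolution, classified, and
upsampled x4 back to input resolution.

Seven ablation variants (``base``, ``M``, ``MDS``, ``MC1``, ``MC2``, ``MC``,
``MDSC``) toggle the enhancements; ``make_variant`` builds their configs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .autograd import (
    Adam,  # noqa: F401  (re-exported for training code)
    BatchNorm2d,
    Conv2d,
    Module,
    ReLU,
    ReLU6,
    Sequential,
    Tensor,
    concat,
    no_grad,
    relu,
    sigmoid,
    upsample_bilinear,
)

__all__ = [
    "BackboneConfig",
    "ModelConfig",
    "SegmentationOutput",
    "InvertedResidual",
    "MobileNetV2Backbone",
    "StripPooling",
    "CoordinateAttention",
    "ASPP",
    "MDSCDeepLabV3Plus",
    "build_model",
    "make_variant",
    "VARIANT_NAMES",
    "count_parameters",
    "count_flops",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: (expansion t, out_channels c, repeats n, first stride s, dilation r)
Stage = tuple[int, int, int, int, int]

_IMPROVED_STAGES: tuple[Stage, ...] = (
    (1, 16, 1, 1, 1),
    (6, 24, 2, 2, 1),
    (6, 32, 3, 2, 1),
    (6, 64, 4, 2, 1),
    (6, 96, 3, 1, 1),
    (6, 160, 3, 1, 2),
    (6, 320, 1, 1, 5),
)

# stock MobileNetv2 (first 8 layers): the 160-channel stage keeps stride 2
# and no stage is dilated
_ORIGINAL_STAGES: tuple[Stage, ...] = (
    (1, 16, 1, 1, 1),
    (6, 24, 2, 2, 1),
    (6, 32, 3, 2, 1),
    (6, 64, 4, 2, 1),
    (6, 96, 3, 1, 1),
    (6, 160, 3, 2, 1),
    (6, 320, 1, 1, 1),
)


@dataclass(frozen=True)
class BackboneConfig:
    """Truncated MobileNetv2 stage plan.

    ``stages`` holds (t, c, n, s, r) per stage; only the first block of a
    stage uses stride ``s``, repeats use stride 1.  ``low_level_stage`` is
    the index of the 24-channel stage whose output feeds the decoder.
    """

    stages: tuple[Stage, ...] = _IMPROVED_STAGES
    stem_channels: int = 32
    low_level_stage: int = 1

    @classmethod
    def improved(cls) -> "BackboneConfig":
        return cls(stages=_IMPROVED_STAGES)

    @classmethod
    def original(cls) -> "BackboneConfig":
        return cls(stages=_ORIGINAL_STAGES)

    def with_output_stride(self, output_stride: int) -> "BackboneConfig":
        """Convert to output stride 8 by trading the 64-channel stage's stride
        for dilation (stride-16 plans are returned unchanged)."""
        if output_stride == 16:
            return self
        if output_stride != 8:
            raise ValueError(f"output_stride must be 8 or 16, got {output_stride}")
        stages = []
        converted = False
        for t, c, n, s, r in self.stages:
            if c == 64 and s == 2:
                stages.append((t, c, n, 1, 2))
                converted = True
            elif converted:
                stages.append((t, c, n, s, r * 2))
            else:
                stages.append((t, c, n, s, r))
        return BackboneConfig(tuple(stages), self.stem_channels, self.low_level_stage)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture variant description."""

    num_classes: int = 5
    input_size: int = 512
    aspp_dilations: tuple[int, int, int] = (4, 8, 12)
    aspp_channels: int = 256
    low_level_channels: int = 48
    use_improved_backbone: bool = True
    use_strip_pooling: bool = True
    ca_before_decoder: bool = True
    ca_after_aspp: bool = True
    output_stride: int = 16

    def __post_init__(self) -> None:
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        d = self.aspp_dilations
        if not (0 < d[0] < d[1] < d[2]):
            raise ValueError(f"aspp_dilations must be strictly increasing positive, got {d}")
        if self.output_stride not in (8, 16):
            raise ValueError("output_stride must be 8 or 16")

    def to_yaml(self) -> str:
        import yaml

        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelConfig":
        import yaml

        raw = yaml.safe_load(text)
        raw["aspp_dilations"] = tuple(raw["aspp_dilations"])
        return cls(**raw)


@dataclass
class SegmentationOutput:
    """Per-class scores at input resolution and their argmax label map."""

    scores: np.ndarray  # (N, num_classes, H, W)
    labels: np.ndarray  # (N, H, W) int

    def __post_init__(self) -> None:
        assert self.labels.shape == (self.scores.shape[0], *self.scores.shape[2:])


VARIANT_NAMES = ("base", "M", "MDS", "MC1", "MC2", "MC", "MDSC")

_PLAIN_ASPP = (6, 12, 18)


def make_variant(name: str, num_classes: int = 5, input_size: int = 512) -> ModelConfig:
    """Config for one of the seven ablation variants.

    ``base`` is plain DeepLabv3+ on a stock MobileNetv2; ``M`` dilates the
    deep backbone stages; ``MDS`` adds the strip-pooled compact-dilation
    pyramid; ``MC1``/``MC2``/``MC`` add coordinate attention before the
    decoder / after the pyramid / both (on ``M``); ``MDSC`` enables
    everything.
    """
    common = dict(num_classes=num_classes, input_size=input_size)
    table = {
        "base": dict(use_improved_backbone=False, use_strip_pooling=False,
                     ca_before_decoder=False, ca_after_aspp=False,
                     aspp_dilations=_PLAIN_ASPP),
        "M": dict(use_improved_backbone=True, use_strip_pooling=False,
                  ca_before_decoder=False, ca_after_aspp=False,
                  aspp_dilations=_PLAIN_ASPP),
        "MDS": dict(use_improved_backbone=True, use_strip_pooling=True,
                    ca_before_decoder=False, ca_after_aspp=False),
        "MC1": dict(use_improved_backbone=True, use_strip_pooling=False,
                    ca_before_decoder=True, ca_after_aspp=False,
                    aspp_dilations=_PLAIN_ASPP),
        "MC2": dict(use_improved_backbone=True, use_strip_pooling=False,
                    ca_before_decoder=False, ca_after_aspp=True,
                    aspp_dilations=_PLAIN_ASPP),
        "MC": dict(use_improved_backbone=True, use_strip_pooling=False,
                   ca_before_decoder=True, ca_after_aspp=True,
                   aspp_dilations=_PLAIN_ASPP),
        "MDSC": dict(use_improved_backbone=True, use_strip_pooling=True,
                     ca_before_decoder=True, ca_after_aspp=True),
    }
    if name not in table:
        raise ValueError(f"unknown variant {name!r}; valid names: {', '.join(VARIANT_NAMES)}")
    return ModelConfig(**common, **table[name])


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _conv_bn(in_ch, out_ch, k, stride=1, dilation=1, groups=1, act="relu", rng=None) -> Sequential:
    layers: list[Module] = [
        Conv2d(in_ch, out_ch, k, stride=stride, dilation=dilation, groups=groups, rng=rng),
        BatchNorm2d(out_ch),
    ]
    if act == "relu":
        layers.append(ReLU())
    elif act == "relu6":
        layers.append(ReLU6())
    elif act != "linear":
        raise ValueError(act)
    return Sequential(*layers)


class InvertedResidual(Module):
    """MobileNetv2 inverted residual: expand -> depthwise -> linear project.

    The 1x1 expansion widens to ``t * c_in`` channels (omitted when t == 1),
    the 3x3 depthwise convolution carries stride/dilation, and the linear
    1x1 projection compresses to ``c_out``.  A shortcut is added iff
    stride == 1 and c_in == c_out.
    """

    def __init__(self, in_ch: int, out_ch: int, t: int, stride: int = 1,
                 dilation: int = 1, rng=None):
        super().__init__()
        if stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {stride}")
        if t < 1:
            raise ValueError(f"expansion factor must be >= 1, got {t}")
        if stride == 2 and dilation > 1:
            raise ValueError("stride 2 with dilation > 1 is undefined for this block")
        hidden = t * in_ch
        self.use_shortcut = stride == 1 and in_ch == out_ch
        self.expand = _conv_bn(in_ch, hidden, 1, act="relu6", rng=rng) if t > 1 else None
        self.depthwise = _conv_bn(hidden, hidden, 3, stride=stride, dilation=dilation,
                                  groups=hidden, act="relu6", rng=rng)
        self.project = _conv_bn(hidden, out_ch, 1, act="linear", rng=rng)
        self.hidden_channels = hidden

    def forward(self, x: Tensor) -> Tensor:
        y = x if self.expand is None else self.expand(x)
        y = self.project(self.depthwise(y))
        return x + y if self.use_shortcut else y


class MobileNetV2Backbone(Module):
    """Truncated MobileNetv2 feature extractor.

    Maps an NCHW image to ``(low_level, high_level)`` feature maps: the
    24-channel stage output at stride 4 and the 320-channel stage output at
    the configured output stride.
    """

    def __init__(self, config: BackboneConfig | None = None, rng=None):
        super().__init__()
        self.config = config or BackboneConfig.improved()
        self.stem = _conv_bn(3, self.config.stem_channels, 3, stride=2, act="relu6", rng=rng)
        self.stages: list[Sequential] = []
        in_ch = self.config.stem_channels
        for t, c, n, s, r in self.config.stages:
            blocks = []
            for i in range(n):
                blocks.append(InvertedResidual(in_ch, c, t, stride=s if i == 0 else 1,
                                               dilation=r, rng=rng))
                in_ch = c
            self.stages.append(Sequential(*blocks))
        self.out_channels = in_ch
        self.low_level_channels = self.config.stages[self.config.low_level_stage][1]

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        y = self.stem(x)
        low = None
        for i, stage in enumerate(self.stages):
            y = stage(y)
            if i == self.config.low_level_stage:
                low = y
        return low, y


class StripPooling(Module):
    """Strip pooling gate.

    The input is mean-pooled to CxHx1 and Cx1xW strips, each expanded with a
    kernel-3 1-D convolution along its long axis, broadcast-summed back to
    CxHxW, fused by a 1x1 convolution and turned into a sigmoid gate that
    scales the input elementwise.  Output shape equals input shape.
    """

    def __init__(self, channels: int, rng=None):
        super().__init__()
        self.conv_h = Conv2d(channels, channels, (3, 1), rng=rng)
        self.conv_w = Conv2d(channels, channels, (1, 3), rng=rng)
        self.fuse = Conv2d(channels, channels, 1, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        yh = self.conv_h(x.mean(axis=3, keepdims=True))  # (N, C, H, 1)
        yv = self.conv_w(x.mean(axis=2, keepdims=True))  # (N, C, 1, W)
        y = yh + yv  # broadcast to (N, C, H, W)
        return x * sigmoid(self.fuse(y))


class CoordinateAttention(Module):
    """Coordinate attention: directional pooling -> shared transform -> gates.

    Per-channel average pooling along width and height yields CxHx1 and
    Cx1xW encodings; these are concatenated along the strip axis, passed
    through a shared 1x1 convolution + batch norm + ReLU with channel
    reduction, split, and mapped by per-direction 1x1 convolutions and
    sigmoids into attention maps ``a_h`` (CxHx1) and ``a_w`` (Cx1xW).  The
    output is ``x * a_h * a_w`` (broadcast).
    """

    def __init__(self, channels: int, reduction: int = 32, rng=None):
        super().__init__()
        mid = max(8, channels // reduction)
        self.shared = _conv_bn(channels, mid, 1, act="relu", rng=rng)
        self.attn_h = Conv2d(mid, channels, 1, bias=True, rng=rng)
        self.attn_w = Conv2d(mid, channels, 1, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        ph = x.mean(axis=3, keepdims=True)  # (N, C, H, 1)
        pw = x.mean(axis=2, keepdims=True).transpose((0, 1, 3, 2))  # (N, C, W, 1)
        y = self.shared(concat([ph, pw], axis=2))  # (N, mid, H+W, 1)
        yh = y[:, :, :H, :]
        yw = y[:, :, H:, :].transpose((0, 1, 3, 2))  # (N, mid, 1, W)
        a_h = sigmoid(self.attn_h(yh))  # (N, C, H, 1)
        a_w = sigmoid(self.attn_w(yw))  # (N, C, 1, W)
        return x * a_h * a_w


class ASPP(Module):
    """Atrous spatial pyramid pooling with optional strip-pooling branch.

    Branches: 1x1 convolution; three 3x3 depthwise-separable convolutions at
    the configured dilations; global average pooling broadcast back; and,
    when enabled, a strip-pooling gate followed by a 1x1 projection.  Branch
    outputs (``out_ch`` channels each) are concatenated and fused to
    ``out_ch`` by a 1x1 convolution.
    """

    def __init__(self, in_ch: int, out_ch: int, dilations: Sequence[int],
                 use_strip_pooling: bool, rng=None):
        super().__init__()
        self.conv1x1 = _conv_bn(in_ch, out_ch, 1, rng=rng)
        self.branches = []
        for d in dilations:
            self.branches.append(Sequential(
                _conv_bn(in_ch, in_ch, 3, dilation=d, groups=in_ch, rng=rng),
                _conv_bn(in_ch, out_ch, 1, rng=rng),
            ))
        self.pool_conv = _conv_bn(in_ch, out_ch, 1, rng=rng)
        self.strip = StripPooling(in_ch, rng=rng) if use_strip_pooling else None
        self.strip_proj = _conv_bn(in_ch, out_ch, 1, rng=rng) if use_strip_pooling else None
        n_branches = 2 + len(self.branches) + (1 if use_strip_pooling else 0)
        self.n_branches = n_branches
        self.project = _conv_bn(n_branches * out_ch, out_ch, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        feats = [self.conv1x1(x)]
        for b in self.branches:
            feats.append(b(x))
        pooled = self.pool_conv(x.mean(axis=(2, 3), keepdims=True))
        feats.append(pooled + Tensor(np.zeros_like(feats[0].data)))  # broadcast back
        if self.strip is not None:
            feats.append(self.strip_proj(self.strip(x)))
        return self.project(concat(feats, axis=1))


class MDSCDeepLabV3Plus(Module):
    """The full encoder-decoder segmentation model (any ablation variant)."""

    def __init__(self, config: ModelConfig | None = None, seed: int | None = None):
        super().__init__()
        self.config = config or ModelConfig()
        rng = np.random.default_rng(seed)
        bb_cfg = (BackboneConfig.improved() if self.config.use_improved_backbone
                  else BackboneConfig.original())
        bb_cfg = bb_cfg.with_output_stride(self.config.output_stride)
        self.backbone = MobileNetV2Backbone(bb_cfg, rng=rng)
        c = self.config.aspp_channels
        self.aspp = ASPP(self.backbone.out_channels, c, self.config.aspp_dilations,
                         self.config.use_strip_pooling, rng=rng)
        self.ca_encoder = (CoordinateAttention(c, rng=rng)
                           if self.config.ca_after_aspp else None)
        self.ca_low = (CoordinateAttention(self.backbone.low_level_channels, rng=rng)
                       if self.config.ca_before_decoder else None)
        low_ch = self.config.low_level_channels
        self.low_proj = _conv_bn(self.backbone.low_level_channels, low_ch, 1, rng=rng)
        fused = c + low_ch
        self.refine = Sequential(
            _conv_bn(fused, fused, 3, groups=fused, rng=rng),
            _conv_bn(fused, c, 1, rng=rng),
        )
        self.classifier = Conv2d(c, self.config.num_classes, 1, bias=True, rng=rng)

    def forward_scores(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        if H % 16 or W % 16:
            raise ValueError(
                f"input spatial size ({H}x{W}) must be divisible by 16; resize the image"
            )
        low, high = self.backbone(x)
        high = self.aspp(high)
        if self.ca_encoder is not None:
            high = self.ca_encoder(high)
        if self.ca_low is not None:
            low = self.ca_low(low)
        low = self.low_proj(low)
        lh, lw = low.shape[2], low.shape[3]
        high = upsample_bilinear(high, (lh, lw))
        y = self.refine(concat([low, high], axis=1))
        y = self.classifier(y)
        return upsample_bilinear(y, (H, W))

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_scores(x)

    def predict(self, images: np.ndarray) -> SegmentationOutput:
        """Inference on an NCHW float array; returns scores and argmax labels."""
        self.eval()
        with no_grad():
            scores = self.forward_scores(Tensor(images)).data
        return SegmentationOutput(scores=scores, labels=scores.argmax(axis=1))


def build_model(variant: str = "MDSC", num_classes: int = 5, input_size: int = 512,
                seed: int | None = None) -> MDSCDeepLabV3Plus:
    return MDSCDeepLabV3Plus(make_variant(variant, num_classes, input_size), seed=seed)


# ---------------------------------------------------------------------------
# accounting
# ---------------------------------------------------------------------------

def count_parameters(model: Module) -> int:
    """Total trainable weight elements."""
    return int(sum(p.data.size for p in model.parameters()))


_FLOP_TAPE: list[int] | None = None


def count_flops(model: MDSCDeepLabV3Plus, input_size: int = 512) -> int:
    """FLOPs of one forward pass at batch 1 on a 3 x size x size input.

    Convention: 2 FLOPs per multiply-accumulate; convolutions, linear maps
    and normalizations are counted (interpolation and elementwise gates are
    negligible and ignored).  Counted by replaying a forward pass and
    letting each layer report its cost at the spatial size it actually saw.
    """
    counted = 0
    originals = []

    def wrap(layer):
        orig = layer.forward

        def counted_forward(x, _layer=layer, _orig=orig):
            nonlocal counted
            counted += _layer.flops(x.shape[2], x.shape[3])
            return _orig(x)

        return orig, counted_forward

    for m in model.modules():
        if isinstance(m, (Conv2d, BatchNorm2d)):
            orig, new = wrap(m)
            originals.append((m, orig))
            m.forward = new
    try:
        was_training = model.training
        model.eval()
        with no_grad():
            model.forward_scores(Tensor(np.zeros((1, 3, input_size, input_size), np.float32)))
        if was_training:
            model.train()
    finally:
        for m, orig in originals:
            m.forward = orig
    return counted


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: MDSCDeepLabV3Plus, path) -> None:
    """Serialize weights (npz) with the model config as a JSON sidecar."""
    path = str(path)
    np.savez(path if path.endswith(".npz") else path + ".npz", **model.state_dict())
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json", "w", encoding="utf-8") as fh:
        json.dump(asdict(model.config), fh, indent=2)


def load_checkpoint(path) -> MDSCDeepLabV3Plus:
    path = str(path)
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json", encoding="utf-8") as fh:
        raw = json.load(fh)
    raw["aspp_dilations"] = tuple(raw["aspp_dilations"])
    model = MDSCDeepLabV3Plus(ModelConfig(**raw))
    with np.load(base + ".npz") as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
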