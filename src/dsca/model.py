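"""DSCA-PSPNet: dilated ResNet34 encoder + pyramid pooling decoder,
with D-scSE attention after every encoder stage and after the decoder's
feature concatenation.

Layout (input 3×512×512, output stride 8):

    stem   7×7/2 conv + BN + ReLU + 3×3/2 max-pool      -> 64×128×128
    stage1 3 residual blocks,  64 ch, stride 1          -> 64×128×128  + D-scSE
    stage2 4 residual blocks, 128 ch, stride 2          -> 128×64×64   + D-scSE
    stage3 6 residual blocks, 256 ch, dilation 2        -> 256×64×64   + D-scSE
    stage4 3 residual blocks, 512 ch, dilation 4        -> 512×64×64   + D-scSE
    PSP    bins (1,2,3,6), 1×1 conv to C/4 each, upsample, concat -> 1024×64×64
    D-scSE on the concatenated map
    head   3×3 conv + BN + ReLU -> 1×1 conv to 2 classes -> bilinear ×8

Stages 3–4 trade their stride for dilation, keeping the encoder's
parameter count identical to the plain ResNet34 while enlarging the
receptive field — the standard stride-8 arrangement for pyramid-pooling
decoders.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .attention import DscSE, dscse_param_count
from .nn import Tensor
from .nn import functional as F
from .seeds import derive_seed


@dataclass(frozen=True)
class BackboneSpec:
    """Configuration of the modified ResNet34 encoder."""

    stage_block_counts: tuple[int, int, int, int] = (3, 4, 6, 3)
    stage_channels: tuple[int, int, int, int] = (64, 128, 256, 512)
    stage_strides: tuple[int, int, int, int] = (1, 2, 1, 1)
    stage_dilations: tuple[int, int, int, int] = (1, 1, 2, 4)
    dscse_after_stage: tuple[bool, bool, bool, bool] = (True, True, True, True)
    in_channels: int = 3

    def validate(self) -> None:
        for name in ("stage_block_counts", "stage_channels", "stage_strides",
                     "stage_dilations", "dscse_after_stage"):
            if len(getattr(self, name)) != 4:
                raise ValueError(f"{name} must list exactly four stages")
        if any(d < 1 for d in self.stage_dilations):
            raise ValueError("dilations must be >= 1")
        if self.stage_dilations[0] != 1 or self.stage_dilations[1] != 1:
            raise ValueError("stages 1-2 must use dilation 1")


@dataclass(frozen=True)
class PyramidSpec:
    """Configuration of the pyramid pooling module."""

    bin_sizes: tuple[int, int, int, int] = (1, 2, 3, 6)

    def validate(self) -> None:
        if len(self.bin_sizes) != 4:
            raise ValueError("the pyramid pooling module has exactly 4 branches")
        if any(b < 1 for b in self.bin_sizes):
            raise ValueError("bin sizes must be >= 1")


@dataclass(frozen=True)
class ModelSpec:
    """Full model configuration (the 'pinned spec' for profiling)."""

    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    pyramid: PyramidSpec = field(default_factory=PyramidSpec)
    head_channels: int = 512
    num_classes: int = 2
    input_size: tuple[int, int] = (512, 512)
    decoder_dscse: bool = True

    def validate(self) -> None:
        self.backbone.validate()
        self.pyramid.validate()
        if self.head_channels < 1 or self.num_classes < 2:
            raise ValueError("head_channels >= 1 and num_classes >= 2 required")
        if self.backbone.stage_channels[-1] % 4 != 0:
            raise ValueError("encoder output channels must be divisible by 4")

    def without_attention(self) -> "ModelSpec":
        """The plain PSPNet-ResNet34 baseline (all D-scSE removed)."""
        bb = BackboneSpec(self.backbone.stage_block_counts, self.backbone.stage_channels,
                          self.backbone.stage_strides, self.backbone.stage_dilations,
                          (False, False, False, False), self.backbone.in_channels)
        return ModelSpec(bb, self.pyramid, self.head_channels, self.num_classes,
                         self.input_size, decoder_dscse=False)

    @staticmethod
    def reduced(input_size: tuple[int, int] = (64, 64)) -> "ModelSpec":
        """A narrow configuration for desk-scale (CPU) experiments.

        One block and an eighth of the channels per stage, and output
        stride 4 instead of 8 (stage 2 keeps stride 1): at 64-px tiles
        the stride-8 grid is too coarse to resolve field boundaries.
        """
        bb = BackboneSpec(stage_block_counts=(1, 1, 1, 1),
                          stage_channels=(16, 32, 64, 128),
                          stage_strides=(1, 1, 1, 1))
        return ModelSpec(backbone=bb, head_channels=64, input_size=input_size)

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "ModelSpec":
        bb = d.get("backbone", {})
        backbone = BackboneSpec(
            tuple(bb.get("stage_block_counts", (3, 4, 6, 3))),
            tuple(bb.get("stage_channels", (64, 128, 256, 512))),
            tuple(bb.get("stage_strides", (1, 2, 1, 1))),
            tuple(bb.get("stage_dilations", (1, 1, 2, 4))),
            tuple(bb.get("dscse_after_stage", (True, True, True, True))),
            int(bb.get("in_channels", 3)),
        )
        pyramid = PyramidSpec(tuple(d.get("pyramid", {}).get("bin_sizes", (1, 2, 3, 6))))
        return ModelSpec(backbone, pyramid, int(d.get("head_channels", 512)),
                         int(d.get("num_classes", 2)),
                         tuple(d.get("input_size", (512, 512))),
                         bool(d.get("decoder_dscse", True)))


class BasicBlock(nn.Module):
    """ResNet34 basic block; dilation replaces stride in the late stages."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, dilation: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, padding=dilation,
                               dilation=dilation, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, padding=dilation,
                               dilation=dilation, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down_conv = nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng)
            self.down_bn = nn.BatchNorm2d(out_ch)
            self.has_down = True
        else:
            self.has_down = False

    def forward(self, x: Tensor) -> Tensor:
        h = F.relu(self.bn1(self.conv1(x)))
        h = self.bn2(self.conv2(h))
        shortcut = self.down_bn(self.down_conv(x)) if self.has_down else x
        return F.relu(F.add(h, shortcut))


class Backbone(nn.Module):
    """Modified ResNet34: stem, four residual stages, optional D-scSE each."""

    def __init__(self, spec: BackboneSpec, seed: int = 0):
        super().__init__()
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(derive_seed(seed, "backbone"))
        c0 = spec.stage_channels[0]
        self.stem_conv = nn.Conv2d(spec.in_channels, c0, 7, stride=2, padding=3,
                                   bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(c0)
        self.pool = nn.MaxPool2d(3, 2, 1)
        in_ch = c0
        for s in range(4):
            blocks = []
            for b in range(spec.stage_block_counts[s]):
                stride = spec.stage_strides[s] if b == 0 else 1
                blocks.append(BasicBlock(in_ch, spec.stage_channels[s], stride,
                                         spec.stage_dilations[s], rng))
                in_ch = spec.stage_channels[s]
            setattr(self, f"stage{s + 1}", nn.Sequential(*blocks))
            attn = (DscSE(spec.stage_channels[s],
                          rng=np.random.default_rng(derive_seed(seed, "backbone", f"attn{s + 1}")))
                    if spec.dscse_after_stage[s] else nn.Identity())
            setattr(self, f"attn{s + 1}", attn)
        self.out_channels = in_ch

    def forward(self, x: Tensor) -> Tensor:
        h = self.pool(F.relu(self.stem_bn(self.stem_conv(x))))
        for s in range(1, 5):
            h = getattr(self, f"stage{s}")(h)
            h = getattr(self, f"attn{s}")(h)
        return h

    def stage_outputs(self, x: Tensor) -> list[Tensor]:
        """Per-stage (post-attention) activations, for inspection."""
        outs = []
        h = self.pool(F.relu(self.stem_bn(self.stem_conv(x))))
        for s in range(1, 5):
            h = getattr(self, f"stage{s}")(h)
            h = getattr(self, f"attn{s}")(h)
            outs.append(h)
        return outs


def build_backbone(spec: BackboneSpec, seed: int = 0) -> Backbone:
    return Backbone(spec, seed)


class PyramidPooling(nn.Module):
    """Four-branch average-pool pyramid; output has 2C channels.

    Each branch pools the C-channel input to ``bin×bin``, reduces it to
    C/4 channels with a 1×1 conv (+BN+ReLU) and bilinearly upsamples
    back; the branches are concatenated with the input map.
    """

    def __init__(self, in_channels: int, spec: PyramidSpec, seed: int = 0):
        super().__init__()
        spec.validate()
        if in_channels % 4 != 0:
            raise ValueError(f"pyramid input channels must be divisible by 4, got {in_channels}")
        self.spec = spec
        self.in_channels = in_channels
        reduced = in_channels // 4
        self.reduced_channels = reduced
        rng = np.random.default_rng(derive_seed(seed, "pyramid"))
        for i, _ in enumerate(spec.bin_sizes):
            setattr(self, f"reduce{i}", nn.Conv2d(in_channels, reduced, 1, bias=False, rng=rng))
            setattr(self, f"bn{i}", nn.BatchNorm2d(reduced))

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        branches = [x]
        for i, bins in enumerate(self.spec.bin_sizes):
            b = F.adaptive_avg_pool2d(x, (bins, bins))
            b = F.relu(getattr(self, f"bn{i}")(getattr(self, f"reduce{i}")(b)))
            branches.append(F.bilinear_resize(b, (h, w)))
        return F.concat(branches, axis=1)


def pyramid_pool(feature_map: np.ndarray, spec: PyramidSpec, seed: int = 0) -> np.ndarray:
    """Functional pyramid pooling of a single C×H×W map (fresh weights)."""
    x = np.asarray(feature_map, dtype=np.float32)
    module = PyramidPooling(x.shape[0], spec, seed=seed).eval()
    with nn.no_grad():
        return module(Tensor(x[None])).data[0]


class DSCAPSPNet(nn.Module):
    """The full segmentation network; returns per-class logits at input size."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        super().__init__()
        spec.validate()
        self.spec = spec
        self.backbone = Backbone(spec.backbone, seed)
        c = self.backbone.out_channels
        self.psp = PyramidPooling(c, spec.pyramid, seed)
        cat_ch = 2 * c
        self.decoder_attn = (DscSE(cat_ch, rng=np.random.default_rng(derive_seed(seed, "decoder", "attn")))
                             if spec.decoder_dscse else nn.Identity())
        rng = np.random.default_rng(derive_seed(seed, "decoder"))
        self.head_conv = nn.Conv2d(cat_ch, spec.head_channels, 3, padding=1, bias=False, rng=rng)
        self.head_bn = nn.BatchNorm2d(spec.head_channels)
        self.classifier = nn.Conv2d(spec.head_channels, spec.num_classes, 1, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 4 or x.shape[1] != self.spec.backbone.in_channels:
            raise ValueError(f"expected N×{self.spec.backbone.in_channels}×H×W input, got {tuple(x.shape)}")
        h, w = x.shape[2], x.shape[3]
        feat = self.backbone(x)
        feat = self.psp(feat)
        feat = self.decoder_attn(feat)
        feat = F.relu(self.head_bn(self.head_conv(feat)))
        logits = self.classifier(feat)
        return F.bilinear_resize(logits, (h, w))

    def attention_blocks(self) -> dict[str, DscSE]:
        """Every D-scSE block in the network, keyed by insertion point."""
        blocks: dict[str, DscSE] = {}
        for s in range(1, 5):
            attn = getattr(self.backbone, f"attn{s}")
            if isinstance(attn, DscSE):
                blocks[f"stage{s}"] = attn
        if isinstance(self.decoder_attn, DscSE):
            blocks["decoder"] = self.decoder_attn
        return blocks


def build_model(spec: ModelSpec | None = None, seed: int = 0) -> DSCAPSPNet:
    """Build the network deterministically from ``spec`` under ``seed``."""
    return DSCAPSPNet(spec or ModelSpec(), seed)


def dscse_budget(spec: ModelSpec) -> int:
    """Closed-form parameter cost of all D-scSE insertions in ``spec``."""
    total = 0
    for enabled, c in zip(spec.backbone.dscse_after_stage, spec.backbone.stage_channels):
        if enabled:
            total += dscse_param_count(c)
    if spec.decoder_dscse:
        total += dscse_param_count(2 * spec.backbone.stage_channels[-1])
    return total


def model_forward(images: np.ndarray, model: DSCAPSPNet) -> np.ndarray:
    """Evaluation-mode forward of an N×3×H×W batch; returns logits array."""
    model.eval()
    with nn.no_grad():
        return model(Tensor(np.asarray(images, dtype=np.float32))).data
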