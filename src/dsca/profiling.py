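"""Model complexity accounting and attention-map extraction.

FLOPs are counted as 2 per multiply-accumulate, over convolutions and
affine layers (including the attention blocks' 1×1 convs and FC
layers); batch norm, activations and pooling are ignored. The
convention is embedded in every report because published GFLOP figures
vary by tool more than by model.

Parameter memory is reported by the formula parameters × 4 bytes /
1024², i.e. float32 storage, rather than any printed figure.
"""

from __future__ import annotations

import time
import zlib
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .model import DSCAPSPNet
from .nn import Tensor

FLOP_CONVENTION = "2 FLOPs per MAC; conv + affine + attention ops; BN/activations ignored"


def count_parameters(model) -> int:
    """Sum of element counts over all trainable weight arrays."""
    return model.num_parameters()


def estimate_flops(model, input_shape: tuple[int, int, int] = (3, 512, 512)) -> float:
    """GFLOPs of one forward pass at ``input_shape`` (counted, not timed)."""
    model.eval()
    x = Tensor(np.zeros((1, *input_shape), dtype=np.float32))
    with nn.no_grad(), nn.count_macs() as counter:
        model(x)
    return 2.0 * counter["macs"] / 1e9


def _state_checksum(model) -> int:
    crc = 0
    for _, p in sorted(model.named_parameters()):
        crc = zlib.crc32(p.data.tobytes(), crc)
    for _, b in sorted(model.named_buffers()):
        crc = zlib.crc32(np.ascontiguousarray(b).tobytes(), crc)
    return crc


@dataclass
class ProfileReport:
    trainable_parameters: int
    parameters_million: float
    flop_estimate_gflops: float
    parameter_memory_mb: float
    forward_time_ms: float        # informational only; hardware-dependent
    input_shape: tuple[int, int, int]
    flop_convention: str = FLOP_CONVENTION

    def as_dict(self) -> dict:
        return asdict(self)


def profile_model(model, input_shape: tuple[int, int, int] = (3, 512, 512),
                  measure_time: bool = True) -> ProfileReport:
    """Full complexity report; guaranteed not to change any weight."""
    before = _state_checksum(model)
    params = count_parameters(model)
    gflops = estimate_flops(model, input_shape)
    elapsed_ms = float("nan")
    if measure_time:
        x = Tensor(np.zeros((1, *input_shape), dtype=np.float32))
        model.eval()
        with nn.no_grad():
            t0 = time.perf_counter()
            model(x)
            elapsed_ms = (time.perf_counter() - t0) * 1e3
    if _state_checksum(model) != before:
        raise RuntimeError("profiling must not modify model state")
    return ProfileReport(
        trainable_parameters=params,
        parameters_million=round(params / 1e6, 2),
        flop_estimate_gflops=round(gflops, 2),
        parameter_memory_mb=round(params * 4 / 1024 ** 2, 2),
        forward_time_ms=round(elapsed_ms, 2),
        input_shape=tuple(input_shape),
    )


def minmax_normalize(arr: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; a constant array maps to all zeros."""
    lo, hi = float(arr.min()), float(arr.max())
    if hi - lo < 1e-12:
        return np.zeros_like(arr, dtype=np.float32)
    return ((arr - lo) / (hi - lo)).astype(np.float32)


def attention_map(model: DSCAPSPNet, image: np.ndarray,
                  upsample_to_input: bool = False) -> np.ndarray:
    """Heat map from the final backbone stage (post-attention).

    Channel-wise mean of the stage-4 activation, min-max normalised to
    [0, 1]; a constant activation normalises to all zeros. With
    ``upsample_to_input`` the map is bilinearly resized from the
    stride-8 grid back to the image size for overlay.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim == 3 and image.shape[2] in (3, 4):   # HWC -> CHW
        image = image[..., :3].transpose(2, 0, 1)
    model.eval()
    with nn.no_grad():
        feats = model.backbone.stage_outputs(Tensor(image[None]))
    heat = minmax_normalize(feats[-1].data[0].mean(axis=0))
    if upsample_to_input:
        with nn.no_grad():
            heat = nn.bilinear_resize(Tensor(heat[None, None]),
                                      (image.shape[1], image.shape[2])).data[0, 0]
        heat = np.clip(heat, 0.0, 1.0)
    return heat
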