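"""Dynamic squeeze-and-excitation context (D-scSE) attention.

The block recalibrates a feature map ``U`` (C×H×W) along two independent
axes and blends the results with learnable scalars:

* **spatial excitation (sSE)** — a 1×1 convolution with weights
  ``W_k ∈ R^{C}`` squeezes the channel axis to a score map ``k`` (H×W);
  the sigmoid of ``k`` gates every channel per pixel:
  ``U_sSE[c,i,j] = σ(k[i,j]) · U[c,i,j]``.
* **channel excitation (cSE)** — global average pooling and global max
  pooling are concatenated into a descriptor ``x ∈ R^{2C}``; a single
  fully connected layer ``W ∈ R^{C×2C}`` applied to ``ReLU(x)`` followed
  by a sigmoid yields per-channel gates ``s ∈ (0,1)^C`` that rescale
  each channel.
* **dynamic fusion** — ``U_out = α·U_sSE + β·U_cSE`` with trainable
  scalars α, β initialised from U(−√(6/n), +√(6/n)).

Unlike the classic scSE (which sums or maxes the two branches with fixed
weight 1), the learned α, β let each insertion point choose how much
spatial versus channel recalibration it wants; the balance shifts during
training as the gradients reach α and β.

Two surfaces are provided: plain-numpy functions on single C×H×W maps
(the reference semantics, used by the oracle tests) and the
:class:`DscSE` layer on batched tensors for use inside the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from . import nn
from .nn import Tensor
from .nn import functional as F


# ---------------------------------------------------------------------------
# plain-numpy reference operations (single feature map, C×H×W)
# ---------------------------------------------------------------------------

def spatial_excite(u: np.ndarray, spatial_kernel: np.ndarray, bias: float = 0.0) -> np.ndarray:
    """Channel-squeeze / spatial-excite: gate every pixel by σ(W_k·U + b)."""
    u = np.asarray(u, dtype=np.float64)
    kern = np.asarray(spatial_kernel, dtype=np.float64).ravel()
    if u.ndim != 3:
        raise ValueError(f"feature map must be C×H×W, got shape {u.shape}")
    if kern.shape[0] != u.shape[0]:
        raise ValueError(f"spatial kernel length {kern.shape[0]} != channel count {u.shape[0]}")
    k = np.tensordot(kern, u, axes=1) + bias          # (H, W)
    return expit(k)[None, :, :] * u


def channel_excite(u: np.ndarray, channel_weight: np.ndarray,
                   bias: np.ndarray | float = 0.0) -> np.ndarray:
    """Spatial-squeeze / channel-excite: rescale channels by σ(W·ReLU(x)+b)."""
    u = np.asarray(u, dtype=np.float64)
    w = np.asarray(channel_weight, dtype=np.float64)
    if u.ndim != 3:
        raise ValueError(f"feature map must be C×H×W, got shape {u.shape}")
    c = u.shape[0]
    if w.shape != (c, 2 * c):
        raise ValueError(f"channel weight must be {c}×{2 * c}, got {w.shape}")
    x = np.concatenate([u.mean(axis=(1, 2)), u.max(axis=(1, 2))])  # (2C,)
    s = expit(w @ np.maximum(x, 0.0) + bias)                        # (C,)
    return s[:, None, None] * u


def fuse(u_sse: np.ndarray, u_cse: np.ndarray, weights: "FusionWeights") -> np.ndarray:
    """Dynamically weighted combination α·U_sSE + β·U_cSE."""
    u_sse = np.asarray(u_sse, dtype=np.float64)
    u_cse = np.asarray(u_cse, dtype=np.float64)
    if u_sse.shape != u_cse.shape:
        raise ValueError(f"branch shapes differ: {u_sse.shape} vs {u_cse.shape}")
    return weights.alpha * u_sse + weights.beta * u_cse


@dataclass
class FusionWeights:
    """The learnable fusion scalars of a D-scSE block."""

    alpha: float
    beta: float


def init_fusion_weights(n: int = 2, seed: int | None = None) -> FusionWeights:
    """Draw α, β i.i.d. from U(−√(6/n), +√(6/n)).

    ``n`` is the number of input units feeding the fusion weight tensor;
    the two-branch sum has two inputs, hence the default ``n = 2``
    (bound √3).
    """
    if n < 1:
        raise ValueError(f"n must be a positive integer, got {n}")
    bound = float(np.sqrt(6.0 / n))
    rng = np.random.default_rng(seed)
    a, b = rng.uniform(-bound, bound, size=2)
    return FusionWeights(alpha=float(a), beta=float(b))


@dataclass
class DscseParams:
    """All parameters of one D-scSE block, in reference (numpy) form."""

    spatial_kernel: np.ndarray          # (C,)
    spatial_bias: float
    channel_weight: np.ndarray          # (C, 2C)
    channel_bias: np.ndarray            # (C,)
    fusion: FusionWeights

    def __post_init__(self):
        c = np.asarray(self.spatial_kernel).ravel().shape[0]
        w = np.asarray(self.channel_weight)
        if w.shape != (c, 2 * c):
            raise ValueError(f"channel weight must be {c}×{2 * c}, got {w.shape}")


def dscse_forward(u: np.ndarray, params: DscseParams) -> np.ndarray:
    """Reference forward pass of the full block on a single C×H×W map."""
    u_sse = spatial_excite(u, params.spatial_kernel, params.spatial_bias)
    u_cse = channel_excite(u, params.channel_weight, params.channel_bias)
    return fuse(u_sse, u_cse, params.fusion)


def dscse_param_count(channels: int) -> int:
    """Closed-form trainable-parameter count of one block: 2C² + 2C + 3.

    FC weights 2C² plus bias C, 1×1 spatial conv C plus bias 1, and the
    two fusion scalars α, β.
    """
    c = int(channels)
    return 2 * c * c + 2 * c + 3


# ---------------------------------------------------------------------------
# network layer (batched tensors)
# ---------------------------------------------------------------------------

class DscSE(nn.Module):
    """D-scSE attention layer for N×C×H×W tensors.

    Biases of the 1×1 spatial conv and the FC layer start at zero, so at
    initialisation the layer computes exactly the bias-free formulas.
    """

    def __init__(self, channels: int, fusion_init_n: int = 2,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.spatial_conv = nn.Conv2d(channels, 1, 1, bias=True, rng=rng)
        self.channel_fc = nn.Linear(2 * channels, channels, bias=True, rng=rng)
        bound = float(np.sqrt(6.0 / fusion_init_n))
        a, b = rng.uniform(-bound, bound, size=2)
        self.alpha = Tensor(np.float32(a), requires_grad=True)
        self.beta = Tensor(np.float32(b), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        if c != self.channels:
            raise ValueError(f"DscSE built for {self.channels} channels, got {c}")
        # sSE branch
        gate_s = F.sigmoid(self.spatial_conv(x))            # (N,1,H,W)
        u_sse = F.mul(x, gate_s)
        # cSE branch
        desc = F.concat([F.mean_spatial(x), F.amax_spatial(x)], axis=1)  # (N,2C)
        gate_c = F.sigmoid(self.channel_fc(F.relu(desc)))    # (N,C)
        u_cse = F.mul(x, F.reshape(gate_c, (n, c, 1, 1)))
        return F.add(F.mul(self.alpha, u_sse), F.mul(self.beta, u_cse))

    def fusion_weights(self) -> FusionWeights:
        return FusionWeights(alpha=float(self.alpha.data), beta=float(self.beta.data))

    def reference_params(self) -> DscseParams:
        """Export the layer's parameters in reference (numpy) form."""
        return DscseParams(
            spatial_kernel=self.spatial_conv.weight.data.reshape(-1).copy(),
            spatial_bias=float(self.spatial_conv.bias.data[0]),
            channel_weight=self.channel_fc.weight.data.copy(),
            channel_bias=self.channel_fc.bias.data.copy(),
            fusion=self.fusion_weights(),
        )
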