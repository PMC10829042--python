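"""The D-scSE attention block on a tiny hand-made feature map.

Builds a 2-channel 2x2 map, runs the spatial-excitation branch, the
channel-excitation branch and the dynamically weighted fusion, and
prints the gate values so the arithmetic can be followed by hand.
"""

import numpy as np

from dsca import (DscseParams, FusionWeights, channel_excite, dscse_forward,
                  init_fusion_weights, spatial_excite)

u = np.array([[[1.0, 2.0], [3.0, 4.0]],
              [[5.0, 6.0], [7.0, 8.0]]])
print("feature map U (2 channels, 2x2):")
print(u)

# spatial branch: the 1x1 conv squeezes channels to a score per pixel
out_s = spatial_excite(u, spatial_kernel=np.array([1.0, -1.0]), bias=0.0)
print("\nspatial gate with kernel (1,-1): every pixel scores 1*U0 - 1*U1 = -4,")
print(f"so the sigmoid gate is {1 / (1 + np.exp(4)):.6f} everywhere and")
print("U_sSE = gate * U:")
print(out_s)

# channel branch: avg+max pooled descriptor -> FC -> sigmoid per channel
w = np.array([[1.0, 0, 0, 0], [0, 0, 0, 1.0]])
out_c = channel_excite(np.stack([np.ones((1, 2)), np.array([[0.0, 2.0]])]), w)
print("\nchannel gates from descriptor (avg0, avg1, max0, max1) = (1,1,1,2):")
print(f"s = (sigmoid(1), sigmoid(2)) -> channel 0 scaled by {out_c[0, 0, 0]:.6f},"
      f" channel 1 max scaled to {out_c[1, 0, 1]:.6f}")

# dynamic fusion: alpha, beta drawn from U(-sqrt(6/n), +sqrt(6/n))
fw = init_fusion_weights(n=2, seed=42)
print(f"\nfusion weights drawn with n=2 (bound ±{np.sqrt(3):.3f}): "
      f"alpha={fw.alpha:.4f}, beta={fw.beta:.4f}")
params = DscseParams(np.zeros(2), 0.0, np.zeros((2, 4)), np.zeros(2),
                     FusionWeights(1.0, 1.0))
print("\nwith all-zero gate parameters both gates are 0.5, and alpha=beta=1")
print("makes the whole block the identity:")
print(dscse_forward(u, params))
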