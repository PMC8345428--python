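"""A hand-weighted network implementing an explicit color rule.

For pipeline tests and demonstrations it is useful to have a model whose
segmentation behavior is known *by construction*, with no training. The
weights below make the 1/32-width network compute, per pixel,

* channel 0 of conv1: ``relu(B − R)`` — strong on pale-blue benign
  material, weak on violet PTC, zero on glass and on the zero padding;
* channel 1 of conv1: ``relu(R − G)`` — strong on violet PTC only;

smooth both with a 3×3 mean filter (conv1_2), carry them through the max
pooling chain, threshold them at conv6, and turn the thresholded
evidence into class logits at conv8. The transposed convolution is the
standard bilinear kernel, so the coarse decisions are interpolated back
to pixel resolution. Argmax then yields label 0 on background, 1 on
benign clusters and 2 on PTC clusters.

Being max-pool based, decisions are made on 32-px blocks: cluster
boundaries dilate by up to one block, which bounds the achievable IoU on
small objects — adequate for the large-cluster fixtures it is paired
with.
"""

from __future__ import annotations

import numpy as np

from .model import FCNModel, NetworkConfig
from ..training import init_weights

__all__ = ["make_color_rule_model"]


def make_color_rule_model(input_px: int = 512) -> FCNModel:
    """Build the deterministic color-rule segmenter (see module docstring)."""
    cfg = NetworkConfig(width_multiplier=1.0 / 32.0, input_px=input_px,
                        dropout=0.0)
    model = FCNModel(cfg, seed=0)
    init_weights(model, scheme="random", seed=0)  # bilinear deconv included

    def zero(lyr):
        lyr.params["W"] = np.zeros_like(lyr.params["W"])
        if "b" in lyr.params:
            lyr.params["b"] = np.zeros_like(lyr.params["b"])

    # conv1_1: ch0 = relu(B - R), ch1 = relu(R - G); center tap only.
    # Inputs are optical density (1 - rgb/255), so color differences flip
    # sign: B - R = OD_R - OD_B, and R - G = OD_G - OD_R.
    c11 = model.layer("conv1_1")
    zero(c11)
    c11.params["W"][0, 0, 1, 1] = 1.0   # +OD_R
    c11.params["W"][0, 2, 1, 1] = -1.0  # -OD_B
    c11.params["W"][1, 1, 1, 1] = 1.0   # +OD_G
    c11.params["W"][1, 0, 1, 1] = -1.0  # -OD_R

    # conv1_2: 3x3 mean filter per channel (noise suppression before max pools)
    c12 = model.layer("conv1_2")
    zero(c12)
    c12.params["W"][0, 0] = 1.0 / 9.0
    c12.params["W"][1, 1] = 1.0 / 9.0

    # conv2..conv5: per-channel identity pass-through of ch0/ch1
    for name in ("conv2_1", "conv2_2", "conv3_1", "conv3_2", "conv3_3",
                 "conv4_1", "conv4_2", "conv4_3",
                 "conv5_1", "conv5_2", "conv5_3"):
        lyr = model.layer(name)
        zero(lyr)
        lyr.params["W"][0, 0, 1, 1] = 1.0
        lyr.params["W"][1, 1, 1, 1] = 1.0

    # conv6: threshold the two stain signals (center tap of the 7x7 kernel)
    thr = 0.08
    c6 = model.layer("conv6")
    zero(c6)
    c6.params["W"][0, 0, 3, 3] = 1.0
    c6.params["b"][0] = -thr
    c6.params["W"][1, 1, 3, 3] = 1.0
    c6.params["b"][1] = -thr

    c7 = model.layer("conv7")
    zero(c7)
    c7.params["W"][0, 0, 0, 0] = 1.0
    c7.params["W"][1, 1, 0, 0] = 1.0

    # conv8: logits — class 0 fixed at 0; benign driven by ch0, PTC by ch1
    c8 = model.layer("conv8")
    zero(c8)
    c8.params["W"][1, 0, 0, 0] = 50.0   # benign <- relu(B-R) evidence
    c8.params["W"][1, 1, 0, 0] = -30.0  # ...suppressed by PTC evidence
    c8.params["b"][1] = -1.0
    c8.params["W"][2, 1, 0, 0] = 50.0   # PTC <- relu(R-G) evidence
    c8.params["b"][2] = -1.0
    return model
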