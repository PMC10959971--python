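"""NumPy forward-pass definitions of the three backbone architectures.

Each builder returns ``(params, forward, tap_dim)`` where ``forward(x,
params)`` maps a normalized ``(3, H, W)`` float32 image to the tap-layer
feature vector: the post-ReLU "fc7" activation for AlexNet (4096), the
global average pooling output for ResNet50 (2048) and DenseNet201 (1920).
Weights are He-initialized from a seeded generator; batch-norm layers start
as the identity (gamma 1, beta 0, zero running mean, unit running
variance), which is exact for the randomly initialized inference-only use
these networks see here.
"""

from __future__ import annotations

import numpy as np

from ._nn import (avgpool2d, batchnorm, conv2d, global_avg_pool, he_conv,
                  he_fc, linear, maxpool2d, relu)

__all__ = ["build_alexnet", "build_resnet50", "build_densenet201",
           "ARCH_TAP_DIM", "ARCH_TAP_LAYER", "ARCH_INPUT_SIZE"]

ARCH_TAP_DIM = {"alexnet": 4096, "resnet50": 2048, "densenet201": 1920}
ARCH_TAP_LAYER = {"alexnet": "fc7", "resnet50": "final_avg_pool",
                  "densenet201": "final_avg_pool"}
ARCH_INPUT_SIZE = {"alexnet": (227, 227), "resnet50": (224, 224),
                   "densenet201": (224, 224)}


def _bn_identity(c: int) -> dict:
    return {
        "gamma": np.ones(c, dtype=np.float32),
        "beta": np.zeros(c, dtype=np.float32),
        "mean": np.zeros(c, dtype=np.float32),
        "var": np.ones(c, dtype=np.float32),
    }


def _bn(x, p):
    return batchnorm(x, p["gamma"], p["beta"], p["mean"], p["var"])


# ----------------------------------------------------------------- AlexNet
def build_alexnet(rng: np.random.Generator):
    """Classic 227x227 AlexNet up to the second fully connected layer."""
    p = {}
    p["conv1"] = he_conv(rng, 64, 3, 11, bias=True)
    p["conv2"] = he_conv(rng, 192, 64, 5, bias=True)
    p["conv3"] = he_conv(rng, 384, 192, 3, bias=True)
    p["conv4"] = he_conv(rng, 256, 384, 3, bias=True)
    p["conv5"] = he_conv(rng, 256, 256, 3, bias=True)
    p["fc6"] = he_fc(rng, 4096, 256 * 6 * 6)
    p["fc7"] = he_fc(rng, 4096, 4096)

    def forward(x: np.ndarray, p: dict) -> np.ndarray:
        x = relu(conv2d(x, *p["conv1"], stride=4, padding=2))
        x = maxpool2d(x, 3, 2)
        x = relu(conv2d(x, *p["conv2"], padding=2))
        x = maxpool2d(x, 3, 2)
        x = relu(conv2d(x, *p["conv3"], padding=1))
        x = relu(conv2d(x, *p["conv4"], padding=1))
        x = relu(conv2d(x, *p["conv5"], padding=1))
        x = maxpool2d(x, 3, 2)
        flat = x.reshape(-1)  # row-major (C, H, W) flatten
        x = relu(linear(flat, *p["fc6"]))
        return relu(linear(x, *p["fc7"]))

    return p, forward, 4096


# ----------------------------------------------------------------- ResNet50
_RESNET50_STAGES = [(3, 64, 1), (4, 128, 2), (6, 256, 2), (3, 512, 2)]
_EXPANSION = 4


def build_resnet50(rng: np.random.Generator):
    """ResNet-50: bottleneck residual stages ending in global average pooling."""
    p: dict = {"stem": he_conv(rng, 64, 3, 7)[0], "stem_bn": _bn_identity(64)}
    in_ch = 64
    stages = []
    for si, (blocks, width, stride) in enumerate(_RESNET50_STAGES):
        stage = []
        for bi in range(blocks):
            s = stride if bi == 0 else 1
            out_ch = width * _EXPANSION
            block = {
                "c1": he_conv(rng, width, in_ch, 1)[0], "bn1": _bn_identity(width),
                "c2": he_conv(rng, width, width, 3)[0], "bn2": _bn_identity(width),
                "c3": he_conv(rng, out_ch, width, 1)[0], "bn3": _bn_identity(out_ch),
                "stride": s,
            }
            if s != 1 or in_ch != out_ch:
                block["down"] = he_conv(rng, out_ch, in_ch, 1)[0]
                block["down_bn"] = _bn_identity(out_ch)
            stage.append(block)
            in_ch = out_ch
        stages.append(stage)
    p["stages"] = stages

    def forward(x: np.ndarray, p: dict) -> np.ndarray:
        x = relu(_bn(conv2d(x, p["stem"], stride=2, padding=3), p["stem_bn"]))
        x = maxpool2d(x, 3, 2, padding=1)
        for stage in p["stages"]:
            for b in stage:
                identity = x
                y = relu(_bn(conv2d(x, b["c1"]), b["bn1"]))
                y = relu(_bn(conv2d(y, b["c2"], stride=b["stride"], padding=1),
                             b["bn2"]))
                y = _bn(conv2d(y, b["c3"]), b["bn3"])
                if "down" in b:
                    identity = _bn(conv2d(x, b["down"], stride=b["stride"]),
                                   b["down_bn"])
                x = relu(y + identity)
        return global_avg_pool(x)

    return p, forward, 2048


# -------------------------------------------------------------- DenseNet201
_DENSENET201_BLOCKS = (6, 12, 48, 32)
_GROWTH = 32
_BN_SIZE = 4


def build_densenet201(rng: np.random.Generator):
    """DenseNet-201: dense blocks (6, 12, 48, 32) with growth rate 32."""
    p: dict = {"stem": he_conv(rng, 64, 3, 7)[0], "stem_bn": _bn_identity(64)}
    ch = 64
    blocks = []
    transitions = []
    for bi, n_layers in enumerate(_DENSENET201_BLOCKS):
        layers = []
        for _ in range(n_layers):
            bottleneck = _BN_SIZE * _GROWTH
            layers.append({
                "bn1": _bn_identity(ch),
                "c1": he_conv(rng, bottleneck, ch, 1)[0],
                "bn2": _bn_identity(bottleneck),
                "c2": he_conv(rng, _GROWTH, bottleneck, 3)[0],
            })
            ch += _GROWTH
        blocks.append(layers)
        if bi != len(_DENSENET201_BLOCKS) - 1:
            out_ch = ch // 2
            transitions.append({"bn": _bn_identity(ch),
                                "c": he_conv(rng, out_ch, ch, 1)[0]})
            ch = out_ch
    p["blocks"] = blocks
    p["transitions"] = transitions
    p["final_bn"] = _bn_identity(ch)

    def forward(x: np.ndarray, p: dict) -> np.ndarray:
        x = relu(_bn(conv2d(x, p["stem"], stride=2, padding=3), p["stem_bn"]))
        x = maxpool2d(x, 3, 2, padding=1)
        for bi, layers in enumerate(p["blocks"]):
            for lp in layers:
                y = relu(_bn(x, lp["bn1"]))
                y = conv2d(y, lp["c1"])
                y = relu(_bn(y, lp["bn2"]))
                y = conv2d(y, lp["c2"], padding=1)
                x = np.concatenate([x, y], axis=0)
            if bi < len(p["transitions"]):
                tp = p["transitions"][bi]
                x = conv2d(relu(_bn(x, tp["bn"])), tp["c"])
                x = avgpool2d(x, 2, 2)
        x = relu(_bn(x, p["final_bn"]))
        return global_avg_pool(x)

    return p, forward, 1920
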