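"""Shape-level definitions of ImageNet backbone architectures.

These tables instantiate an architecture's parameter *shapes* — every
convolution, bias, and batch-normalization layer with its channel counts —
without allocating weights, which is all that parameter accounting needs.
Counts follow the published reference definitions of each architecture
(convolution bias usage, channel rounding rules, block layouts) for the
feature extractor up to and including global average pooling, i.e. without
any classification head.

Conventions mirrored from the reference implementations:

* VGG16 — 13 biased 3x3 convolutions, no batch norm.
* ResNet50 — biased convolutions, BN after every convolution, projection
  shortcut (conv + BN) on the first block of each stage.
* ResNet50V2 — pre-activation: BN precedes the convolutions inside each
  block; first and last 1x1 convolutions carry bias as in the reference
  (stem conv biased, inner convolutions bias-free), plus a final BN.
* MobileNetV2 — bias-free convolutions, BN everywhere, inverted-residual
  blocks, channel widths scaled by alpha and rounded to multiples of 8;
  the final 1280-wide convolution is not narrowed for alpha < 1.
* DenseNet — bias-free convolutions; BN-ReLU-conv ordering with 1x1
  bottlenecks (4x growth), transition convolutions halving channels,
  growth rate 32.

A batch-normalization layer over C channels contributes 2C trainable
parameters (gamma, beta) and 2C running statistics; both enter the total
parameter count, only gamma/beta enter the trainable count, and neither is
updated during fine-tuning (frozen-BN policy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["ArchitectureCount", "layer_table", "LAYER_TABLES"]


@dataclass
class ArchitectureCount:
    """Parameter accounting for one backbone's feature extractor."""

    name: str
    feature_dim: int = 0
    weights: int = 0  # conv/dense kernels and biases
    bn_gamma_beta: int = 0
    bn_stats: int = 0

    def conv(self, cin: int, cout: int, k: int = 3, bias: bool = True) -> int:
        self.weights += k * k * cin * cout + (cout if bias else 0)
        return cout

    def dwconv(self, c: int, k: int = 3, bias: bool = False) -> int:
        self.weights += k * k * c + (c if bias else 0)
        return c

    def bn(self, c: int) -> None:
        self.bn_gamma_beta += 2 * c
        self.bn_stats += 2 * c

    @property
    def total_params(self) -> int:
        """All parameters including BN running statistics (framework 'Total')."""
        return self.weights + self.bn_gamma_beta + self.bn_stats

    @property
    def trainable_params(self) -> int:
        """Framework 'Trainable' convention: everything but BN statistics."""
        return self.weights + self.bn_gamma_beta

    def head_params(self) -> int:
        """Binary head: dense(feature_dim -> 1) + bias after GAP."""
        return self.feature_dim + 1

    def retrain_trainable(self) -> int:
        return self.head_params()

    def finetune_trainable(self) -> int:
        """Everything except frozen BN layers, plus the binary head."""
        return self.weights + self.head_params()


def _vgg16() -> ArchitectureCount:
    a = ArchitectureCount("vgg16")
    c = 3
    for cout in [64, 64, 128, 128, 256, 256, 256, 512, 512, 512, 512, 512, 512]:
        c = a.conv(c, cout, k=3, bias=True)
    a.feature_dim = c
    return a


def _resnet50() -> ArchitectureCount:
    a = ArchitectureCount("resnet50")
    c = a.conv(3, 64, k=7, bias=True)
    a.bn(c)
    for f, blocks in [(64, 3), (128, 4), (256, 6), (512, 3)]:
        for b in range(blocks):
            cin = c
            if b == 0:  # projection shortcut
                a.conv(cin, 4 * f, k=1, bias=True)
                a.bn(4 * f)
            x = a.conv(cin, f, k=1, bias=True)
            a.bn(x)
            x = a.conv(x, f, k=3, bias=True)
            a.bn(x)
            x = a.conv(x, 4 * f, k=1, bias=True)
            a.bn(x)
            c = 4 * f
    a.feature_dim = c
    return a


def _resnet50v2() -> ArchitectureCount:
    a = ArchitectureCount("resnet50v2")
    c = a.conv(3, 64, k=7, bias=True)  # pre-activation stem: no BN here
    for f, blocks in [(64, 3), (128, 4), (256, 6), (512, 3)]:
        for b in range(blocks):
            cin = c
            a.bn(cin)  # pre-activation BN
            if b == 0:
                a.conv(cin, 4 * f, k=1, bias=True)  # projection shortcut
            x = a.conv(cin, f, k=1, bias=False)
            a.bn(x)
            x = a.conv(x, f, k=3, bias=False)
            a.bn(x)
            x = a.conv(x, 4 * f, k=1, bias=True)
            c = 4 * f
    a.bn(c)  # post-activation BN before pooling
    a.feature_dim = c
    return a


def _make_divisible(v: float, divisor: int = 8) -> int:
    new_v = max(divisor, int(v + divisor / 2) // divisor * divisor)
    if new_v < 0.9 * v:
        new_v += divisor
    return new_v


def _mobilenetv2(alpha: float) -> ArchitectureCount:
    a = ArchitectureCount(f"mobilenetv2_{int(round(alpha * 100)):03d}")
    c = a.conv(3, _make_divisible(32 * alpha), k=3, bias=False)
    a.bn(c)
    # (expansion, base filters, repeats)
    blocks = [(1, 16, 1), (6, 24, 2), (6, 32, 3), (6, 64, 4), (6, 96, 3), (6, 160, 3), (6, 320, 1)]
    for t, f, n in blocks:
        cout = _make_divisible(f * alpha)
        for _ in range(n):
            cin = c
            if t > 1:
                x = a.conv(cin, t * cin, k=1, bias=False)
                a.bn(x)
            else:
                x = cin
            a.dwconv(x, k=3)
            a.bn(x)
            a.conv(x, cout, k=1, bias=False)
            a.bn(cout)
            c = cout
    last = _make_divisible(1280 * alpha) if alpha > 1.0 else 1280
    c = a.conv(c, last, k=1, bias=False)
    a.bn(c)
    a.feature_dim = c
    return a


def _densenet(name: str, block_layers: list[int], growth: int = 32) -> ArchitectureCount:
    a = ArchitectureCount(name)
    c = a.conv(3, 2 * growth, k=7, bias=False)
    a.bn(c)
    for bi, n_layers in enumerate(block_layers):
        for _ in range(n_layers):
            a.bn(c)
            x = a.conv(c, 4 * growth, k=1, bias=False)
            a.bn(x)
            a.conv(x, growth, k=3, bias=False)
            c += growth  # dense connectivity: concatenate
        if bi < len(block_layers) - 1:  # transition halves the channels
            a.bn(c)
            c = a.conv(c, c // 2, k=1, bias=False)
    a.bn(c)
    a.feature_dim = c
    return a


def _tinycnn() -> ArchitectureCount:
    a = ArchitectureCount("tinycnn")
    c = a.conv(3, 8, k=3, bias=True)
    c = a.conv(c, 16, k=3, bias=True)
    a.bn(c)
    c = a.conv(c, 64, k=3, bias=True)
    a.feature_dim = c
    return a


LAYER_TABLES = {
    "tinycnn": _tinycnn,
    "vgg16": _vgg16,
    "resnet50": _resnet50,
    "resnet50v2": _resnet50v2,
    "mobilenetv2_035": lambda: _mobilenetv2(0.35),
    "mobilenetv2_100": lambda: _mobilenetv2(1.0),
    "mobilenetv2_140": lambda: _mobilenetv2(1.4),
    "densenet121": lambda: _densenet("densenet121", [6, 12, 24, 16]),
    "densenet169": lambda: _densenet("densenet169", [6, 12, 32, 32]),
    "densenet201": lambda: _densenet("densenet201", [6, 12, 48, 32]),
}


def layer_table(key: str) -> ArchitectureCount:
    try:
        return LAYER_TABLES[key]()
    except KeyError:
        raise KeyError(
            f"no shape-level definition for {key!r}; available: {sorted(LAYER_TABLES)}"
        ) from None
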