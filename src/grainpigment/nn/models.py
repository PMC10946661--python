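"""Network architectures: encoder-decoder segmenter and residual classifier.

The segmenter is a U-Net: an encoder of stacked 3x3 convolution blocks with
2x2 max pooling, a decoder of 2x upsampling steps, and skip connections
concatenated at matching resolutions, ending in a 1x1 convolution that
emits per-pixel logits.  The encoder "family" selects block count and width
multiplier in the spirit of the named reference architectures
(``resnet18``-style: one residual double-conv block per stage;
``resnet34``-style: two; ``efficientnet-b0``-style: wider single blocks).
A pooled classification head can be attached to the encoder bottleneck for
multi-task operation.

The classifier is a small residual network: 3x3 convolution blocks with
additive skip connections, channel doubling at every downsampling stage,
global average pooling, and one fully connected output layer.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    Conv2d,
    GlobalAvgPool,
    InstanceNorm,
    Linear,
    MaxPool2,
    ReLU,
    Upsample2,
    concat_channels,
    split_channels,
)

__all__ = ["ENCODER_FAMILIES", "DoubleConv", "UNet", "ResNetClassifier"]

# family -> (blocks per stage, width multiplier)
ENCODER_FAMILIES = {
    "resnet18": (1, 1.0),
    "resnet34": (2, 1.0),
    "efficientnet-b0": (1, 1.25),
}


def resolve_family(name: str) -> tuple[int, float]:
    key = name.lower().removesuffix("-style")
    if key not in ENCODER_FAMILIES:
        raise ValueError(
            f"unknown encoder family {name!r}; expected one of {sorted(ENCODER_FAMILIES)}"
        )
    return ENCODER_FAMILIES[key]


class DoubleConv:
    """conv3x3-norm-ReLU-conv3x3-norm with an additive identity/projection
    skip, then ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, residual: bool = True):
        self.conv1 = Conv2d(c_in, c_out, rng)
        self.norm1 = InstanceNorm(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, rng)
        self.norm2 = InstanceNorm(c_out)
        self.relu2 = ReLU()
        self.residual = residual
        self.proj = Conv2d(c_in, c_out, rng, kernel=1) if (residual and c_in != c_out) else None

    def params(self):
        ps = (self.conv1.params() + self.norm1.params()
              + self.conv2.params() + self.norm2.params())
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.relu1.forward(self.norm1.forward(self.conv1.forward(x)))
        y = self.norm2.forward(self.conv2.forward(y))
        if self.residual:
            y = y + (self.proj.forward(x) if self.proj is not None else x)
        return self.relu2.forward(y)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dy = self.relu2.backward(dout)
        dx = self.conv1.backward(self.norm1.backward(
            self.relu1.backward(self.conv2.backward(self.norm2.backward(dy)))))
        if self.residual:
            dx = dx + (self.proj.backward(dy) if self.proj is not None else dy)
        return dx


class _Stage:
    """One resolution level: `blocks` DoubleConvs, first changing width."""

    def __init__(self, c_in, c_out, blocks, rng, residual=True):
        self.blocks = [DoubleConv(c_in if i == 0 else c_out, c_out, rng, residual)
                       for i in range(blocks)]

    def params(self):
        return [p for b in self.blocks for p in b.params()]

    def forward(self, x):
        for b in self.blocks:
            x = b.forward(x)
        return x

    def backward(self, d):
        for b in reversed(self.blocks):
            d = b.backward(d)
        return d


class UNet:
    """Encoder-decoder segmenter with skip connections and optional class head.

    Parameters
    ----------
    out_channels : number of per-pixel output logits (1 for grain/background,
        2 for per-pigment maps).
    depth : number of 2x downsampling steps; inputs must be divisible by
        ``2 ** depth``.
    base_width : channels at full resolution; width doubles per level.
    with_head : attach a pooled 2-logit classification head to the
        bottleneck (multi-task operation).
    """

    def __init__(
        self,
        rng: np.random.Generator,
        in_channels: int = 3,
        out_channels: int = 1,
        depth: int = 5,
        base_width: int = 8,
        encoder_family: str = "resnet18",
        with_head: bool = False,
        head_outputs: int = 2,
    ):
        blocks, mult = resolve_family(encoder_family)
        widths = [max(4, int(round(base_width * mult)) << i) for i in range(depth + 1)]
        self.depth = depth
        self.widths = widths
        self.with_head = with_head

        self.enc = []
        c = in_channels
        for i in range(depth):
            self.enc.append(_Stage(c, widths[i], blocks, rng))
            c = widths[i]
        self.pools = [MaxPool2() for _ in range(depth)]
        self.bottleneck = _Stage(c, widths[depth], blocks, rng)

        self.ups = [Upsample2() for _ in range(depth)]
        self.reduce = [Conv2d(widths[i + 1], widths[i], rng, kernel=1) for i in range(depth)]
        self.dec = [_Stage(2 * widths[i], widths[i], 1, rng) for i in range(depth)]
        # full-resolution input skip: the output convolution sees the raw
        # channels next to the decoder features, so pixel-wise color rules
        # are directly expressible
        self.in_channels = in_channels
        self.out_conv = Conv2d(widths[0] + in_channels, out_channels, rng, kernel=1)
        # start from zero logits: the first steps then move the whole map
        # coherently instead of unlearning init noise
        self.out_conv.W.value[...] = 0.0

        if with_head:
            self.gap = GlobalAvgPool()
            self.head = Linear(widths[depth], head_outputs, rng)

    def params(self):
        ps = []
        for st in self.enc:
            ps += st.params()
        ps += self.bottleneck.params()
        for conv in self.reduce:
            ps += conv.params()
        for st in self.dec:
            ps += st.params()
        ps += self.out_conv.params()
        if self.with_head:
            ps += self.head.params()
        return ps

    def forward(self, x: np.ndarray):
        """Return per-pixel logits (and head logits if ``with_head``)."""
        if x.shape[2] % (1 << self.depth) or x.shape[3] % (1 << self.depth):
            raise ValueError(
                f"input spatial size {x.shape[2:]} not divisible by {1 << self.depth}"
            )
        x_in = x
        skips = []
        for i in range(self.depth):
            x = self.enc[i].forward(x)
            skips.append(x)
            x = self.pools[i].forward(x)
        x = self.bottleneck.forward(x)
        head_logits = None
        if self.with_head:
            head_logits = self.head.forward(self.gap.forward(x))
        for i in reversed(range(self.depth)):
            x = self.reduce[i].forward(self.ups[i].forward(x))
            x = concat_channels(x, skips[i])
            x = self.dec[i].forward(x)
        seg_logits = self.out_conv.forward(concat_channels(x, x_in))
        if self.with_head:
            return seg_logits, head_logits
        return seg_logits

    def backward(self, d_seg: np.ndarray, d_head: np.ndarray | None = None) -> None:
        d = self.out_conv.backward(d_seg)
        d, _d_input = split_channels(d, self.widths[0])  # input carries no params
        d_skips = [None] * self.depth
        for i in range(self.depth):
            d = self.dec[i].backward(d)
            d, d_skip = split_channels(d, self.widths[i])
            d_skips[i] = d_skip
            d = self.ups[i].backward(self.reduce[i].backward(d))
        d = self.bottleneck.backward(
            d + (self.gap.backward(self.head.backward(d_head))
                 if (self.with_head and d_head is not None) else 0.0)
        )
        for i in reversed(range(self.depth)):
            d = self.pools[i].backward(d) + d_skips[i]
            d = self.enc[i].backward(d)


class ResNetClassifier:
    """Residual CNN emitting two pigment-presence logits.

    Channel count doubles at every downsampling stage; the network ends in
    global average pooling and a single fully connected layer.
    """

    def __init__(
        self,
        rng: np.random.Generator,
        in_channels: int = 3,
        n_outputs: int = 2,
        base_width: int = 8,
        n_stages: int = 3,
        blocks_per_stage: int = 1,
    ):
        widths = [base_width << i for i in range(n_stages)]
        self.stem = Conv2d(in_channels, widths[0], rng)
        self.stem_relu = ReLU()
        self.stages = []
        self.pools = []
        c = widths[0]
        for i in range(n_stages):
            self.stages.append(_Stage(c, widths[i], blocks_per_stage, rng, residual=True))
            self.pools.append(MaxPool2())
            c = widths[i]
        self.gap = GlobalAvgPool()
        self.fc = Linear(c, n_outputs, rng)

    def params(self):
        ps = self.stem.params()
        for st in self.stages:
            ps += st.params()
        return ps + self.fc.params()

    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = self.stem_relu.forward(self.stem.forward(x))
        for st, pool in zip(self.stages, self.pools):
            x = pool.forward(st.forward(x))
        return self.fc.forward(self.gap.forward(x))

    def backward(self, dout: np.ndarray) -> None:
        d = self.gap.backward(self.fc.backward(dout))
        for st, pool in zip(reversed(self.stages), reversed(self.pools)):
            d = st.backward(pool.backward(d))
        self.stem.backward(self.stem_relu.backward(d))
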