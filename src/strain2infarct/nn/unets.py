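"""Encoder-decoder segmentation architectures (UNet family).

All four networks share the same contract: a 3-channel square image in
[0, 1] (NCHW) goes in, a single-channel per-pixel probability map of the
same spatial size comes out through a final 1x1 convolution and sigmoid.
Channel widths double per level (base 16 -> 256 at depth 5); the base UNet
uses two 3x3 conv + ReLU blocks per level, 2x2 max pooling on the way down
and biased 2x2 stride-2 up-convolutions with skip concatenation on the way
up, and no batch normalization.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, maxpool2x2, upsample2x
from .layers import Adam, BatchNorm2d, Conv2d, ConvTranspose2x2, Module


class _DoubleConv(Module):
    """Two 3x3 convolutions, each followed by ReLU."""

    def __init__(self, cin: int, cout: int, rng):
        self.c1 = Conv2d(cin, cout, 3, rng)
        self.c2 = Conv2d(cout, cout, 3, rng)

    def __call__(self, x):
        return self.c2(self.c1(x).relu()).relu()


class _AttentionGate(Module):
    """Additive attention on a skip connection.

    The gating signal ``g`` is the coarser decoder-side feature map; it is
    upsampled to the skip resolution, both inputs are projected to an
    intermediate width of half the skip channels, and a sigmoid of a 1x1
    convolution of their rectified sum scales the skip features per pixel.
    """

    def __init__(self, c_skip: int, c_gate: int, rng):
        c_int = max(c_skip // 2, 1)
        self.wx = Conv2d(c_skip, c_int, 1, rng)
        self.wg = Conv2d(c_gate, c_int, 1, rng)
        self.psi = Conv2d(c_int, 1, 1, rng)

    def __call__(self, x, g):
        gu = upsample2x(g)
        alpha = self.psi((self.wx(x) + self.wg(gu)).relu()).sigmoid()
        return x * alpha


class _DenseBlock(Module):
    """Concatenative block: each 3x3 conv sees all preceding feature maps.

    Two growth layers (conv 3x3 -> BN -> ReLU) with growth rate equal to the
    level width, closed by a 1x1 transition back to the level width so the
    surrounding UNet scaffolding is unchanged.
    """

    def __init__(self, cin: int, cout: int, rng):
        self.l1 = Conv2d(cin, cout, 3, rng)
        self.bn1 = BatchNorm2d(cout)
        self.l2 = Conv2d(cin + cout, cout, 3, rng)
        self.bn2 = BatchNorm2d(cout)
        self.transition = Conv2d(cin + 2 * cout, cout, 1, rng)

    def __call__(self, x):
        f1 = self.bn1(self.l1(x)).relu()
        f2 = self.bn2(self.l2(concat([x, f1], axis=1))).relu()
        return self.transition(concat([x, f1, f2], axis=1))


class _ResidualBlock(Module):
    """Pre-activation residual block with a three-conv branch.

    out = shortcut(x) + c3(relu(c2(relu(c1(relu(x)))))); zeroing the last
    convolution's weights reduces the block to its shortcut exactly.
    """

    def __init__(self, cin: int, cout: int, rng):
        self.c1 = Conv2d(cin, cout, 3, rng)
        self.c2 = Conv2d(cout, cout, 3, rng)
        self.c3 = Conv2d(cout, cout, 3, rng)
        self.proj = None if cin == cout else Conv2d(cin, cout, 1, rng)

    def __call__(self, x):
        r = self.c3(self.c2(self.c1(x.relu()).relu()).relu())
        s = x if self.proj is None else self.proj(x)
        return s + r


class UNetBase(Module):
    """Shared scaffolding for the four architectures."""

    #: factory for encoder blocks; decoder blocks are plain double convs
    encoder_block = staticmethod(_DoubleConv)
    use_attention = False

    def __init__(self, in_channels: int = 3, base_channels: int = 16,
                 depth: int = 5, seed: int | None = None):
        if depth < 2:
            raise ValueError("depth must be >= 2")
        rng = np.random.default_rng(seed)
        self.in_channels = in_channels
        self.base_channels = base_channels
        self.depth = depth
        widths = [base_channels * 2 ** i for i in range(depth)]
        self.widths = widths

        enc, cin = [], in_channels
        for w in widths:
            enc.append(self.encoder_block(cin, w, rng))
            cin = w
        self.encoders = enc

        ups, decs, gates = [], [], []
        for w_deep, w_skip in zip(widths[:0:-1], widths[-2::-1]):
            ups.append(ConvTranspose2x2(w_deep, w_skip, rng))
            decs.append(_DoubleConv(2 * w_skip, w_skip, rng))
            if self.use_attention:
                gates.append(_AttentionGate(w_skip, w_deep, rng))
        self.ups = ups
        self.decoders = decs
        self.gates = gates
        self.head = Conv2d(widths[0], 1, 1, rng)

    def _check_input(self, x: Tensor):
        h, w = x.shape[2], x.shape[3]
        div = 2 ** (self.depth - 1)
        if h % div or w % div:
            raise ValueError(
                f"input size {h}x{w} not divisible by {div} "
                f"(depth {self.depth})"
            )

    def __call__(self, x: Tensor) -> Tensor:
        self._check_input(x)
        skips = []
        h = x
        for i, block in enumerate(self.encoders):
            h = block(h)
            if i < self.depth - 1:
                skips.append(h)
                h = maxpool2x2(h)
        for i, (up, dec) in enumerate(zip(self.ups, self.decoders)):
            skip = skips[-(i + 1)]
            if self.use_attention:
                skip = self.gates[i](skip, h)
            h = dec(concat([up(h), skip], axis=1))
        return self.head(h).sigmoid()


class UNet(UNetBase):
    pass


class AttentionUNet(UNetBase):
    use_attention = True


class DenseUNet(UNetBase):
    encoder_block = staticmethod(_DenseBlock)


class ResidualAttentionUNet(UNetBase):
    encoder_block = staticmethod(_ResidualBlock)
    use_attention = True


__all__ = [
    "UNet",
    "AttentionUNet",
    "DenseUNet",
    "ResidualAttentionUNet",
    "UNetBase",
    "Adam",
    "Module",
]
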