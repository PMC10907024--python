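"""Network topologies for the virtual-staining model zoo.

All image-to-image networks map a (N, in_slices, H, W) DIC stack to a
(N, 1, H, W) fluorescence prediction bounded to [0, 1] by a final sigmoid.
Spatial sizes must be divisible by ``2**depth`` (``4`` for the
DeepLab-style network, which pools twice).
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Var
from .layers import Conv2d, Dense, Module


class ConvBlock(Module):
    """Two 3x3 conv + ReLU; optional residual shortcut (1x1 projection)."""

    def __init__(self, cin: int, cout: int, rng, residual: bool = False):
        self.conv1 = Conv2d(cin, cout, 3, rng=rng)
        self.conv2 = Conv2d(cout, cout, 3, rng=rng)
        self.residual = residual
        if residual:
            self.proj = Conv2d(cin, cout, 1, rng=rng)

    def __call__(self, x: Var) -> Var:
        h = ad.relu(self.conv1(x))
        h = self.conv2(h)
        if self.residual:
            h = ad.add(h, self.proj(x))
        return ad.relu(h)


class AttentionGate(Module):
    """Additive attention gate modulating a skip connection."""

    def __init__(self, skip_ch: int, gate_ch: int, rng):
        inter = max(1, skip_ch // 2)
        self.wx = Conv2d(skip_ch, inter, 1, rng=rng)
        self.wg = Conv2d(gate_ch, inter, 1, rng=rng)
        self.psi = Conv2d(inter, 1, 1, rng=rng)

    def __call__(self, skip: Var, gate: Var) -> Var:
        a = ad.relu(ad.add(self.wx(skip), self.wg(gate)))
        alpha = ad.sigmoid(self.psi(a))          # (N, 1, H, W)
        alpha = ad.concat_channels([alpha] * skip.data.shape[1])
        return ad.mul(skip, alpha)


class UNet(Module):
    """Encoder-decoder with skip connections; res/att variants via flags."""

    def __init__(self, in_ch: int, depth: int = 3, base_width: int = 8,
                 rng: np.random.Generator | None = None,
                 residual: bool = False, attention: bool = False):
        rng = rng or np.random.default_rng(0)
        self.depth = depth
        widths = [base_width * 2 ** i for i in range(depth + 1)]
        self.enc = [ConvBlock(in_ch if i == 0 else widths[i - 1], widths[i], rng,
                              residual=residual) for i in range(depth)]
        self.bottleneck = ConvBlock(widths[depth - 1], widths[depth], rng,
                                    residual=residual)
        self.attention = attention
        if attention:
            self.gates = [AttentionGate(widths[i], widths[i + 1], rng)
                          for i in range(depth)]
        self.dec = [ConvBlock(widths[i] + widths[i + 1], widths[i], rng,
                              residual=residual) for i in range(depth)]
        self.head = Conv2d(widths[0], 1, 1, rng=rng)

    def __call__(self, x: Var) -> Var:
        skips = []
        h = x
        for block in self.enc:
            h = block(h)
            skips.append(h)
            h = ad.avg_pool2(h)
        h = self.bottleneck(h)
        for i in reversed(range(self.depth)):
            h = ad.upsample2(h)
            s = skips[i]
            if self.attention:
                s = self.gates[i](s, h)
            h = self.dec[i](ad.concat_channels([s, h]))
        return ad.sigmoid(self.head(h))


class DeepLabLike(Module):
    """Encoder + atrous spatial pyramid pooling (ASPP) regression network.

    Two stride-2 stages, ASPP with dilations (1, 2, 4) at 1/4 resolution,
    then a lightweight upsampling decoder and a 1-channel head.
    """

    def __init__(self, in_ch: int, base_width: int = 8,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        w = base_width
        self.stem = ConvBlock(in_ch, w, rng)
        self.enc2 = ConvBlock(w, 2 * w, rng)
        self.aspp1 = Conv2d(2 * w, 2 * w, 1, rng=rng)
        self.aspp2 = Conv2d(2 * w, 2 * w, 3, dilation=2, rng=rng)
        self.aspp3 = Conv2d(2 * w, 2 * w, 3, dilation=4, rng=rng)
        self.fuse = Conv2d(6 * w, 2 * w, 1, rng=rng)
        self.dec1 = ConvBlock(2 * w, w, rng)
        self.dec2 = ConvBlock(w, w, rng)
        self.head = Conv2d(w, 1, 1, rng=rng)
        self.depth = 2  # two poolings -> size must divide by 4

    def __call__(self, x: Var) -> Var:
        h = ad.avg_pool2(self.stem(x))
        h = ad.avg_pool2(self.enc2(h))
        a = ad.concat_channels([
            ad.relu(self.aspp1(h)),
            ad.relu(self.aspp2(h)),
            ad.relu(self.aspp3(h)),
        ])
        h = ad.relu(self.fuse(a))
        h = self.dec1(ad.upsample2(h))
        h = self.dec2(ad.upsample2(h))
        return ad.sigmoid(self.head(h))


class PatchDiscriminator(Module):
    """PatchGAN-style discriminator conditioned on the input stack.

    Consumes concat(DIC stack, fluorescence image) and emits a grid of
    real/fake logits.  The final 1x1 convolution is the "last layer" that
    few-shot fine-tuning reinitializes.
    """

    def __init__(self, in_ch: int, base_width: int = 8,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        w = base_width
        self.c1 = Conv2d(in_ch, w, 3, rng=rng)
        self.c2 = Conv2d(w, 2 * w, 3, rng=rng)
        self.c3 = Conv2d(2 * w, 4 * w, 3, rng=rng)
        self.final = Conv2d(4 * w, 1, 1, rng=rng)

    def __call__(self, x: Var) -> Var:
        h = ad.avg_pool2(ad.leaky_relu(self.c1(x)))
        h = ad.avg_pool2(ad.leaky_relu(self.c2(h)))
        h = ad.leaky_relu(self.c3(h))
        return self.final(h)                      # raw logits


class SmallVGGClassifier(Module):
    """VGG-style conv classifier for dataset matching.

    conv-pool stages with doubling width, global average pooling, and a
    dense softmax head over the local dataset ids.
    """

    def __init__(self, n_classes: int, in_ch: int = 1, base_width: int = 8,
                 n_stages: int = 3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        widths = [base_width * 2 ** i for i in range(n_stages)]
        self.convs = [Conv2d(in_ch if i == 0 else widths[i - 1], widths[i], 3, rng=rng)
                      for i in range(n_stages)]
        self.fc = Dense(widths[-1], n_classes, rng=rng)
        self.n_stages = n_stages

    def logits(self, x: Var) -> Var:
        h = x
        for conv in self.convs:
            h = ad.max_pool2(ad.relu(conv(h)))
        return self.fc(ad.spatial_mean(h))

    def predict_probs(self, x: np.ndarray) -> np.ndarray:
        out = self.logits(Var(x))
        return ad.softmax_probs(out.data)
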