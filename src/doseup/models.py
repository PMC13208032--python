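"""Translation-network architectures.

* **Generator** — the ResNet-style encoder / residual-bottleneck / decoder
  used throughout the contrastive-translation family: a 7x7 stem, two
  stride-2 downsampling convolutions, ``n_res_blocks`` residual blocks (9
  at full scale) and a mirrored decoder with nearest-neighbor upsampling +
  convolution. Instance normalization and ReLU throughout, reflect
  padding, tanh output. Unit-domain slices are mapped to [-1, 1] on entry
  and back on exit.

  The generator exposes nine feature tap points ("layers 0-8": the input
  plus eight encoder-side activations) for patch-contrastive learning.

* **Discriminator** — the standard 70x70 PatchGAN: 4x4 convolutions,
  strides (2, 2, 2, 1, 1), widths (ndf, 2ndf, 4ndf, 8ndf, 1), LeakyReLU
  0.2, instance norm on the middle blocks. Receptive-field arithmetic:
  4 -> 10 -> 22 -> 46 -> 70 px.

* **PatchProjector** — the contrastive feature net (netF): per tap layer a
  2-layer MLP (256 hidden/output channels) applied to sampled patch
  vectors, L2-normalized.

Width parameters (``ngf``/``ndf``) scale all hidden layers; the full-scale
configuration uses 64, hermetic smoke training uses narrower nets.
"""

from __future__ import annotations

import numpy as np

from .nn import Conv2d, InstanceNorm2d, Linear, Module, ResnetBlock, Tensor

__all__ = ["ResnetGenerator", "PatchGANDiscriminator", "PatchProjector",
           "patchgan_receptive_field"]


class ResnetGenerator(Module):
    def __init__(self, ngf: int = 64, n_res_blocks: int = 9,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.ngf = ngf
        self.n_res_blocks = n_res_blocks
        self.stem = Conv2d(1, ngf, 7, padding=3, pad_mode="reflect", rng=rng)
        self.stem_norm = InstanceNorm2d(ngf)
        self.down1 = Conv2d(ngf, ngf * 2, 3, stride=2, padding=1, rng=rng)
        self.down1_norm = InstanceNorm2d(ngf * 2)
        self.down2 = Conv2d(ngf * 2, ngf * 4, 3, stride=2, padding=1, rng=rng)
        self.down2_norm = InstanceNorm2d(ngf * 4)
        self.blocks = [ResnetBlock(ngf * 4, rng) for _ in range(n_res_blocks)]
        for i, b in enumerate(self.blocks):
            setattr(self, f"res{i}", b)
        self.up1 = Conv2d(ngf * 4, ngf * 2, 3, padding=1, rng=rng)
        self.up1_norm = InstanceNorm2d(ngf * 2)
        self.up2 = Conv2d(ngf * 2, ngf, 3, padding=1, rng=rng)
        self.up2_norm = InstanceNorm2d(ngf)
        self.head = Conv2d(ngf, 1, 7, padding=3, pad_mode="reflect", rng=rng)

    # -- encoder with feature taps ---------------------------------------
    def encode(self, x: Tensor, collect: bool = False):
        """Run the encoder half; optionally collect the 9 tap activations.

        Tap 0 is the (scaled) input itself; taps 1-3 are the stem and the
        two downsampling blocks; taps 4-8 sit on residual blocks spread
        evenly across the bottleneck.
        """
        taps = [x] if collect else None
        h = self.stem_norm(self.stem(x)).relu()
        if collect:
            taps.append(h)
        h = self.down1_norm(self.down1(h)).relu()
        if collect:
            taps.append(h)
        h = self.down2_norm(self.down2(h)).relu()
        if collect:
            taps.append(h)
        n = self.n_res_blocks
        tap_blocks = set(np.unique(np.linspace(0, n - 1, 5).round().astype(int))) \
            if n else set()
        for i, block in enumerate(self.blocks):
            h = block(h)
            if collect and i in tap_blocks:
                taps.append(h)
        return (h, taps) if collect else (h, None)

    def decode(self, h: Tensor) -> Tensor:
        h = self.up1_norm(self.up1(h.upsample_nearest2x())).relu()
        h = self.up2_norm(self.up2(h.upsample_nearest2x())).relu()
        return self.head(h).tanh()

    def forward(self, x: Tensor, collect_features: bool = False):
        """Map a unit-domain batch (N,1,H,W) to its translated batch.

        With ``collect_features`` also returns the encoder tap list (for
        patch-contrastive losses).
        """
        x2 = x * 2.0 - 1.0
        h, taps = self.encode(x2, collect=collect_features)
        y = self.decode(h) * 0.5 + 0.5
        return (y, taps) if collect_features else y

    def feature_channels(self) -> list[int]:
        g = self.ngf
        n_res_taps = len(set(np.unique(
            np.linspace(0, self.n_res_blocks - 1, 5).round().astype(int)))) \
            if self.n_res_blocks else 0
        return [1, g, g * 2, g * 4] + [g * 4] * n_res_taps


# layer stack of the 70x70 PatchGAN: (kernel, stride) pairs
_PATCHGAN_STACK = ((4, 2), (4, 2), (4, 2), (4, 1), (4, 1))


def patchgan_receptive_field() -> int:
    rf, jump = 1, 1
    for k, s in _PATCHGAN_STACK:
        rf += (k - 1) * jump
        jump *= s
    return rf


class PatchGANDiscriminator(Module):
    def __init__(self, ndf: int = 64, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.c1 = Conv2d(1, ndf, 4, stride=2, padding=1, rng=rng)
        self.c2 = Conv2d(ndf, ndf * 2, 4, stride=2, padding=1, rng=rng)
        self.n2 = InstanceNorm2d(ndf * 2)
        self.c3 = Conv2d(ndf * 2, ndf * 4, 4, stride=2, padding=1, rng=rng)
        self.n3 = InstanceNorm2d(ndf * 4)
        self.c4 = Conv2d(ndf * 4, ndf * 8, 4, stride=1, padding=1, rng=rng)
        self.n4 = InstanceNorm2d(ndf * 8)
        self.c5 = Conv2d(ndf * 8, 1, 4, stride=1, padding=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.c1(x * 2.0 - 1.0).leaky_relu(0.2)
        h = self.n2(self.c2(h)).leaky_relu(0.2)
        h = self.n3(self.c3(h)).leaky_relu(0.2)
        h = self.n4(self.c4(h)).leaky_relu(0.2)
        return self.c5(h)


class _LayerMLP(Module):
    def __init__(self, in_ch: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(in_ch, hidden, rng)
        self.fc2 = Linear(hidden, hidden, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class PatchProjector(Module):
    """Per-tap-layer 2-layer MLP projection heads with L2 normalization."""

    def __init__(self, channel_list: list[int], hidden: int = 256,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.heads = [_LayerMLP(c, hidden, rng) for c in channel_list]
        for i, h in enumerate(self.heads):
            setattr(self, f"head{i}", h)

    def project(self, layer_index: int, patches: Tensor) -> Tensor:
        """(B, K, C) sampled patch vectors -> (B, K, hidden), unit norm."""
        z = self.heads[layer_index](patches)
        norm = ((z * z).sum(axis=-1, keepdims=True) + 1e-10).sqrt()
        return z / norm
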