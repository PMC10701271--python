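"""3D encoder-decoder dose-prediction networks.

Two variants:

* ``UNet3D`` — a single encoder over the stacked input channels, a
  bottleneck, and a decoder with skip connections; dual 3x3x3 convolutions
  with feature normalization and ReLU at every level, 2x2x2 max pooling
  between encoder levels, nearest-neighbour upsampling in the decoder.  The
  filter count starts at ``base_filters`` and doubles at every level, so a
  depth-4, base-32 model peaks at 512 bottleneck filters.

* ``AttUNet3D`` — separate structure and CT encoders; at the bottleneck the
  two feature blocks are fused by multi-head attention (queries from the
  structure stream, keys/values from the CT stream), and a single decoder
  with skip connections from the structure encoder predicts the dose.

Both preserve spatial resolution: the output shape equals the input shape,
with a single dose channel.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm3d,
    Conv3d,
    Layer,
    MaxPool3d,
    MultiHeadAttention3d,
    ReLU,
    Upsample3d,
)

__all__ = ["ConvBlock", "UNet3D", "AttUNet3D"]


class ConvBlock:
    """Two (conv -> norm -> ReLU) stages."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.layers = [
            Conv3d(cin, cout, 3, rng), BatchNorm3d(cout), ReLU(),
            Conv3d(cout, cout, 3, rng), BatchNorm3d(cout), ReLU(),
        ]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class _Base:
    """Shared bookkeeping: parameter traversal, train/eval mode."""

    def __init__(self) -> None:
        self._param_layers: list[Layer] = []

    def _register(self, *items) -> list:
        for it in items:
            if isinstance(it, ConvBlock):
                self._param_layers.extend(l for l in it.layers if l.params)
            elif isinstance(it, Layer) and it.params:
                self._param_layers.append(it)
        return list(items)

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(l, k) for l in self._param_layers for k in l.params]

    def n_parameters(self) -> int:
        return sum(l.params[k].size for l, k in self.parameters())

    def zero_grad(self) -> None:
        for layer in self._param_layers:
            layer.zero_grad()

    def set_training(self, flag: bool) -> None:
        for layer in self._param_layers:
            if isinstance(layer, BatchNorm3d):
                layer.training = flag

    def _check_shape(self, x: np.ndarray) -> None:
        if x.ndim != 4:
            raise ValueError(f"expected (C, X, Y, Z) input, got shape {x.shape}")
        div = 2**self.depth
        if any(s % div for s in x.shape[1:]):
            raise ValueError(
                f"spatial shape {x.shape[1:]} is not divisible by 2^depth = {div}; "
                "pad or crop the input"
            )

    def channel_schedule(self) -> list[int]:
        """Encoder filter counts level by level, bottleneck last."""
        return [self.base * 2**l for l in range(self.depth + 1)]

    @property
    def bottleneck_filters(self) -> int:
        return self.base * 2**self.depth


class UNet3D(_Base):
    def __init__(self, in_channels: int, depth: int = 4, base_filters: int = 32,
                 seed: int = 0):
        super().__init__()
        self.depth, self.base = depth, base_filters
        rng = np.random.default_rng(seed)
        ch = self.channel_schedule()
        self.enc = self._register(
            *[ConvBlock(in_channels if l == 0 else ch[l - 1], ch[l], rng) for l in range(depth)]
        )
        self.pools = [MaxPool3d() for _ in range(depth)]
        (self.bottleneck,) = self._register(ConvBlock(ch[depth - 1], ch[depth], rng))
        self.ups = [Upsample3d() for _ in range(depth)]
        self.upconv = self._register(
            *[Conv3d(ch[l + 1], ch[l], 3, rng) for l in reversed(range(depth))]
        )
        self.upnorm = self._register(*[BatchNorm3d(ch[l]) for l in reversed(range(depth))])
        self.uprelu = [ReLU() for _ in range(depth)]
        self.dec = self._register(
            *[ConvBlock(2 * ch[l], ch[l], rng) for l in reversed(range(depth))]
        )
        (self.head,) = self._register(Conv3d(ch[0], 1, 1, rng))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._check_shape(x)
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_channels = [s.shape[0] for s in skips]
        for i, skip in enumerate(reversed(skips)):
            x = self.ups[i].forward(x)
            x = self.uprelu[i].forward(self.upnorm[i].forward(self.upconv[i].forward(x)))
            x = np.concatenate([skip, x], axis=0)
            x = self.dec[i].forward(x)
        return self.head.forward(x)[0]

    def backward(self, gy: np.ndarray) -> None:
        g = self.head.backward(gy[None])
        skip_grads: list[np.ndarray] = []
        for i in reversed(range(self.depth)):
            g = self.dec[i].backward(g)
            c_skip = self._skip_channels[self.depth - 1 - i]
            skip_grads.append(g[:c_skip])
            g = g[c_skip:]
            g = self.upconv[i].backward(self.upnorm[i].backward(self.uprelu[i].backward(g)))
            g = self.ups[i].backward(g)
        g = self.bottleneck.backward(g)
        # skip_grads collected decoder-bottom-up = encoder-top-down order
        for l in reversed(range(self.depth)):
            g = self.pools[l].backward(g)
            g = g + skip_grads[l]
            g = self.enc[l].backward(g)


class AttUNet3D(_Base):
    def __init__(self, struct_channels: int, ct_channels: int = 1, depth: int = 4,
                 base_filters: int = 32, n_heads: int = 8, head_dim: int = 64,
                 scale_attention: bool = True, seed: int = 0):
        super().__init__()
        self.depth, self.base = depth, base_filters
        rng = np.random.default_rng(seed)
        ch = self.channel_schedule()

        def encoder(cin: int) -> list[ConvBlock]:
            return self._register(
                *[ConvBlock(cin if l == 0 else ch[l - 1], ch[l], rng) for l in range(depth)]
            )

        self.enc_s = encoder(struct_channels)
        self.enc_c = encoder(ct_channels)
        self.pools_s = [MaxPool3d() for _ in range(depth)]
        self.pools_c = [MaxPool3d() for _ in range(depth)]
        (self.bott_s,) = self._register(ConvBlock(ch[depth - 1], ch[depth], rng))
        (self.bott_c,) = self._register(ConvBlock(ch[depth - 1], ch[depth], rng))
        (self.attention,) = self._register(
            MultiHeadAttention3d(ch[depth], ch[depth], n_heads, head_dim, scale_attention, rng)
        )
        self.ups = [Upsample3d() for _ in range(depth)]
        self.upconv = self._register(
            *[Conv3d(ch[l + 1], ch[l], 3, rng) for l in reversed(range(depth))]
        )
        self.upnorm = self._register(*[BatchNorm3d(ch[l]) for l in reversed(range(depth))])
        self.uprelu = [ReLU() for _ in range(depth)]
        self.dec = self._register(
            *[ConvBlock(2 * ch[l], ch[l], rng) for l in reversed(range(depth))]
        )
        (self.head,) = self._register(Conv3d(ch[0], 1, 1, rng))

    def forward(self, x: np.ndarray) -> np.ndarray:
        """``x`` is the full channel stack; the last channel is CT."""
        self._check_shape(x)
        xs, xc = x[:-1], x[-1:]
        skips = []
        for block_s, pool_s, block_c, pool_c in zip(
            self.enc_s, self.pools_s, self.enc_c, self.pools_c
        ):
            xs = block_s.forward(xs)
            skips.append(xs)
            xs = pool_s.forward(xs)
            xc = pool_c.forward(block_c.forward(xc))
        xs = self.bott_s.forward(xs)
        xc = self.bott_c.forward(xc)
        fused = self.attention.forward(xs, xc)
        self._skip_channels = [s.shape[0] for s in skips]
        y = fused
        for i, skip in enumerate(reversed(skips)):
            y = self.ups[i].forward(y)
            y = self.uprelu[i].forward(self.upnorm[i].forward(self.upconv[i].forward(y)))
            y = np.concatenate([skip, y], axis=0)
            y = self.dec[i].forward(y)
        return self.head.forward(y)[0]

    def backward(self, gy: np.ndarray) -> None:
        g = self.head.backward(gy[None])
        skip_grads: list[np.ndarray] = []
        for i in reversed(range(self.depth)):
            g = self.dec[i].backward(g)
            c_skip = self._skip_channels[self.depth - 1 - i]
            skip_grads.append(g[:c_skip])
            g = g[c_skip:]
            g = self.upconv[i].backward(self.upnorm[i].backward(self.uprelu[i].backward(g)))
            g = self.ups[i].backward(g)
        gs, gc = self.attention.backward(g)
        gs = self.bott_s.backward(gs)
        gc = self.bott_c.backward(gc)
        for l in reversed(range(self.depth)):
            gs = self.pools_s[l].backward(gs)
            gs = gs + skip_grads[l]
            gs = self.enc_s[l].backward(gs)
            gc = self.enc_c[l].backward(self.pools_c[l].backward(gc))
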