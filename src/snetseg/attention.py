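"""Channel and spatial attention for convolutional feature maps.

The channel branch pools each channel over space (average and maximum),
pushes both descriptors through one shared two-layer perceptron, sums
them and normalizes into per-channel importance weights.  The spatial
branch pools across channels, mixes the two pooled maps with a 1x1
convolution and normalizes into a per-position importance map.  Applied
sequentially, the two branches multiplicatively refine the feature map
(the CBAM design).

Normalization defaults to softmax, which makes the weights a proper
probability distribution; a sigmoid option is provided because
softmax-normalized maps scale as 1/(H*W) and can starve gradients.
With softmax, an optional rescaling by the element count keeps the
expected feature magnitude unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv2d, Linear, Module, Tensor, concat, softmax


@dataclass
class ChannelWeights:
    """Per-channel importance; sums to 1 under softmax normalization."""

    weights: np.ndarray


@dataclass
class SpatialWeights:
    """Per-position importance map; sums to 1 under softmax normalization."""

    weights: np.ndarray


class CBAMBlock(Module):
    """Trainable channel + spatial attention for (N, C, H, W) tensors.

    Parameters
    ----------
    channels : feature channels C; must be divisible by `reduction`.
    reduction : bottleneck ratio r of the shared MLP (C -> C/r -> C).
    activation : "softmax" (default) or "sigmoid".
    rescale : with softmax, multiply refined features by C (channel
        stage) and H*W (spatial stage) so uniform attention is identity.
    identity_init : with r = 1, set both MLP layers to the identity —
        useful for analytically predictable behaviour in tests.
    """

    def __init__(self, channels: int, reduction: int = 8,
                 activation: str = "softmax", rescale: bool = True,
                 rng: np.random.Generator | None = None,
                 identity_init: bool = False):
        super().__init__()
        if activation not in ("softmax", "sigmoid"):
            raise ValueError(f"unknown activation {activation!r}")
        if channels % reduction:
            raise ValueError(f"reduction {reduction} must divide channels {channels}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.channels = channels
        self.activation = activation
        self.rescale = rescale
        self.mlp_in = Linear(channels, channels // reduction, rng)
        self.mlp_out = Linear(channels // reduction, channels, rng)
        self.spatial_conv = Conv2d(2, 1, 1, rng)
        if identity_init:
            if reduction != 1:
                raise ValueError("identity_init requires reduction == 1")
            self.mlp_in.weight.data = np.eye(channels, dtype=np.float32)
            self.mlp_out.weight.data = np.eye(channels, dtype=np.float32)

    # -- branches ------------------------------------------------------
    def _activate(self, logits: Tensor, axis) -> Tensor:
        if self.activation == "softmax":
            return softmax(logits, axis=axis)
        return logits.sigmoid()

    def channel_weights(self, x: Tensor) -> Tensor:
        """(N, C, H, W) -> (N, C) channel importance."""
        if x.data.ndim != 4 or x.data.shape[1] != self.channels:
            raise ValueError(f"expected (N,{self.channels},H,W), got {x.data.shape}")
        avg = x.mean(axis=(2, 3))            # (N, C)
        mx = x.amax(axis=(2, 3))
        shared = lambda d: self.mlp_out(self.mlp_in(d).relu())
        return self._activate(shared(avg) + shared(mx), axis=1)

    def spatial_weights(self, x: Tensor) -> Tensor:
        """(N, C, H, W) -> (N, H, W) position importance."""
        if x.data.ndim != 4:
            raise ValueError(f"expected 4D input, got {x.data.ndim}D")
        N, C, H, W = x.data.shape
        avg = x.mean(axis=1, keepdims=True)  # (N, 1, H, W)
        mx = x.amax(axis=1, keepdims=True)
        logits = self.spatial_conv(concat([avg, mx], axis=1)).reshape(N, H * W)
        return self._activate(logits, axis=1).reshape(N, H, W)

    def forward(self, x: Tensor) -> Tensor:
        """Sequential channel-then-spatial multiplicative refinement."""
        N, C, H, W = x.data.shape
        wc = self.channel_weights(x).reshape(N, C, 1, 1)
        out = x * wc
        if self.activation == "softmax" and self.rescale:
            out = out * float(C)
        ws = self.spatial_weights(out).reshape(N, 1, H, W)
        out = out * ws
        if self.activation == "softmax" and self.rescale:
            out = out * float(H * W)
        return out

    def permute_channels(self, perm: np.ndarray) -> "CBAMBlock":
        """Return a block whose parameters are re-indexed by `perm`.

        With these re-indexed weights, permuting the input channels
        permutes the channel weights identically (the equivariance of
        the parametrized family).
        """
        out = CBAMBlock(self.channels, self.channels // self.mlp_in.weight.data.shape[1],
                        self.activation, self.rescale)
        out.mlp_in.weight.data = self.mlp_in.weight.data[perm, :].copy()
        out.mlp_in.bias.data = self.mlp_in.bias.data.copy()
        out.mlp_out.weight.data = self.mlp_out.weight.data[:, perm].copy()
        out.mlp_out.bias.data = self.mlp_out.bias.data[perm].copy()
        out.spatial_conv.weight.data = self.spatial_conv.weight.data.copy()
        out.spatial_conv.bias.data = self.spatial_conv.bias.data.copy()
        return out


def _as_batched(F) -> tuple[Tensor, bool]:
    if isinstance(F, Tensor):
        return F, True
    arr = np.asarray(F, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError(f"feature map must be (C, H, W), got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("feature map contains non-finite values")
    return Tensor(arr[None]), False


def channel_attention(F, params: CBAMBlock) -> ChannelWeights:
    """Channel importance weights for a single (C, H, W) feature map."""
    x, batched = _as_batched(F)
    w = params.channel_weights(x)
    return ChannelWeights(weights=w.data if batched else w.data[0])


def spatial_attention(F, params: CBAMBlock) -> SpatialWeights:
    """Position importance map for a single (C, H, W) feature map."""
    x, batched = _as_batched(F)
    w = params.spatial_weights(x)
    return SpatialWeights(weights=w.data if batched else w.data[0])


def apply_cbam(F, params: CBAMBlock):
    """Refine a feature map by channel then spatial attention."""
    x, batched = _as_batched(F)
    out = params(x)
    return out if batched else out.data[0]
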