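"""S-Net: a U-shaped encoder–decoder with bottleneck attention.

The contraction path doubles the channel count at each resolution level
with 2x2 max-pooling between levels; the bottleneck applies channel and
spatial attention; the expansion path mirrors the encoder with nearest-
neighbour upsampling and halving channels.  Long-hop connections
concatenate each encoder level's output onto the same-resolution
decoder level.  A final 1x1 convolution with sigmoid yields a per-pixel
tumor probability map.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .attention import CBAMBlock
from .nn import BatchNorm2d, Conv2d, Module, Tensor, concat, conv2d, maxpool2, upsample2


@dataclass
class AttentionConfig:
    reduction: int = 8
    activation: str = "softmax"
    rescale: bool = True


@dataclass
class ModelConfig:
    """Architecture hyperparameters, pinned in one place."""

    depth: int = 4
    base_channels: int = 32
    kernel_size: int = 3
    convs_per_block: int = 2
    attention: AttentionConfig = field(default_factory=AttentionConfig)
    in_channels: int = 1
    out_channels: int = 1
    # prior log-odds of the foreground class; tumors are rare, so a
    # negative output-bias init keeps early predictions near zero and
    # gives the Dice loss usable gradients from the first steps
    head_bias_init: float = -4.0
    seed: int = 0

    def validate(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if self.convs_per_block < 1:
            raise ValueError("convs_per_block must be >= 1")

    def encoder_channels(self) -> list[int]:
        return [self.base_channels * 2 ** i for i in range(self.depth)]


class ConvBlock(Module):
    """convs_per_block x (conv -> batch norm -> ReLU)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, n_convs: int,
                 rng: np.random.Generator):
        super().__init__()
        self.convs = [Conv2d(in_ch if i == 0 else out_ch, out_ch, kernel, rng)
                      for i in range(n_convs)]
        self.norms = [BatchNorm2d(out_ch) for _ in range(n_convs)]

    def forward(self, x: Tensor) -> Tensor:
        for conv, norm in zip(self.convs, self.norms):
            x = norm(conv(x)).relu()
        return x


class SNet(Module):
    """The assembled network; build with :func:`build_model`."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        chans = config.encoder_channels()
        k, nc = config.kernel_size, config.convs_per_block

        self.encoders = []
        in_ch = config.in_channels
        for c in chans[:-1]:
            self.encoders.append(ConvBlock(in_ch, c, k, nc, rng))
            in_ch = c
        self.bottleneck = ConvBlock(in_ch, chans[-1], k, nc, rng)
        att = config.attention
        self.cbam = CBAMBlock(chans[-1], att.reduction, att.activation,
                              att.rescale, rng)
        self.decoders = []
        for c in reversed(chans[:-1]):
            # input = upsampled (2c) concatenated with the skip (c)
            self.decoders.append(ConvBlock(2 * c + c, c, k, nc, rng))
        self.head = Conv2d(chans[0], config.out_channels, 1, rng)
        self.head.bias.data[:] = config.head_bias_init

    def forward(self, x: Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.data.ndim == 3:          # (N, H, W) -> (N, 1, H, W)
            x = x.reshape(x.data.shape[0], 1, *x.data.shape[1:])
        N, C, H, W = x.data.shape
        div = 2 ** (self.config.depth - 1)
        if H % div or W % div:
            raise ValueError(
                f"spatial size {H}x{W} must be divisible by {div} "
                f"(depth {self.config.depth}); pad to "
                f"{-H % div} x {-W % div} more pixels")
        skips = []
        for enc in self.encoders:
            x = enc(x)
            skips.append(x)
            x = maxpool2(x)
        x = self.cbam(self.bottleneck(x))
        for dec, skip in zip(self.decoders, reversed(skips)):
            x = dec(concat([upsample2(x), skip], axis=1))
        return self.head(x).sigmoid()


def build_model(config: ModelConfig) -> SNet:
    """Deterministically build an S-Net from its config."""
    return SNet(config)


def forward(model: SNet, batch) -> np.ndarray:
    """Run inference on a (N, H, W) batch; returns (N, H, W) probabilities."""
    from .nn.autograd import no_grad

    model.eval()
    with no_grad():
        out = model(Tensor(np.asarray(batch, dtype=np.float32)))
    return out.data[:, 0]


def predict_mask(model: SNet, slice_image: np.ndarray,
                 threshold: float = 0.5) -> np.ndarray:
    """Threshold the probability map: foreground where p >= threshold."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    probs = forward(model, np.asarray(slice_image)[None])[0]
    return probs >= threshold


def parameter_count(model: SNet) -> int:
    return int(sum(p.data.size for p in model.parameters()))


# -- checkpointing -----------------------------------------------------

def save_checkpoint(path, model: SNet, extra: dict | None = None) -> None:
    """Single-file checkpoint: weights + embedded ModelConfig."""
    meta = {"model_config": dataclasses.asdict(model.config)}
    if extra:
        meta.update(extra)
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint(path) -> tuple[SNet, dict]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    mc = dict(meta["model_config"])
    mc["attention"] = AttentionConfig(**mc["attention"])
    model = build_model(ModelConfig(**mc))
    model.load_state_dict(state)
    return model, meta
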