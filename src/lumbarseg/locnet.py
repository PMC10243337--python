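"""UNet-based lumbar-spine localization network.

The network maps a windowed CT volume to a single-channel heatmap whose high
values mark the lumbar spine.  It is a five-level encoder (two 3x3x3
conv->BN->ReLU per level, 64 channels throughout, 2x max-pool between
levels) and a four-level decoder.  Each decoder level upsamples the deeper
map with a stride-2 transposed convolution and concatenates it with a fixed
channel slice (default [16, 48)) of the same-scale encoder map — a slimmed
skip connection — before two fusion convolutions.  A final 1x1x1 convolution
and sigmoid produce the heatmap.

At the default 96x96x128 input the encoder scales are 96x96x128, 48x48x64,
24x24x32, 12x12x16 and a 6x6x8 bottleneck, all at 64 channels, and every
decoder concatenation carries 32 + 64 = 96 channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import ConfigurationError, DataError, DivergenceError, ShapeError
from .nn import functional as F
from .nn.autograd import Tensor

__all__ = [
    "LocNetConfig",
    "TrainConfig",
    "LocalizationUNet",
    "build_localization_net",
    "loc_forward",
    "train_localization",
]


@dataclass(frozen=True)
class LocNetConfig:
    """Architecture of the localization network."""

    input_shape: tuple[int, int, int] = (96, 96, 128)
    encoder_channels: int = 64
    skip_slice: tuple[int, int] = (16, 48)
    levels: int = 5

    def __post_init__(self) -> None:
        div = 2 ** (self.levels - 1)
        for ax in self.input_shape:
            if ax % div != 0:
                raise ConfigurationError(
                    f"every input axis must be divisible by {div}, got {self.input_shape}"
                )
        lo, hi = self.skip_slice
        if not (0 <= lo < hi <= self.encoder_channels):
            raise ConfigurationError(
                f"skip_slice {self.skip_slice} must lie inside "
                f"[0, {self.encoder_channels})"
            )

    @property
    def skip_width(self) -> int:
        return self.skip_slice[1] - self.skip_slice[0]

    def to_dict(self) -> dict:
        return {
            "input_shape": list(self.input_shape),
            "encoder_channels": self.encoder_channels,
            "skip_slice": list(self.skip_slice),
            "levels": self.levels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LocNetConfig":
        return cls(
            input_shape=tuple(d["input_shape"]),
            encoder_channels=int(d["encoder_channels"]),
            skip_slice=tuple(d["skip_slice"]),
            levels=int(d["levels"]),
        )


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of a training run (shared by both stages)."""

    loss_kind: str = "mse"
    learning_rate: float = 1e-3
    steps: int = 200
    batch_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ConfigurationError(f"steps must be >= 1, got {self.steps}")
        if self.batch_size < 1:
            raise ConfigurationError(f"batch_size must be >= 1, got {self.batch_size}")


class LocalizationUNet(nn.Module):
    """Fully-convolutional heatmap-regression UNet (see module docstring)."""

    def __init__(self, cfg: LocNetConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        ch = cfg.encoder_channels
        # encoder: two convs per level; channels ch at every level
        for i in range(1, cfg.levels + 1):
            in_ch = 1 if i == 1 else ch
            setattr(self, f"enc{i}a", nn.ConvBNReLU(in_ch, ch, 3, rng))
            setattr(self, f"enc{i}b", nn.ConvBNReLU(ch, ch, 3, rng))
        # decoder: levels-1 stages, deepest first
        fused = cfg.skip_width + ch
        for i in range(1, cfg.levels):
            setattr(self, f"up{i}", nn.ConvTranspose3d2x(ch, ch, rng))
            setattr(self, f"dec{i}a", nn.ConvBNReLU(fused, ch, 3, rng))
            setattr(self, f"dec{i}b", nn.ConvBNReLU(ch, ch, 3, rng))
        self.head = nn.Conv3d(ch, 1, 1, rng)

    def forward(self, x: Tensor | np.ndarray,
                record: dict[str, tuple] | None = None) -> Tensor:
        """Run the network; optionally record activation shapes.

        ``record`` (if given) is filled with name -> (channels, spatial shape)
        for every encoder/decoder stage output.
        """
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.data.ndim != 5 or x.data.shape[1] != 1:
            raise ShapeError(f"expected (N, 1, D, H, W) input, got {x.data.shape}")
        div = 2 ** (self.cfg.levels - 1)
        if any(s % div for s in x.data.shape[2:]):
            raise ShapeError(
                f"spatial dims {x.data.shape[2:]} must be divisible by {div}"
            )

        def note(name: str, t: Tensor) -> None:
            if record is not None:
                record[name] = (t.data.shape[1], tuple(t.data.shape[2:]))

        lo, hi = self.cfg.skip_slice
        skips: list[Tensor] = []
        h = x
        for i in range(1, self.cfg.levels + 1):
            h = getattr(self, f"enc{i}b")(getattr(self, f"enc{i}a")(h))
            note(f"enc{i}", h)
            if i < self.cfg.levels:
                skips.append(h)
                h = F.maxpool3d_2x(h)
                note(f"enc{i}_down", h)
        for i in range(1, self.cfg.levels):
            skip = skips[-i]
            up = getattr(self, f"up{i}")(h)
            h = F.concat([F.channel_slice(skip, lo, hi), up], axis=1)
            note(f"dec{i}_concat", h)
            h = getattr(self, f"dec{i}b")(getattr(self, f"dec{i}a")(h))
            note(f"dec{i}", h)
        out = F.sigmoid(self.head(h))
        note("head", out)
        return out


def build_localization_net(cfg: LocNetConfig = LocNetConfig(), seed: int = 0) -> LocalizationUNet:
    """Construct the localization network with seeded initialization."""
    return LocalizationUNet(cfg, seed=seed)


def loc_forward(net: LocalizationUNet, vol: np.ndarray) -> np.ndarray:
    """Predict heatmaps for a batch (or single volume) without gradients.

    Accepts (D, H, W) or (N, D, H, W) arrays; returns the same leading shape
    with values in [0, 1].
    """
    vol = np.asarray(vol, dtype=np.float32)
    single = vol.ndim == 3
    if single:
        vol = vol[None]
    if vol.ndim != 4:
        raise ShapeError(f"expected (D,H,W) or (N,D,H,W), got {vol.shape}")
    net.eval()
    with nn.no_grad():
        out = net(vol[:, None]).data[:, 0]
    return out[0] if single else out


def train_localization(
    net: LocalizationUNet,
    dataset: list[tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig = TrainConfig(),
) -> list[float]:
    """Train on (windowed volume, target heatmap) pairs; returns loss trace.

    Mean-squared error against the Gaussian heatmap, Adam optimizer.  The
    example order and any stochasticity derive from ``cfg.seed``, so a fixed
    seed reproduces the loss trace run-to-run on the same platform.
    """
    if len(dataset) == 0:
        raise DataError("training dataset is empty")
    if cfg.loss_kind != "mse":
        raise ConfigurationError(f"unsupported localization loss: {cfg.loss_kind!r}")
    rng = np.random.default_rng(cfg.seed)
    net.train()
    opt = nn.Adam(net.parameters(), lr=cfg.learning_rate)
    losses: list[float] = []
    for step in range(cfg.steps):
        idx = rng.integers(0, len(dataset), size=cfg.batch_size)
        vols = np.stack([np.asarray(dataset[i][0], dtype=np.float32) for i in idx])
        tgts = np.stack([np.asarray(dataset[i][1], dtype=np.float32) for i in idx])
        net.zero_grad()
        pred = net(vols[:, None])
        loss = F.mse_loss(pred, tgts[:, None])
        val = loss.item()
        if not np.isfinite(val):
            raise DivergenceError(step)
        loss.backward()
        opt.step()
        losses.append(val)
    return losses
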