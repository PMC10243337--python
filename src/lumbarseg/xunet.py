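"""3D multi-scale XUnet for multi-class vertebra segmentation.

Encoder: three levels of two 3x3x3 conv->BN->ReLU (32, 64, 128 channels)
each followed by 2x max-pooling, then a fourth level consisting of one
convolution (to 256 channels), a 2x max-pool, and a four-branch Inception
block whose concatenated output has 256 channels.

The Inception block has two feature-extraction layers wired in the
canonical four-branch pattern:

* branch 1: 64 kernels 1x1x1 (straight to the output);
* branch 2: 32 kernels 1x1x1 -> 128 kernels 3x3x3;
* branch 3: 16 kernels 3x3x3 -> 32 kernels 5x5x5;
* branch 4: 3x3x3 max-pool (stride 1) -> 32 kernels 1x1x1;

giving 64 + 128 + 32 + 32 = 256 output channels at unchanged spatial shape.

Decoder: three levels of full multi-scale fusion.  Each level gathers a
named set of encoder/decoder maps, rescales every map to the level's
resolution by repeated 2x max-pool (down) or stride-2 transposed
convolution (up), concatenates along channels and fuses with two 3x3x3
conv->BN->ReLU.  At the default 64x64x128 input:

* level 1 fuses X2, X3 and the upsampled X4 at 16x16x32 -> 128 channels;
* level 2 fuses X1, X2, X3 and Y1' at 32x32x64 -> 64 channels;
* level 3 fuses X1, X2 and Y2' at 64x64x128 -> 32 channels.

A 1x1x1 convolution to ``n_classes`` channels and a per-voxel softmax
produce the class-probability grid (background + L1..L5 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError, DataError, DivergenceError, ShapeError
from .locnet import TrainConfig
from .nn import functional as F
from .nn.autograd import Tensor

__all__ = [
    "InceptionSpec",
    "XUnetConfig",
    "InceptionBlock",
    "XUNet3D",
    "build_inception_block",
    "build_xunet",
    "seg_forward",
    "predict_labels",
    "train_segmentation",
]


@dataclass(frozen=True)
class InceptionSpec:
    """Kernel counts of the four Inception branches."""

    b1: int = 64          # 1x1x1, straight to output
    b2_reduce: int = 32   # 1x1x1
    b2: int = 128         # 3x3x3
    b3_reduce: int = 16   # 3x3x3
    b3: int = 32          # 5x5x5
    b4: int = 32          # 1x1x1 after 3x3x3 max-pool

    @property
    def out_channels(self) -> int:
        return self.b1 + self.b2 + self.b3 + self.b4

    @classmethod
    def scaled(cls, out_channels: int) -> "InceptionSpec":
        """Spec with all branch widths scaled so the output has ``out_channels``."""
        base = cls()
        if out_channels * base.b3_reduce % base.out_channels:
            raise ConfigurationError(
                f"inception output {out_channels} must be a multiple of "
                f"{base.out_channels // base.b3_reduce}"
            )
        s = out_channels / base.out_channels
        return cls(*(int(round(v * s)) for v in
                     (base.b1, base.b2_reduce, base.b2, base.b3_reduce, base.b3, base.b4)))


@dataclass(frozen=True)
class XUnetConfig:
    """Architecture of the segmentation network."""

    input_shape: tuple[int, int, int] = (64, 64, 128)
    encoder_channels: tuple[int, int, int, int] = (32, 64, 128, 256)
    decoder_channels: tuple[int, int, int] = (128, 64, 32)
    n_classes: int = 6
    levels: int = 4

    def __post_init__(self) -> None:
        div = 2 ** (self.levels - 1)
        for ax in self.input_shape:
            if ax % div != 0:
                raise ConfigurationError(
                    f"every input axis must be divisible by {div}, got {self.input_shape}"
                )
        if self.n_classes < 2:
            raise ConfigurationError(f"n_classes must be >= 2, got {self.n_classes}")
        if len(self.encoder_channels) != 4 or len(self.decoder_channels) != 3:
            raise ConfigurationError("expected 4 encoder and 3 decoder channel widths")

    def to_dict(self) -> dict:
        return {
            "input_shape": list(self.input_shape),
            "encoder_channels": list(self.encoder_channels),
            "decoder_channels": list(self.decoder_channels),
            "n_classes": self.n_classes,
            "levels": self.levels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "XUnetConfig":
        return cls(
            input_shape=tuple(d["input_shape"]),
            encoder_channels=tuple(d["encoder_channels"]),
            decoder_channels=tuple(d["decoder_channels"]),
            n_classes=int(d["n_classes"]),
            levels=int(d["levels"]),
        )


class _ConvReLU(nn.Module):
    """conv -> ReLU used inside the Inception branches (bias, no BN)."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv3d(in_ch, out_ch, k, rng)

    def forward(self, x: Tensor) -> Tensor:
        return F.relu(self.conv(x))


class InceptionBlock(nn.Module):
    """Four-branch Inception module; output channels fixed by its spec."""

    def __init__(self, in_channels: int, rng: np.random.Generator | int = 0,
                 spec: InceptionSpec = InceptionSpec()):
        super().__init__()
        if in_channels < 1:
            raise ConfigurationError(f"in_channels must be >= 1, got {in_channels}")
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.spec = spec
        self.in_channels = in_channels
        self.b1 = _ConvReLU(in_channels, spec.b1, 1, rng)
        self.b2a = _ConvReLU(in_channels, spec.b2_reduce, 1, rng)
        self.b2b = _ConvReLU(spec.b2_reduce, spec.b2, 3, rng)
        self.b3a = _ConvReLU(in_channels, spec.b3_reduce, 3, rng)
        self.b3b = _ConvReLU(spec.b3_reduce, spec.b3, 5, rng)
        self.b4 = _ConvReLU(in_channels, spec.b4, 1, rng)

    @property
    def out_channels(self) -> int:
        return self.spec.out_channels

    def forward(self, x: Tensor) -> Tensor:
        y1 = self.b1(x)
        y2 = self.b2b(self.b2a(x))
        y3 = self.b3b(self.b3a(x))
        y4 = self.b4(F.maxpool3d_same(x, 3))
        return F.concat([y1, y2, y3, y4], axis=1)


def build_inception_block(in_channels: int, seed: int = 0,
                          spec: InceptionSpec = InceptionSpec()) -> InceptionBlock:
    """Construct a standalone Inception block with seeded initialization."""
    return InceptionBlock(in_channels, np.random.default_rng(seed), spec)


class _Upsample2x(nn.Module):
    """m repeated stride-2 transposed convolutions (2^m upsampling)."""

    def __init__(self, ch: int, steps: int, rng: np.random.Generator):
        super().__init__()
        self.steps = nn.Sequential(*[nn.ConvTranspose3d2x(ch, ch, rng) for _ in range(steps)])

    def forward(self, x: Tensor) -> Tensor:
        return self.steps(x)


class XUNet3D(nn.Module):
    """The multi-scale segmentation network (see module docstring)."""

    def __init__(self, cfg: XUnetConfig = XUnetConfig(), seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        c1, c2, c3, c4 = cfg.encoder_channels
        d1, d2, d3 = cfg.decoder_channels
        # encoder levels 1-3: two convs each
        self.enc1a = nn.ConvBNReLU(1, c1, 3, rng)
        self.enc1b = nn.ConvBNReLU(c1, c1, 3, rng)
        self.enc2a = nn.ConvBNReLU(c1, c2, 3, rng)
        self.enc2b = nn.ConvBNReLU(c2, c2, 3, rng)
        self.enc3a = nn.ConvBNReLU(c2, c3, 3, rng)
        self.enc3b = nn.ConvBNReLU(c3, c3, 3, rng)
        # level 4: one conv, downsample, Inception block
        self.enc4 = nn.ConvBNReLU(c3, c4, 3, rng)
        self.inception = InceptionBlock(c4, rng, InceptionSpec.scaled(c4))
        # decoder level 1: X2 (down), X3, X4 (up x4)
        self.up_x4 = _Upsample2x(c4, 2, rng)
        self.dec1a = nn.ConvBNReLU(c2 + c3 + c4, d1, 3, rng)
        self.dec1b = nn.ConvBNReLU(d1, d1, 3, rng)
        # decoder level 2: X1 (down), X2, X3 (up), Y1' (up)
        self.up_x3 = nn.ConvTranspose3d2x(c3, c3, rng)
        self.up_y1 = nn.ConvTranspose3d2x(d1, d1, rng)
        self.dec2a = nn.ConvBNReLU(c1 + c2 + c3 + d1, d2, 3, rng)
        self.dec2b = nn.ConvBNReLU(d2, d2, 3, rng)
        # decoder level 3: X1, X2 (up), Y2' (up)
        self.up_x2 = nn.ConvTranspose3d2x(c2, c2, rng)
        self.up_y2 = nn.ConvTranspose3d2x(d2, d2, rng)
        self.dec3a = nn.ConvBNReLU(c1 + c2 + d2, d3, 3, rng)
        self.dec3b = nn.ConvBNReLU(d3, d3, 3, rng)
        self.head = nn.Conv3d(d3, cfg.n_classes, 1, rng)

    def features(self, x: Tensor | np.ndarray,
                 record: dict[str, tuple] | None = None) -> Tensor:
        """Forward pass up to (excluding) the classification head."""
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

        x1 = self.enc1b(self.enc1a(x))                      # c1 @ full
        note("enc1", x1)
        x1d = F.maxpool3d_2x(x1)
        note("enc1_down", x1d)
        x2 = self.enc2b(self.enc2a(x1d))                    # c2 @ 1/2
        note("enc2", x2)
        x2d = F.maxpool3d_2x(x2)
        note("enc2_down", x2d)
        x3 = self.enc3b(self.enc3a(x2d))                    # c3 @ 1/4
        note("enc3", x3)
        x3d = F.maxpool3d_2x(x3)
        note("enc3_down", x3d)
        x4 = self.inception(F.maxpool3d_2x(self.enc4(x3d)))  # c4 @ 1/8
        note("enc4", x4)

        y1 = F.concat([F.maxpool3d_2x(x2), x3, self.up_x4(x4)], axis=1)
        note("dec1_concat", y1)
        y1 = self.dec1b(self.dec1a(y1))                     # d1 @ 1/4
        note("dec1", y1)
        y2 = F.concat([F.maxpool3d_2x(x1), x2, self.up_x3(x3), self.up_y1(y1)], axis=1)
        note("dec2_concat", y2)
        y2 = self.dec2b(self.dec2a(y2))                     # d2 @ 1/2
        note("dec2", y2)
        y3 = F.concat([x1, self.up_x2(x2), self.up_y2(y2)], axis=1)
        note("dec3_concat", y3)
        y3 = self.dec3b(self.dec3a(y3))                     # d3 @ full
        note("dec3", y3)
        return y3

    def forward(self, x: Tensor | np.ndarray,
                record: dict[str, tuple] | None = None) -> Tensor:
        """Per-voxel class probabilities (N, n_classes, D, H, W)."""
        out = F.softmax(self.head(self.features(x, record)), axis=1)
        if record is not None:
            record["head"] = (out.data.shape[1], tuple(out.data.shape[2:]))
        return out


def build_xunet(cfg: XUnetConfig = XUnetConfig(), seed: int = 0) -> XUNet3D:
    """Construct the segmentation network with seeded initialization."""
    return XUNet3D(cfg, seed=seed)


def seg_forward(net: XUNet3D, vol: np.ndarray) -> np.ndarray:
    """Class probabilities for a (D, H, W) volume or (N, D, H, W) batch.

    Returns (C, D, H, W) for a single volume, (N, C, D, H, W) for a batch;
    per-voxel channel values sum to 1.
    """
    vol = np.asarray(vol, dtype=np.float32)
    single = vol.ndim == 3
    if single:
        vol = vol[None]
    if vol.ndim != 4:
        raise ShapeError(f"expected (D,H,W) or (N,D,H,W), got {vol.shape}")
    net.eval()
    with nn.no_grad():
        out = net(vol[:, None]).data
    return out[0] if single else out


def predict_labels(probs: np.ndarray) -> np.ndarray:
    """Per-voxel argmax over the class axis; ties go to the smaller index.

    Accepts (C, D, H, W) or (N, C, D, H, W) probability grids.
    """
    probs = np.asarray(probs)
    if probs.ndim == 4:
        return probs.argmax(axis=0).astype(np.int16)
    if probs.ndim == 5:
        return probs.argmax(axis=1).astype(np.int16)
    raise ShapeError(f"expected a 4D or 5D probability grid, got {probs.ndim} axes")


def _soft_dice_loss(probs: Tensor, labels: np.ndarray, n_classes: int,
                    eps: float = 1e-5) -> Tensor:
    """Mean (1 - soft Dice) over the foreground classes present anywhere."""
    terms = []
    for c in range(1, n_classes):
        t = (labels == c).astype(probs.data.dtype)[:, None]
        p = F.channel_slice(probs, c, c + 1)
        inter = F.tsum(F.mul(p, t))
        denom = F.tsum(p) + float(t.sum())
        terms.append(1.0 - (2.0 * inter + eps) / (denom + eps))
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))


def train_segmentation(
    net: XUNet3D,
    dataset: list[tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig = TrainConfig(loss_kind="dice_ce", steps=300),
) -> list[float]:
    """Train on (cropped windowed volume, cropped label grid) pairs.

    Loss is voxel cross-entropy plus mean foreground soft-Dice; Adam
    optimizer; the loss trace is reproducible for a fixed ``cfg.seed``.
    """
    if len(dataset) == 0:
        raise DataError("training dataset is empty")
    if cfg.loss_kind not in ("dice_ce", "ce"):
        raise ConfigurationError(f"unsupported segmentation loss: {cfg.loss_kind!r}")
    n_classes = net.cfg.n_classes
    for _, lab in dataset:
        lab = np.asarray(lab)
        if lab.min() < 0 or lab.max() >= n_classes:
            raise DataError(
                f"label values must lie in 0..{n_classes - 1}, "
                f"found range [{lab.min()}, {lab.max()}]"
            )
    rng = np.random.default_rng(cfg.seed)
    net.train()
    opt = nn.Adam(net.parameters(), lr=cfg.learning_rate)
    losses: list[float] = []
    for step in range(cfg.steps):
        idx = rng.integers(0, len(dataset), size=cfg.batch_size)
        vols = np.stack([np.asarray(dataset[i][0], dtype=np.float32) for i in idx])
        labs = np.stack([np.asarray(dataset[i][1], dtype=np.int64) for i in idx])
        net.zero_grad()
        logits = net.head(net.features(vols[:, None]))
        logp = F.log_softmax(logits, axis=1)
        loss = F.nll_loss(logp, labs)
        if cfg.loss_kind == "dice_ce":
            probs = F.exp(logp)
            loss = loss + _soft_dice_loss(probs, labs, n_classes)
        val = loss.item()
        if not np.isfinite(val):
            raise DivergenceError(step)
        loss.backward()
        opt.step()
        losses.append(val)
    return losses
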