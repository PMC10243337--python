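"""Checkpoint files: network weights + architecture config + seed.

A checkpoint is a single ``.npz`` holding every parameter/buffer array plus
a JSON-encoded header identifying the stage (``loc`` or ``seg``), its
architecture config and the training seed, so a file can always be reloaded
into a freshly built network.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import CompatibilityError
from .locnet import LocalizationUNet, LocNetConfig
from .xunet import XUNet3D, XUnetConfig

__all__ = ["save_checkpoint", "load_checkpoint"]


def save_checkpoint(net: LocalizationUNet | XUNet3D, path, seed: int = 0) -> None:
    if isinstance(net, LocalizationUNet):
        kind = "loc"
    elif isinstance(net, XUNet3D):
        kind = "seg"
    else:
        raise TypeError(f"cannot checkpoint object of type {type(net).__name__}")
    header = json.dumps({"kind": kind, "config": net.cfg.to_dict(), "seed": seed})
    arrays = {f"state::{k}": v for k, v in net.state_dict().items()}
    np.savez(Path(path), header=np.frombuffer(header.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path, expect_kind: str | None = None):
    """Rebuild the network stored at ``path``.

    Returns ``(net, kind, seed)``.  Raises :class:`CompatibilityError` if the
    file is not a checkpoint or ``expect_kind`` does not match.
    """
    path = Path(path)
    with np.load(path) as data:
        if "header" not in data:
            raise CompatibilityError(f"{path}: not a checkpoint file")
        header = json.loads(bytes(data["header"]).decode())
        state = {k[len("state::"):]: data[k] for k in data.files if k.startswith("state::")}
    kind = header["kind"]
    if expect_kind is not None and kind != expect_kind:
        raise CompatibilityError(
            f"{path}: expected a {expect_kind!r} checkpoint, found {kind!r}"
        )
    if kind == "loc":
        net = LocalizationUNet(LocNetConfig.from_dict(header["config"]))
    else:
        net = XUNet3D(XUnetConfig.from_dict(header["config"]))
    try:
        net.load_state_dict(state)
    except (KeyError, ValueError) as e:
        raise CompatibilityError(f"{path}: state does not fit the stored config: {e}")
    return net, kind, header["seed"]
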