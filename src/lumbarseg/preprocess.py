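"""CT windowing, localization-heatmap generation, and shape adaptation.

The bone window (level 400 HU, width 1800 HU) maps the lumbar skeletal
intensity range onto [0, 1] for the networks.  The localization target is a
Gaussian-smoothed whole-spine mask, peak-normalized to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .grids import CTVolume, Heatmap, LabelMap

__all__ = ["WindowSpec", "apply_window", "make_heatmap", "resize_to_shape"]

#: bone window for lumbar skeletal tissue (HU)
DEFAULT_WINDOW_LEVEL = 400.0
DEFAULT_WINDOW_WIDTH = 1800.0
#: Gaussian std (voxels) for the localization target
DEFAULT_HEATMAP_SIGMA = 3.0


@dataclass(frozen=True)
class WindowSpec:
    """An HU display window: center ``level`` spanning ``width``."""

    level: float = DEFAULT_WINDOW_LEVEL
    width: float = DEFAULT_WINDOW_WIDTH

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ParameterError(f"window width must be positive, got {self.width}")

    @property
    def lo(self) -> float:
        return self.level - self.width / 2.0

    @property
    def hi(self) -> float:
        return self.level + self.width / 2.0


def apply_window(vol: CTVolume, window: WindowSpec = WindowSpec()) -> CTVolume:
    """Clip HU to the window and rescale affinely to [0, 1].

    ``level - width/2`` maps to 0, ``level + width/2`` to 1; the level
    itself maps to 0.5.  Shape and spacing are unchanged.
    """
    clipped = np.clip(vol.voxels.astype(np.float32), window.lo, window.hi)
    normalized = (clipped - window.lo) / window.width
    return CTVolume(voxels=normalized, spacing=vol.spacing,
                    orientation_tag=vol.orientation_tag)


def make_heatmap(mask: LabelMap, sigma: float = DEFAULT_HEATMAP_SIGMA) -> Heatmap:
    """Gaussian-smooth the binarized spine mask into a localization target.

    Any label > 0 counts as foreground (the whole lumbar spine is one
    localization region).  The smoothed field is divided by its maximum so
    the peak is exactly 1; an empty mask yields an all-zero heatmap.

    Parameters
    ----------
    mask:
        label map whose support defines the spine region.
    sigma:
        isotropic Gaussian std, in voxels.
    """
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    fg = (mask.labels > 0).astype(np.float32)
    smoothed = ndimage.gaussian_filter(fg, sigma=float(sigma))
    peak = float(smoothed.max())
    if peak > 0:
        smoothed = smoothed / peak
    return Heatmap(values=np.clip(smoothed, 0.0, 1.0), spacing=mask.spacing)


def resize_to_shape(
    grid: np.ndarray,
    target_shape: tuple[int, int, int],
    mode: str = "trilinear",
) -> np.ndarray:
    """Resample a 3D grid to an exact target shape.

    ``mode="trilinear"`` uses first-order spline interpolation (continuous
    grids); ``mode="nearest"`` uses nearest-neighbor and therefore preserves
    the label set of integer grids.  The effective spacing of the result is
    the old spacing scaled by ``old_shape / new_shape`` per axis.
    """
    grid = np.asarray(grid)
    target_shape = tuple(int(t) for t in target_shape)
    if len(target_shape) != 3 or any(t < 1 for t in target_shape):
        raise ParameterError(f"target_shape must be 3 positive integers, got {target_shape}")
    if mode not in ("trilinear", "nearest"):
        raise ParameterError(f"unknown interpolation mode: {mode!r}")
    if grid.shape == target_shape:
        return grid.copy()
    zoom = [t / s for t, s in zip(target_shape, grid.shape)]
    order = 1 if mode == "trilinear" else 0
    out = ndimage.zoom(grid, zoom, order=order, mode="nearest", grid_mode=True)
    # ndimage.zoom rounds the output length; force the exact contract
    if out.shape != target_shape:
        out = out[tuple(slice(0, t) for t in target_shape)]
        pad = [(0, t - s) for t, s in zip(target_shape, out.shape)]
        if any(p[1] for p in pad):
            out = np.pad(out, pad, mode="edge")
    return out


def rescaled_spacing(
    spacing: tuple[float, float, float],
    old_shape: tuple[int, int, int],
    new_shape: tuple[int, int, int],
) -> tuple[float, float, float]:
    """Spacing of a grid after :func:`resize_to_shape` (mm per voxel)."""
    return tuple(sp * o / n for sp, o, n in zip(spacing, old_shape, new_shape))
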