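"""Core in-memory containers: CT volumes, label maps, heatmaps, boxes.

Conventions used throughout the package:

* grids are 3D numpy arrays in canonical (closest-to-RAS) axis order;
* ``spacing`` is mm per voxel along each of the three axes;
* indices are 0-based and intervals half-open ``[lo, hi)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BoundsError, DimensionalityError, FormatError, LabelRangeError

#: names of the five lumbar vertebral bodies, keyed by label value
LUMBAR_LABEL_NAMES: dict[int, str] = {1: "L1", 2: "L2", 3: "L3", 4: "L4", 5: "L5"}

#: highest vertebra label handled by the pipeline
N_VERTEBRAE = 5


def _check_grid(arr: np.ndarray) -> None:
    if arr.ndim != 3:
        raise DimensionalityError(f"expected a 3D grid, got {arr.ndim} axes")
    if min(arr.shape) < 1:
        raise DimensionalityError(f"every axis must have length >= 1, got {arr.shape}")


def _check_spacing(spacing: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise FormatError(f"spacing must be 3 positive lengths (mm), got {spacing}")
    return spacing


@dataclass
class CTVolume:
    """A 3D CT scan in Hounsfield units with physical voxel spacing.

    Parameters
    ----------
    voxels:
        3D float array of HU values, canonical axis order.
    spacing:
        mm per voxel along each axis.
    orientation_tag:
        marker for the axis convention the voxels are stored in.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    orientation_tag: str = "RAS"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        _check_grid(self.voxels)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class LabelMap:
    """Integer segmentation aligned to a :class:`CTVolume`.

    0 is background; 1..5 are the lumbar vertebrae L1..L5.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    label_names: dict[int, str] = field(default_factory=lambda: dict(LUMBAR_LABEL_NAMES))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        _check_grid(self.labels)
        self.spacing = _check_spacing(self.spacing)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError(f"labels must be integers, got dtype {self.labels.dtype}")
        lo, hi = int(self.labels.min()), int(self.labels.max())
        if lo < 0 or hi > N_VERTEBRAE:
            raise LabelRangeError(
                f"labels must lie in 0..{N_VERTEBRAE}, found range [{lo}, {hi}]"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


@dataclass
class Heatmap:
    """Scalar localization target/prediction in [0, 1] on a CT lattice."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        _check_grid(self.values)
        self.spacing = _check_spacing(self.spacing)
        vmin, vmax = float(self.values.min()), float(self.values.max())
        if vmin < -1e-6 or vmax > 1 + 1e-6:
            raise FormatError(f"heatmap values must lie in [0, 1], found [{vmin}, {vmax}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass(frozen=True)
class BoundingBox3D:
    """Axis-aligned crop region: per-axis half-open interval [lo, hi)."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "lo", tuple(int(v) for v in self.lo))
        object.__setattr__(self, "hi", tuple(int(v) for v in self.hi))
        for k in range(3):
            if self.lo[k] < 0:
                raise BoundsError(f"axis {k}: lo must be >= 0, got {self.lo[k]}")
            if self.hi[k] <= self.lo[k]:
                raise BoundsError(
                    f"axis {k}: hi must exceed lo, got [{self.lo[k]}, {self.hi[k]})"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    def check_within(self, grid_shape: tuple[int, ...]) -> None:
        for k in range(3):
            if self.hi[k] > grid_shape[k]:
                raise BoundsError(
                    f"axis {k}: box [{self.lo[k]}, {self.hi[k]}) exceeds grid "
                    f"length {grid_shape[k]}"
                )
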