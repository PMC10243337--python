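"""NIfTI reading and writing with a fixed canonical orientation.

All volumes are reoriented to nibabel's closest-to-RAS canonical axis order on
load, so shape statements elsewhere in the package (e.g. network input sizes)
always refer to the same in-memory convention.  Writing produces a NIfTI-1
file with the grid's spacing in the affine; a write/read round trip preserves
voxel values (exactly for integer labels, to float32 for HU).
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import AlignmentError, DimensionalityError, FormatError, LabelRangeError
from .grids import CTVolume, Heatmap, LabelMap

__all__ = ["read_volume", "read_labelmap", "read_heatmap", "write_image"]


def _load_canonical(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(str(path))
    if img.ndim == 4 and img.shape[3] == 1:
        # tolerate a singleton trailing dimension, common in exported NIfTIs
        img = nib.funcs.squeeze_image(img)
    if img.ndim != 3:
        raise DimensionalityError(f"{path}: expected a 3D image, got {img.ndim} axes")
    img = nib.as_closest_canonical(img)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise FormatError(f"{path}: non-positive voxel spacing {zooms}")
    # get_fdata applies scl_slope/scl_inter so values are in HU
    data = np.asarray(img.get_fdata(dtype=np.float64))
    return data, zooms


def read_volume(path: str | os.PathLike) -> CTVolume:
    """Read a CT volume, reorienting to the canonical axis order.

    Voxel values are returned in Hounsfield units (NIfTI scaling applied)
    as float32; spacing comes from the header zooms.
    """
    data, zooms = _load_canonical(path)
    return CTVolume(voxels=data.astype(np.float32), spacing=zooms)


def read_labelmap(path: str | os.PathLike, reference: CTVolume | None = None) -> LabelMap:
    """Read an integer label map, optionally checking alignment to a volume.

    Raises
    ------
    AlignmentError
        if ``reference`` is given and the grids differ in shape.
    FormatError
        if stored values deviate from integers by more than 1e-6.
    LabelRangeError
        if any value lies outside 0..5.
    """
    data, zooms = _load_canonical(path)
    rounded = np.rint(data)
    if np.abs(data - rounded).max(initial=0.0) > 1e-6:
        raise FormatError(f"{path}: label values are not integral")
    labels = rounded.astype(np.int16)
    if reference is not None and labels.shape != reference.shape:
        raise AlignmentError(
            f"{path}: label grid {labels.shape} does not match "
            f"reference volume {reference.shape}"
        )
    lm = LabelMap(labels=labels, spacing=zooms)  # raises LabelRangeError if out of range
    return lm


def read_heatmap(path: str | os.PathLike) -> Heatmap:
    """Read a localization heatmap (values clipped only by validation)."""
    data, zooms = _load_canonical(path)
    return Heatmap(values=data.astype(np.float32), spacing=zooms)


def write_image(grid: CTVolume | LabelMap | Heatmap, path: str | os.PathLike) -> None:
    """Write any grid to NIfTI-1, spacing in the affine diagonal.

    The parent directory must already exist; integer label maps are stored
    as int16, scalar grids as float32.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"parent directory does not exist: {path.parent}")
    if isinstance(grid, LabelMap):
        data = grid.labels.astype(np.int16)
    elif isinstance(grid, CTVolume):
        data = grid.voxels.astype(np.float32)
    elif isinstance(grid, Heatmap):
        data = grid.values.astype(np.float32)
    else:
        raise TypeError(f"cannot write object of type {type(grid).__name__}")
    affine = np.diag(list(grid.spacing) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))
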