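"""Synthetic CT phantoms: five stacked vertebra-like bodies on soft tissue.

Each phantom is an HU-valued volume containing ``n_vertebrae`` ellipsoidal
"vertebral bodies" with a small posterior protrusion, stacked with gaps
along the longest axis and labeled 1..n in stacking order.  Object voxels
get bone-range HU, the background soft-tissue-range HU, and Gaussian noise
is added everywhere.  The matching label map and the Gaussian localization
heatmap make every pipeline stage testable without real scans.

The geometry is deliberately simple — enough to exercise localization,
cropping, multi-class segmentation and surface metrics; no anatomical
realism is claimed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import GeometryError, ParameterError
from .grids import CTVolume, Heatmap, LabelMap
from .preprocess import DEFAULT_HEATMAP_SIGMA, make_heatmap

__all__ = ["PhantomConfig", "generate_phantom", "generate_dataset"]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and intensity model of the synthetic phantom."""

    shape: tuple[int, int, int] = (64, 64, 96)
    n_vertebrae: int = 5
    body_radius_range: tuple[float, float] = (6.0, 9.0)
    gap: float = 3.0
    bone_hu_range: tuple[float, float] = (300.0, 1200.0)
    tissue_hu_range: tuple[float, float] = (-100.0, 100.0)
    noise_sd: float = 20.0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    heatmap_sigma: float = DEFAULT_HEATMAP_SIGMA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vertebrae < 1:
            raise ParameterError("n_vertebrae must be >= 1")
        if self.bone_hu_range[0] <= self.tissue_hu_range[1]:
            raise ParameterError(
                f"bone HU range {self.bone_hu_range} must lie above "
                f"tissue HU range {self.tissue_hu_range}"
            )

    @property
    def stack_axis(self) -> int:
        return int(np.argmax(self.shape))


def _vertebra_mask(shape, center, r_inplane, r_axial, stack_axis) -> np.ndarray:
    """Ellipsoidal body plus a posterior protrusion (spinous-process stub)."""
    grids = np.indices(shape, dtype=np.float32)
    radii = [r_inplane, r_inplane, r_inplane]
    radii[stack_axis] = r_axial
    dist2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    body = dist2 <= 1.0
    # protrusion: a thin box reaching backward along the first in-plane axis
    post_axis = 0 if stack_axis != 0 else 1
    lo = [int(round(c - r / 2)) for c, r in zip(center, radii)]
    hi = [int(round(c + r / 2)) + 1 for c, r in zip(center, radii)]
    lo[post_axis] = int(round(center[post_axis] + radii[post_axis] * 0.6))
    hi[post_axis] = int(round(center[post_axis] + radii[post_axis] * 1.6)) + 1
    sl = tuple(slice(max(0, l), min(s, h)) for l, h, s in zip(lo, hi, shape))
    proc = np.zeros(shape, dtype=bool)
    if all(s.stop > s.start for s in sl):
        proc[sl] = True
    return body | proc


def generate_phantom(cfg: PhantomConfig = PhantomConfig()) -> tuple[CTVolume, LabelMap, Heatmap]:
    """Generate one phantom triple (volume, labels, heatmap), seeded.

    Identical configs (including seed) produce bit-identical outputs.

    Raises
    ------
    GeometryError
        if the vertebra stack cannot fit inside ``cfg.shape``.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = tuple(cfg.shape)
    ax = cfg.stack_axis
    n = cfg.n_vertebrae
    r_lo, r_hi = cfg.body_radius_range
    radii = rng.uniform(r_lo, r_hi, size=n)
    r_axial = 0.75 * radii  # bodies are flatter along the stack
    extent = float(2 * r_axial.sum() + cfg.gap * (n - 1))
    margin = (shape[ax] - extent) / 2.0
    if margin < 1.0:
        raise GeometryError(
            f"stack of {n} bodies (extent {extent:.1f} vox) does not fit in "
            f"axis {ax} of length {shape[ax]}"
        )
    labels = np.zeros(shape, dtype=np.int16)
    pos = margin
    for i in range(n):
        center = [s / 2.0 + rng.uniform(-1.5, 1.5) for s in shape]
        center[ax] = pos + r_axial[i]
        pos += 2 * r_axial[i] + cfg.gap
        mask = _vertebra_mask(shape, center, radii[i], r_axial[i], ax)
        labels[mask & (labels == 0)] = i + 1

    tissue = rng.uniform(*cfg.tissue_hu_range)
    hu = np.full(shape, tissue, dtype=np.float32)
    for i in range(n):
        hu[labels == i + 1] = rng.uniform(*cfg.bone_hu_range)
    hu += rng.normal(0.0, cfg.noise_sd, size=shape).astype(np.float32)

    vol = CTVolume(voxels=hu, spacing=cfg.spacing)
    lm = LabelMap(labels=labels, spacing=cfg.spacing)
    hm = make_heatmap(lm, sigma=cfg.heatmap_sigma)
    return vol, lm, hm


@dataclass
class DatasetManifest:
    """Seeds, splits and (optional) file paths of a generated dataset."""

    base_config: dict
    items: list[dict] = field(default_factory=list)

    def train_items(self) -> list[dict]:
        return [it for it in self.items if it["split"] == "train"]

    def test_items(self) -> list[dict]:
        return [it for it in self.items if it["split"] == "test"]

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"base_config": self.base_config, "items": self.items}, indent=2))

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        d = json.loads(Path(path).read_text())
        return cls(base_config=d["base_config"], items=d["items"])


def generate_dataset(
    n: int,
    cfg: PhantomConfig = PhantomConfig(),
    n_train: int | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[tuple[CTVolume, LabelMap, Heatmap]], DatasetManifest]:
    """Generate ``n`` phantoms with per-item seeds ``cfg.seed + index``.

    ``n_train`` (default: all) marks the first items as the training split.
    If ``out_dir`` is given, NIfTI triples are written there and their paths
    recorded in the manifest; regeneration from the manifest seeds
    reproduces the volumes exactly.
    """
    if n < 1:
        raise ParameterError(f"dataset size must be >= 1, got {n}")
    if n_train is None:
        n_train = n
    if not (0 <= n_train <= n):
        raise ParameterError(f"n_train must lie in [0, {n}], got {n_train}")
    from dataclasses import asdict, replace

    base = asdict(cfg)
    manifest = DatasetManifest(base_config=base)
    triples = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for i in range(n):
        item_cfg = replace(cfg, seed=cfg.seed + i)
        triple = generate_phantom(item_cfg)
        triples.append(triple)
        item = {"index": i, "seed": item_cfg.seed,
                "split": "train" if i < n_train else "test"}
        if out_dir is not None:
            from .io_nifti import write_image

            paths = {}
            for kind, grid in zip(("volume", "labels", "heatmap"), triple):
                p = out_dir / f"{kind}_{i:03d}.nii.gz"
                write_image(grid, p)
                paths[kind] = str(p)
            item["paths"] = paths
        manifest.items.append(item)
    return triples, manifest
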