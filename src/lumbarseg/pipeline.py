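"""End-to-end orchestration of the two-stage segmentation method.

Inference chain: window the CT -> resize to the localization input size ->
predict the spine heatmap -> threshold / largest component / expanded
bounding box -> map the box back to native indices -> crop the native
windowed volume -> resize the crop to the segmentation input size ->
class-probability forward pass -> argmax -> nearest-neighbor resize back to
the crop -> embed in a full-size label map (background outside the box).

The ROI is computed at the localization-network resolution and its box is
mapped to native indices by per-axis scale factors, rounded outward so no
voxel the low-resolution box covered is lost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .checkpoint import load_checkpoint, save_checkpoint
from .errors import DataError, ParameterError, PairingError
from .grids import BoundingBox3D, CTVolume, LabelMap
from .io_nifti import read_labelmap, read_volume
from .locnet import LocalizationUNet, LocNetConfig, TrainConfig, loc_forward
from .metrics import MetricReport, evaluate_case, write_report_csv
from .phantom import DatasetManifest, PhantomConfig, generate_phantom
from .preprocess import WindowSpec, apply_window, make_heatmap, resize_to_shape
from .roi_crop import (
    DEFAULT_EXPAND_FRAC,
    DEFAULT_THRESHOLD_FRAC,
    crop_to_bbox,
    roi_from_heatmap,
)
from .xunet import XUNet3D, XUnetConfig, predict_labels, seg_forward

__all__ = ["PipelineConfig", "run_inference", "run_training", "run_evaluation",
           "split_folds", "gt_roi_box"]

log = logging.getLogger("lumbarseg")


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the two-stage pipeline in one place."""

    window: WindowSpec = WindowSpec()
    heatmap_sigma: float = 3.0
    loc: LocNetConfig = LocNetConfig()
    seg: XUnetConfig = XUnetConfig()
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC
    expand_frac: float = DEFAULT_EXPAND_FRAC
    crop_source: str = "heatmap"  # or "hu": threshold raw intensities instead
    seed: int = 0

    def __post_init__(self) -> None:
        if self.crop_source not in ("heatmap", "hu"):
            raise ParameterError(f"crop_source must be 'heatmap' or 'hu', got {self.crop_source!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kw = {}
        if "window" in d:
            kw["window"] = WindowSpec(level=d["window"].get("level", 400),
                                      width=d["window"].get("width", 1800))
        if "heatmap" in d:
            kw["heatmap_sigma"] = d["heatmap"].get("sigma", 3.0)
        if "loc" in d:
            kw["loc"] = LocNetConfig.from_dict(d["loc"])
        if "seg" in d:
            kw["seg"] = XUnetConfig.from_dict(d["seg"])
        if "crop" in d:
            kw["threshold_frac"] = d["crop"].get("threshold_frac", DEFAULT_THRESHOLD_FRAC)
            kw["expand_frac"] = d["crop"].get("expand_frac", DEFAULT_EXPAND_FRAC)
            kw["crop_source"] = d["crop"].get("source", "heatmap")
        if "seed" in d:
            kw["seed"] = int(d["seed"])
        return cls(**kw)


def _scale_box(box: BoundingBox3D, from_shape, to_shape) -> BoundingBox3D:
    """Map a box between grids of different shape, rounding outward."""
    lo, hi = [], []
    for k in range(3):
        f = to_shape[k] / from_shape[k]
        lo.append(max(0, int(np.floor(box.lo[k] * f))))
        hi.append(min(to_shape[k], int(np.ceil(box.hi[k] * f))))
    return BoundingBox3D(lo=tuple(lo), hi=tuple(hi))


def run_inference(
    vol: CTVolume,
    loc_net: LocalizationUNet,
    seg_net: XUNet3D,
    cfg: PipelineConfig = PipelineConfig(),
) -> tuple[LabelMap, BoundingBox3D]:
    """Segment the five lumbar vertebrae of one CT volume.

    Returns the full-size label map and the native-resolution bounding box
    that was cropped.  Raises :class:`~lumbarseg.errors.EmptyROIError` if
    localization finds no foreground.
    """
    windowed = apply_window(vol, cfg.window)
    loc_in = resize_to_shape(windowed.voxels, cfg.loc.input_shape, mode="trilinear")
    hm = loc_forward(loc_net, loc_in)
    source = hm if cfg.crop_source == "heatmap" else loc_in
    box_small = roi_from_heatmap(source, cfg.threshold_frac, cfg.expand_frac)
    box = _scale_box(box_small, cfg.loc.input_shape, vol.shape)
    log.info("ROI box (native indices): lo=%s hi=%s", box.lo, box.hi)

    crop = crop_to_bbox(windowed.voxels, box)
    seg_in = resize_to_shape(crop, cfg.seg.input_shape, mode="trilinear")
    probs = seg_forward(seg_net, seg_in)
    labels_small = predict_labels(probs)
    labels_crop = resize_to_shape(labels_small, crop.shape, mode="nearest")

    full = np.zeros(vol.shape, dtype=np.int16)
    full[box.slices()] = labels_crop
    return LabelMap(labels=full, spacing=vol.spacing), box


def gt_roi_box(labels: LabelMap, sigma: float = 3.0,
               threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
               expand_frac: float = DEFAULT_EXPAND_FRAC) -> BoundingBox3D:
    """Reference ROI from the ground-truth mask's own heatmap (training)."""
    return roi_from_heatmap(make_heatmap(labels, sigma), threshold_frac, expand_frac)


def _load_triples(manifest: DatasetManifest, split: str):
    """Regenerate (or read) the phantom triples of one manifest split."""
    items = [it for it in manifest.items if it["split"] == split]
    if not items:
        raise DataError(f"manifest has no items in split {split!r}")
    triples = []
    for it in items:
        if "paths" in it:
            paths = it["paths"]
            for p in paths.values():
                if not Path(p).exists():
                    raise DataError(f"manifest file missing: {p}")
            vol = read_volume(paths["volume"])
            lm = read_labelmap(paths["labels"], reference=vol)
            from .io_nifti import read_heatmap

            hm = read_heatmap(paths["heatmap"])
            triples.append((vol, lm, hm))
        else:
            base = dict(manifest.base_config)
            base["seed"] = it["seed"]
            base = {k: tuple(v) if isinstance(v, list) else v for k, v in base.items()}
            triples.append(generate_phantom(PhantomConfig(**base)))
    return triples


def run_training(
    manifest: DatasetManifest | str | Path,
    cfg: PipelineConfig,
    stage: str,
    out_path: str | Path,
    train_cfg: TrainConfig | None = None,
) -> list[float]:
    """Train one stage on the manifest's train split; write a checkpoint.

    ``stage`` is ``"loc"`` (heatmap regression at the localization input
    size) or ``"seg"`` (vertebra classification on ground-truth-derived
    crops at the segmentation input size).  Returns the loss trace.
    """
    if stage not in ("loc", "seg"):
        raise ParameterError(f"unknown training stage: {stage!r}")
    if isinstance(manifest, (str, Path)):
        manifest = DatasetManifest.load(manifest)
    triples = _load_triples(manifest, "train")

    if stage == "loc":
        from .locnet import build_localization_net, train_localization

        tc = train_cfg or TrainConfig(seed=cfg.seed)
        dataset = []
        for vol, lm, hm in triples:
            win = apply_window(vol, cfg.window).voxels
            x = resize_to_shape(win, cfg.loc.input_shape, mode="trilinear")
            y = resize_to_shape(hm.values, cfg.loc.input_shape, mode="trilinear")
            dataset.append((x, np.clip(y, 0.0, 1.0)))
        net = build_localization_net(cfg.loc, seed=tc.seed)
        losses = train_localization(net, dataset, tc)
    else:
        from .xunet import build_xunet, train_segmentation

        tc = train_cfg or TrainConfig(loss_kind="dice_ce", steps=300, seed=cfg.seed)
        dataset = []
        for vol, lm, hm in triples:
            box = roi_from_heatmap(hm, cfg.threshold_frac, cfg.expand_frac)
            win = apply_window(vol, cfg.window).voxels
            x = resize_to_shape(crop_to_bbox(win, box), cfg.seg.input_shape, "trilinear")
            y = resize_to_shape(crop_to_bbox(lm.labels, box), cfg.seg.input_shape, "nearest")
            dataset.append((x, y))
        net = build_xunet(cfg.seg, seed=tc.seed)
        losses = train_segmentation(net, dataset, tc)

    save_checkpoint(net, out_path, seed=tc.seed)
    log.info("stage %s: %d steps, final loss %.4g -> %s",
             stage, len(losses), losses[-1], out_path)
    return losses


def run_evaluation(pred_dir: str | Path, gt_dir: str | Path,
                   out_csv: str | Path | None = None):
    """Per-case, per-label metric table for paired prediction/truth files.

    Files are paired by identical filename in the two directories; any
    orphan raises :class:`PairingError` naming it.
    """
    pred_dir, gt_dir = Path(pred_dir), Path(gt_dir)
    pred_files = {p.name: p for p in sorted(pred_dir.glob("*.nii*"))}
    gt_files = {p.name: p for p in sorted(gt_dir.glob("*.nii*"))}
    orphans = sorted(set(pred_files) ^ set(gt_files))
    if orphans:
        raise PairingError(f"unpaired files: {orphans}")
    if not pred_files:
        raise PairingError("no NIfTI files found to evaluate")
    reports: dict[str, MetricReport] = {}
    for name in sorted(pred_files):
        pred = read_labelmap(pred_files[name])
        gt = read_labelmap(gt_files[name])
        if pred.shape != gt.shape:
            raise PairingError(f"{name}: prediction and truth shapes differ")
        reports[name] = evaluate_case(pred, gt, gt.spacing)
    if out_csv is not None:
        return write_report_csv(reports, out_csv)
    import pandas as pd

    frames = []
    for case, rep in reports.items():
        df = rep.to_dataframe()
        df.insert(0, "case", case)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def split_folds(n: int, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Shuffle indices 0..n-1 into k near-equal folds (cross-validation)."""
    if k < 2 or k > n:
        raise ParameterError(f"need 2 <= k <= n, got k={k}, n={n}")
    idx = np.random.default_rng(seed).permutation(n)
    return [np.sort(f) for f in np.array_split(idx, k)]
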