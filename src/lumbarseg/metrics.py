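"""Per-vertebra segmentation metrics: DSC, FND, FPD, MSD, ASD.

Overlap metrics share one denominator, so the identity
``DSC + (FND + FPD)/2 = 1`` holds exactly whenever any of TP, FN, FP is
nonzero:

    DSC = 2 TP / (2 TP + FN + FP)
    FND = 2 FN / (2 TP + FN + FP)      (under-segmentation rate)
    FPD = 2 FP / (2 TP + FN + FP)      (over-segmentation rate)

Surface metrics operate on the 6-connectivity border voxels of each mask,
with voxel centers scaled to mm by the grid spacing.  MSD is the symmetric
Hausdorff distance (max over both directed maxima of nearest-neighbor
distances); ASD averages the pooled multiset of directed nearest-neighbor
distances from both surfaces (a directed-means variant is switchable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import AlignmentError, UndefinedMetricError, UndefinedSurfaceError
from .grids import LabelMap, N_VERTEBRAE

__all__ = [
    "ConfusionCounts",
    "SurfacePointSet",
    "MetricReport",
    "confusion_counts",
    "overlap_metrics",
    "extract_surface",
    "surface_distances",
    "evaluate_case",
    "write_report_csv",
]

METRIC_COLUMNS = ["DSC", "FND", "FPD", "MSD", "ASD"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel-level true-positive / false-negative / false-positive counts."""

    TP: int
    FN: int
    FP: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.FP) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class SurfacePointSet:
    """Border-voxel centers of one mask, in mm."""

    points: np.ndarray  # (n, 3) float
    source: str = "pred"


def _labels_of(x) -> np.ndarray:
    return x.labels if isinstance(x, LabelMap) else np.asarray(x)


def confusion_counts(pred, gt, label: int) -> ConfusionCounts:
    """Count TP/FN/FP voxels for one label between aligned grids."""
    p, g = _labels_of(pred), _labels_of(gt)
    if p.shape != g.shape:
        raise AlignmentError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    pm, gm = p == label, g == label
    tp = int(np.count_nonzero(pm & gm))
    fn = int(np.count_nonzero(~pm & gm))
    fp = int(np.count_nonzero(pm & ~gm))
    return ConfusionCounts(TP=tp, FN=fn, FP=fp)


def overlap_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(DSC, FND, FPD) from confusion counts.

    Raises
    ------
    UndefinedMetricError
        when TP = FN = FP = 0 (label absent from both masks).
    """
    denom = 2 * c.TP + c.FN + c.FP
    if denom == 0:
        raise UndefinedMetricError("label absent from both masks")
    return 2 * c.TP / denom, 2 * c.FN / denom, 2 * c.FP / denom


def extract_surface(mask: np.ndarray, spacing: tuple[float, float, float],
                    source: str = "pred") -> SurfacePointSet:
    """Centers of foreground voxels with a background (or edge) 6-neighbor."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise UndefinedSurfaceError("mask is empty; surface undefined")
    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    border = mask & ~interior
    pts = np.argwhere(border).astype(np.float64) * np.asarray(spacing, dtype=np.float64)
    return SurfacePointSet(points=pts, source=source)


def surface_distances(pred_surface: SurfacePointSet,
                      gt_surface: SurfacePointSet,
                      asd_mode: str = "pooled") -> tuple[float, float]:
    """(MSD, ASD) in mm between two surface point sets.

    ``asd_mode="pooled"`` averages all directed nearest-neighbor distances
    from both sets together; ``"directed_means"`` averages the two directed
    means instead.
    """
    a, b = pred_surface.points, gt_surface.points
    if len(a) == 0 or len(b) == 0:
        raise UndefinedSurfaceError("empty surface point set")
    d_ab, _ = cKDTree(b).query(a, k=1)
    d_ba, _ = cKDTree(a).query(b, k=1)
    msd = max(float(d_ab.max()), float(d_ba.max()))
    if asd_mode == "pooled":
        asd = float(np.concatenate([d_ab, d_ba]).mean())
    elif asd_mode == "directed_means":
        asd = float((d_ab.mean() + d_ba.mean()) / 2.0)
    else:
        raise ValueError(f"unknown asd_mode: {asd_mode!r}")
    return msd, asd


@dataclass
class MetricReport:
    """Per-label metric rows (1..5) plus their mean over valid labels."""

    rows: dict[int, dict] = field(default_factory=dict)

    @property
    def mean(self) -> dict:
        out = {}
        for col in METRIC_COLUMNS:
            vals = [r[col] for r in self.rows.values()
                    if r["valid"] and np.isfinite(r[col])]
            out[col] = float(np.mean(vals)) if vals else float("nan")
        return out

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for label in sorted(self.rows):
            r = self.rows[label]
            recs.append({"label": label, **{c: r[c] for c in METRIC_COLUMNS},
                         "valid": r["valid"]})
        m = self.mean
        recs.append({"label": "mean", **m, "valid": True})
        return pd.DataFrame.from_records(recs)


def evaluate_case(pred, gt, spacing: tuple[float, float, float],
                  labels: tuple[int, ...] = tuple(range(1, N_VERTEBRAE + 1)),
                  asd_mode: str = "pooled") -> MetricReport:
    """All five metrics for every vertebra label of one case.

    Labels absent from both masks are flagged invalid and excluded from the
    mean; labels present in only one mask get overlap metrics (DSC = 0) but
    undefined (NaN) surface distances.
    """
    p, g = _labels_of(pred), _labels_of(gt)
    if p.shape != g.shape:
        raise AlignmentError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    report = MetricReport()
    nan = float("nan")
    for label in labels:
        c = confusion_counts(p, g, label)
        if 2 * c.TP + c.FN + c.FP == 0:
            report.rows[label] = {m: nan for m in METRIC_COLUMNS} | {"valid": False}
            continue
        dsc, fnd, fpd = overlap_metrics(c)
        pm, gm = p == label, g == label
        if pm.any() and gm.any():
            msd, asd = surface_distances(
                extract_surface(pm, spacing, "pred"),
                extract_surface(gm, spacing, "gt"),
                asd_mode=asd_mode,
            )
        else:
            msd = asd = nan
        report.rows[label] = {"DSC": dsc, "FND": fnd, "FPD": fpd,
                              "MSD": msd, "ASD": asd, "valid": True}
    return report


def write_report_csv(reports: dict[str, MetricReport], path) -> pd.DataFrame:
    """Concatenate per-case reports into one CSV (column order as published
    result tables: label, DSC, FND, FPD, MSD, ASD)."""
    frames = []
    for case, rep in reports.items():
        df = rep.to_dataframe()
        df.insert(0, "case", case)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(path, index=False)
    return table
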