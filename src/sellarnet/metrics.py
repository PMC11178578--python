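"""Evaluation metrics: IoU/precision, PCK/MPCK, mDistance, fold aggregation,
model comparison deltas and the pixel-to-millimetre scale estimate.

Landmark metrics follow the keypoint-evaluation convention for partially
annotated data: a landmark counts only where ground truth exists, errors are
first averaged within a structure and then averaged (unweighted) across the
four structures.  PCK uses a radius of ``alpha`` x a reference image dimension
(default: 20% of image height, i.e. 144 px on a 1280x720 frame).  Quantities
that are undefined on a given input (empty union, nothing predicted, no
annotated landmark) are reported as NaN rather than a misleading number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "MetricConfig",
    "MetricReport",
    "FoldAggregate",
    "ScaleEstimate",
    "iou",
    "precision",
    "pck_threshold",
    "mpck",
    "mdistance",
    "aggregate_folds",
    "estimate_scale",
    "distance_to_mm",
    "compare_reports",
    "format_report_table",
]


class PCKReference(str, Enum):
    IMAGE_HEIGHT = "image_height"
    IMAGE_WIDTH = "image_width"
    DIAGONAL = "diagonal"


@dataclass(frozen=True)
class MetricConfig:
    pck_alpha: float = 0.2
    pck_reference: PCKReference = PCKReference.IMAGE_HEIGHT
    image_size: tuple[int, int] = (1280, 720)  # (width, height)

    def __post_init__(self) -> None:
        if not 0 < self.pck_alpha <= 1:
            raise ValueError("pck_alpha must be in (0, 1]")


@dataclass
class MetricReport:
    """Per-class segmentation scores and per-structure landmark scores (percent/px)."""

    iou_percent: dict[str, float]
    precision_percent: dict[str, float]
    pck_percent: dict[str, float]
    mpck_percent: float
    mdistance_pixels: float
    n_frames: int

    def flat(self) -> dict[str, float]:
        out = {f"iou_{k}": v for k, v in self.iou_percent.items()}
        out.update({f"precision_{k}": v for k, v in self.precision_percent.items()})
        out.update({f"pck_{k}": v for k, v in self.pck_percent.items()})
        out["mpck"] = self.mpck_percent
        out["mdistance"] = self.mdistance_pixels
        return out


@dataclass
class FoldAggregate:
    """mean +/- std of each metric across cross-validation folds."""

    mean: dict[str, float]
    std: dict[str, float]
    n_folds: int


@dataclass(frozen=True)
class ScaleEstimate:
    mm_per_pixel: float

    def __post_init__(self) -> None:
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")


def _check_shapes(predicted_mask: np.ndarray, gt_mask: np.ndarray) -> None:
    if predicted_mask.shape != gt_mask.shape:
        raise ValueError(f"mask shape mismatch: {predicted_mask.shape} vs {gt_mask.shape}")


def iou(predicted_mask, gt_mask, class_id: int) -> float:
    """100 x |intersection| / |union| for one class; NaN when both sets empty."""
    pred = np.asarray(predicted_mask) == class_id
    gt = np.asarray(gt_mask) == class_id
    _check_shapes(pred, gt)
    union = np.logical_or(pred, gt).sum()
    if union == 0:
        return math.nan
    return 100.0 * np.logical_and(pred, gt).sum() / union


def precision(predicted_mask, gt_mask, class_id: int) -> float:
    """100 x TP / predicted-positive pixels; NaN when nothing is predicted."""
    pred = np.asarray(predicted_mask) == class_id
    gt = np.asarray(gt_mask) == class_id
    _check_shapes(pred, gt)
    positive = pred.sum()
    if positive == 0:
        return math.nan
    return 100.0 * np.logical_and(pred, gt).sum() / positive


def pck_threshold(config: MetricConfig = MetricConfig()) -> float:
    """Tolerance radius in pixels: alpha x reference dimension."""
    w, h = config.image_size
    ref = {
        PCKReference.IMAGE_HEIGHT: h,
        PCKReference.IMAGE_WIDTH: w,
        PCKReference.DIAGONAL: math.hypot(w, h),
    }[config.pck_reference]
    return config.pck_alpha * ref


def _landmark_errors(predictions, ground_truth, annotated):
    """Per-structure lists of Euclidean errors over annotated instances."""
    pred = np.asarray(predictions, dtype=float)
    gt = np.asarray(ground_truth, dtype=float)
    ann = np.asarray(annotated, dtype=bool)
    if pred.shape != gt.shape or pred.shape[:2] != ann.shape:
        raise ValueError("predictions, ground truth and annotated mask disagree in shape")
    dists = np.linalg.norm(pred - gt, axis=-1)  # (n_frames, n_structures)
    return [dists[ann[:, s], s] for s in range(ann.shape[1])]


def mpck(predictions, ground_truth, annotated,
         config: MetricConfig = MetricConfig(),
         structure_names: list[str] | None = None) -> tuple[dict[str, float], float]:
    """Per-structure PCK (percent within the tolerance radius) and their mean.

    Structures with no annotated instance anywhere are excluded from the mean;
    with no annotated landmark at all the MPCK is NaN.
    """
    errors = _landmark_errors(predictions, ground_truth, annotated)
    thr = pck_threshold(config)
    names = structure_names or [f"structure_{i}" for i in range(len(errors))]
    per: dict[str, float] = {}
    means = []
    for name, e in zip(names, errors):
        if len(e) == 0:
            per[name] = math.nan
            continue
        per[name] = 100.0 * float(np.mean(e <= thr))
        means.append(per[name])
    return per, (float(np.mean(means)) if means else math.nan)


def mdistance(predictions, ground_truth, annotated,
              structure_names: list[str] | None = None) -> tuple[dict[str, float], float]:
    """Mean Euclidean error per structure (px) and the mean across structures."""
    errors = _landmark_errors(predictions, ground_truth, annotated)
    names = structure_names or [f"structure_{i}" for i in range(len(errors))]
    per: dict[str, float] = {}
    means = []
    for name, e in zip(names, errors):
        if len(e) == 0:
            per[name] = math.nan
            continue
        per[name] = float(np.mean(e))
        means.append(per[name])
    return per, (float(np.mean(means)) if means else math.nan)


def aggregate_folds(reports: list[MetricReport], population_std: bool = True) -> FoldAggregate:
    """Unweighted mean and (population by default) std across fold reports.

    NaN fold values (undefined metrics on a fold) are excluded per metric.
    """
    if not reports:
        raise ValueError("need at least one fold report")
    keys = reports[0].flat().keys()
    mean: dict[str, float] = {}
    std: dict[str, float] = {}
    ddof = 0 if population_std else 1
    for k in keys:
        vals = np.array([r.flat()[k] for r in reports], dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            mean[k], std[k] = math.nan, math.nan
        else:
            mean[k] = float(vals.mean())
            std[k] = float(vals.std(ddof=ddof)) if len(vals) > ddof else 0.0
    return FoldAggregate(mean=mean, std=std, n_folds=len(reports))


def estimate_scale(diameter_mm: tuple[float, float],
                   diameter_pixels: tuple[float, float]) -> ScaleEstimate:
    """mm-per-pixel from a known structure size, e.g. the sella diameter.

    Evaluated at matched endpoints; returns the common value when the two
    endpoints agree (10-15 mm over 200-300 px -> 0.05 mm/px), otherwise the
    midpoint of the two ratios.
    """
    if min(*diameter_mm, *diameter_pixels) <= 0:
        raise ValueError("diameters must be positive")
    ratios = (diameter_mm[0] / diameter_pixels[0], diameter_mm[1] / diameter_pixels[1])
    return ScaleEstimate(mm_per_pixel=float(np.mean(ratios)))


def distance_to_mm(mean_px: float, std_px: float, scale: ScaleEstimate) -> tuple[float, float]:
    """Convert a mean +/- std pixel error to a (low, high) range in mm, 2 dp."""
    low = (mean_px - std_px) * scale.mm_per_pixel
    high = (mean_px + std_px) * scale.mm_per_pixel
    if low < 0:
        import warnings

        warnings.warn("std exceeds mean; clamping lower endpoint at 0 mm")
        low = 0.0
    return round(low, 2), round(high, 2)


def compare_reports(report_a: FoldAggregate, report_b: FoldAggregate) -> dict[str, float]:
    """Per-metric differences a - b (2 dp), e.g. a new model against a baseline."""
    if set(report_a.mean) != set(report_b.mean):
        raise ValueError("aggregates cover different metric sets")
    return {k: round(report_a.mean[k] - report_b.mean[k], 2) for k in report_a.mean}


def format_report_table(aggregate: FoldAggregate, decimals: int = 2) -> str:
    """Render a mean +/- std table row per metric (cross-validation style)."""
    lines = [f"{'metric':30s}  mean±std"]
    for k in aggregate.mean:
        lines.append(
            f"{k:30s}  {aggregate.mean[k]:.{decimals}f}±{aggregate.std[k]:.{decimals}f}"
        )
    return "\n".join(lines)
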