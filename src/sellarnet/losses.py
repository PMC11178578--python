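"""Loss terms for imbalanced multi-task training and their weighted combination.

The training objective is

    Loss = w1 * Dice + w2 * BDL + w3 * Wing + w4 * FL

where soft Dice and boundary loss (BDL, predicted probability integrated
against the signed Euclidean distance map of the target region) drive
segmentation, and Wing loss on normalized coordinates plus focal loss (FL) on
the per-structure presence logits drive landmark detection.  The default
weights are (0.9, 0.1, 0.8, 0.2).

Every term masks unannotated structures: segmentation terms average only over
region classes flagged annotated, and Wing/FL only over landmarks whose
ground truth exists, which is what makes training on a partially annotated
dataset possible.  All functions accept numpy arrays or autograd tensors and
return a 0-d :class:`~sellarnet.nn.Tensor` (float() it for the value;
backward() it for training).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .nn import Tensor
from .nn import autograd as ag

__all__ = [
    "LossWeights",
    "LossConfig",
    "LossBreakdown",
    "SegVariant",
    "dice_loss",
    "generalized_dice_loss",
    "cross_entropy_loss",
    "boundary_loss",
    "signed_distance_map",
    "wing_loss",
    "mse_coordinate_loss",
    "focal_loss",
    "combined_loss",
]

_FG_CLASSES = (1, 2)  # sella, clival recess


@dataclass(frozen=True)
class LossWeights:
    """Weights (w1..w4) on Dice, boundary, Wing and focal terms."""

    w1: float = 0.9
    w2: float = 0.1
    w3: float = 0.8
    w4: float = 0.2

    def __post_init__(self) -> None:
        if min(self.w1, self.w2, self.w3, self.w4) < 0:
            raise ValueError("loss weights must be non-negative")


class SegVariant(str, enum.Enum):
    DICE = "dice"
    GENERALIZED_DICE = "generalized_dice"
    CROSS_ENTROPY = "cross_entropy"


class BoundaryVariant(str, enum.Enum):
    SIGNED_DISTANCE = "signed_distance"
    NONE = "none"


class CoordVariant(str, enum.Enum):
    WING = "wing"
    MSE = "mse"


@dataclass(frozen=True)
class LossConfig:
    """Internal constants; Wing operates on a percent-of-image error scale."""

    wing_omega: float = 10.0
    wing_epsilon: float = 2.0
    wing_scale: float = 100.0     # |pred - target| multiplier before the Wing curve
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    dice_smooth: float = 1e-5
    seg_variant: SegVariant = SegVariant.DICE
    boundary_variant: BoundaryVariant = BoundaryVariant.SIGNED_DISTANCE
    coord_variant: CoordVariant = CoordVariant.WING

    def __post_init__(self) -> None:
        if self.wing_omega <= 0 or self.wing_epsilon <= 0:
            raise ValueError("wing_omega and wing_epsilon must be positive")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")


@dataclass
class LossBreakdown:
    """The four term values and their weighted total (floats; graph for backward)."""

    dice: float
    bdl: float
    wing: float
    focal: float
    total: float
    graph: Tensor | None = field(default=None, repr=False, compare=False)


def _prep_seg(class_probabilities, target) -> tuple[Tensor, np.ndarray, dict[int, bool]]:
    p = Tensor.as_tensor(class_probabilities)
    if hasattr(target, "labels"):
        labels = np.asarray(target.labels)
        flags = dict(target.class_annotated)
    else:
        labels = np.asarray(target)
        flags = {c: True for c in _FG_CLASSES}
    if p.ndim == 3:
        p = p.reshape((1,) + p.shape)
    if labels.ndim == 2:
        labels = labels[None]
    if p.shape[0] != labels.shape[0] or p.shape[2:] != labels.shape[1:]:
        raise ValueError(f"probability/target shape mismatch: {p.shape} vs {labels.shape}")
    if np.min(p.data) < -1e-6 or np.max(p.data) > 1 + 1e-6:
        raise ValueError("class probabilities must lie in [0, 1]")
    return p, labels, flags


def dice_loss(class_probabilities, target, smooth: float = 1e-5) -> Tensor:
    """Soft Dice loss averaged over annotated foreground classes (in [0, 1])."""
    p, labels, flags = _prep_seg(class_probabilities, target)
    terms = []
    for c in _FG_CLASSES:
        if not flags.get(c, True):
            continue
        q = (labels == c).astype(np.float32)
        pc = ag.sum_(p * _one_hot_channel(p.shape, c), axis=1)
        inter = ag.sum_(pc * Tensor(q))
        denom = ag.sum_(pc) + float(q.sum())
        terms.append(1.0 - (2.0 * inter + smooth) / (denom + smooth))
    if not terms:
        return Tensor(np.float32(0.0))
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))


def _one_hot_channel(shape: tuple[int, ...], c: int) -> np.ndarray:
    sel = np.zeros((1, shape[1], 1, 1), dtype=np.float32)
    sel[0, c, 0, 0] = 1.0
    return sel


def generalized_dice_loss(class_probabilities, target, smooth: float = 1e-5) -> Tensor:
    """Generalized Dice: class terms weighted by inverse squared target volume."""
    p, labels, flags = _prep_seg(class_probabilities, target)
    num = Tensor(np.float32(0.0))
    den = Tensor(np.float32(0.0))
    any_class = False
    for c in _FG_CLASSES:
        if not flags.get(c, True):
            continue
        any_class = True
        q = (labels == c).astype(np.float32)
        vol = float(q.sum())
        wc = 1.0 / max(vol, 1.0) ** 2  # guards the empty-class division
        pc = ag.sum_(p * _one_hot_channel(p.shape, c), axis=1)
        num = num + wc * ag.sum_(pc * Tensor(q))
        den = den + wc * (ag.sum_(pc) + vol)
    if not any_class:
        return Tensor(np.float32(0.0))
    return 1.0 - (2.0 * num + smooth) / (den + smooth)


def cross_entropy_loss(class_probabilities, target, eps: float = 1e-7) -> Tensor:
    """Pixelwise cross-entropy on probabilities (ablation variant)."""
    p, labels, _ = _prep_seg(class_probabilities, target)
    onehot = np.stack([(labels == c) for c in range(p.shape[1])], axis=1).astype(np.float32)
    return -ag.mean(ag.sum_(Tensor(onehot) * ag.log(ag.clip(p, eps, 1.0)), axis=1))


def signed_distance_map(region: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance of a boolean region: negative inside, positive
    outside, magnitude = distance to the nearest pixel of the other side."""
    region = np.asarray(region, dtype=bool)
    if not region.any() or region.all():
        return np.zeros(region.shape, dtype=np.float32)
    outside = ndimage.distance_transform_edt(~region)
    inside = ndimage.distance_transform_edt(region)
    return (outside - inside).astype(np.float32)


def boundary_loss(class_probabilities, target) -> Tensor:
    """Mean over pixels of predicted probability x signed distance to the target
    region, averaged over annotated foreground classes.  Negative values reward
    probability mass placed inside the region; empty target classes are skipped."""
    p, labels, flags = _prep_seg(class_probabilities, target)
    terms = []
    for c in _FG_CLASSES:
        if not flags.get(c, True):
            continue
        region = labels == c
        if not region.any():
            continue
        sdm = np.stack([signed_distance_map(region[i]) for i in range(labels.shape[0])])
        pc = ag.sum_(p * _one_hot_channel(p.shape, c), axis=1)
        terms.append(ag.mean(pc * Tensor(sdm)))
    if not terms:
        return Tensor(np.float32(0.0))
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))


def _prep_coords(predicted, target, annotated_mask, num_landmarks=4):
    pred = Tensor.as_tensor(predicted)
    if pred.ndim == 1:
        pred = pred.reshape((1, -1))
    tgt = np.asarray(target, dtype=np.float32).reshape(pred.shape[0], -1)
    ann = np.asarray(annotated_mask, dtype=bool).reshape(pred.shape[0], -1)
    if ann.shape[1] != num_landmarks:
        raise ValueError(f"annotated mask must have {num_landmarks} entries per frame")
    if tgt.shape[1] != 2 * num_landmarks or pred.shape[1] != 2 * num_landmarks:
        raise ValueError("coordinates must have 2 entries per landmark")
    coord_mask = np.repeat(ann, 2, axis=1).astype(np.float32)
    return pred, tgt, coord_mask


def wing_loss(predicted_coords, target_coords, annotated_mask,
              config: LossConfig = LossConfig()) -> Tensor:
    """Wing loss on normalized coordinates, masked to annotated landmarks.

    The absolute error is scaled by ``config.wing_scale`` (default 100, i.e.
    percent of image size) before the piecewise curve: logarithmic within
    ``omega`` of zero, linear beyond, continuous at the joint.
    Returns 0 when no landmark is annotated.
    """
    pred, tgt, mask = _prep_coords(predicted_coords, target_coords, annotated_mask)
    n_active = float(mask.sum())
    if n_active == 0:
        return ag.sum_(pred * Tensor(np.zeros_like(mask)))  # zero, zero-gradient
    omega, eps = config.wing_omega, config.wing_epsilon
    big_c = omega - omega * np.log(1.0 + omega / eps)
    x = ag.abs_(pred - Tensor(tgt)) * config.wing_scale
    small = x.data < omega
    per_coord = ag.where_const(small,
                               omega * ag.log(1.0 + x * (1.0 / eps)),
                               x - float(big_c))
    return ag.sum_(per_coord * Tensor(mask)) * (1.0 / n_active)


def mse_coordinate_loss(predicted_coords, target_coords, annotated_mask) -> Tensor:
    """Masked mean squared error on normalized coordinates (ablation variant)."""
    pred, tgt, mask = _prep_coords(predicted_coords, target_coords, annotated_mask)
    n_active = float(mask.sum())
    if n_active == 0:
        return ag.sum_(pred * Tensor(np.zeros_like(mask)))
    return ag.sum_(((pred - Tensor(tgt)) ** 2) * Tensor(mask)) * (1.0 / n_active)


def focal_loss(presence_logits, presence_targets,
               config: LossConfig = LossConfig()) -> Tensor:
    """Alpha-balanced focal binary cross-entropy on the presence logits.

    With gamma=0 and alpha=0.5 this reduces to 0.5 x standard BCE.  Targets
    are the per-structure annotated/visible indicators.
    """
    logits = Tensor.as_tensor(presence_logits)
    t = np.asarray(presence_targets, dtype=np.float32).reshape(logits.shape)
    p = ag.sigmoid(logits)
    pt = ag.where_const(t > 0.5, p, 1.0 - p)
    alpha_t = np.where(t > 0.5, config.focal_alpha, 1.0 - config.focal_alpha).astype(np.float32)
    modulator = (1.0 - pt) ** config.focal_gamma if config.focal_gamma else 1.0
    per = -(Tensor(alpha_t) * modulator * ag.log(ag.clip(pt, 1e-12, 1.0)))
    return ag.mean(per)


def combined_loss(seg_probabilities, target_mask, predicted_coords, target_coords,
                  annotated_mask, presence_logits=None,
                  weights: LossWeights = LossWeights(),
                  config: LossConfig = LossConfig()) -> LossBreakdown:
    """Weighted four-term objective; the breakdown's graph tensor is backpropable."""
    if config.seg_variant is SegVariant.DICE:
        seg_term = dice_loss(seg_probabilities, target_mask, smooth=config.dice_smooth)
    elif config.seg_variant is SegVariant.GENERALIZED_DICE:
        seg_term = generalized_dice_loss(seg_probabilities, target_mask,
                                         smooth=config.dice_smooth)
    else:
        seg_term = cross_entropy_loss(seg_probabilities, target_mask)

    if config.boundary_variant is BoundaryVariant.SIGNED_DISTANCE:
        bdl_term = boundary_loss(seg_probabilities, target_mask)
    else:
        bdl_term = Tensor(np.float32(0.0))

    if config.coord_variant is CoordVariant.WING:
        coord_term = wing_loss(predicted_coords, target_coords, annotated_mask, config)
    else:
        coord_term = mse_coordinate_loss(predicted_coords, target_coords, annotated_mask)

    if presence_logits is not None:
        ann = np.asarray(annotated_mask, dtype=np.float32)
        focal_term = focal_loss(presence_logits, ann, config)
    else:
        focal_term = Tensor(np.float32(0.0))

    total = (weights.w1 * seg_term + weights.w2 * bdl_term
             + weights.w3 * coord_term + weights.w4 * focal_term)
    # the reported total is the exact float64 weighted sum of the components;
    # the float32 graph tensor drives backpropagation
    return LossBreakdown(
        dice=float(seg_term), bdl=float(bdl_term), wing=float(coord_term),
        focal=float(focal_term),
        total=(weights.w1 * float(seg_term) + weights.w2 * float(bdl_term)
               + weights.w3 * float(coord_term) + weights.w4 * float(focal_term)),
        graph=total,
    )
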