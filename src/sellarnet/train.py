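"""Two-phase training, evaluation, cross-validation and prediction.

Training follows a two-phase schedule on one SGD run (momentum 0.9, learning
rate decaying linearly from 0.01 to 0.0001 over the full run): during phase 1
the landmark head is frozen and only the segmentation terms (w1*Dice +
w2*BDL) are optimized; phase 2 unfreezes the head and switches to the full
four-term objective.  Frames are drawn by the reciprocal-count sampler and
augmented on the fly; every random draw (weight init, sampling, augmentation)
descends from the config seed, so the loss trajectory is reproducible on a
given machine.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image, ImageDraw

from . import losses as L
from . import metrics as M
from .data import (
    LANDMARK_STRUCTURES,
    REGION_CLASSES,
    AnnotatedFrame,
    DatasetManifest,
    FoldSplit,
    load_frame,
    split_by_patient,
)
from .network import (
    ModelOutput,
    MultiTaskHRNet,
    NetworkConfig,
    build_model,
    load_checkpoint,
    save_checkpoint,
    set_landmark_head_frozen,
)
from .nn import SGD, Tensor, no_grad
from .nn import autograd as ag
from .pipeline import AugmentConfig, augment_frame, compute_sampler, draw_epoch

__all__ = [
    "TrainConfig",
    "ExperimentResult",
    "EngineExportUnavailableError",
    "lr_at_epoch",
    "train",
    "evaluate",
    "cross_validate",
    "predict",
    "desk_scale_experiment",
    "export_engine",
]

_IMG_MEAN, _IMG_STD = 0.5, 0.25


@dataclass
class TrainConfig:
    epochs_total: int = 500
    epochs_phase1: int = 300
    lr_initial: float = 0.01
    lr_min: float = 0.0001
    momentum: float = 0.9
    weight_decay: float = 0.0
    batch_size: int = 8
    seed: int = 0
    weights: L.LossWeights = field(default_factory=L.LossWeights)
    loss: L.LossConfig = field(default_factory=L.LossConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self) -> None:
        if not 0 <= self.epochs_phase1 <= self.epochs_total:
            raise ValueError("need 0 <= epochs_phase1 <= epochs_total")
        if self.lr_min > self.lr_initial:
            raise ValueError("lr_min must not exceed lr_initial")

    # -- YAML round-trip -------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["network"] = self.network.to_dict()
        d["loss"] = {k: (v.value if hasattr(v, "value") else v)
                     for k, v in dataclasses.asdict(self.loss).items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        d["weights"] = L.LossWeights(**d.get("weights", {}))
        loss_d = dict(d.get("loss", {}))
        for key, enum_cls in (("seg_variant", L.SegVariant),
                              ("boundary_variant", L.BoundaryVariant),
                              ("coord_variant", L.CoordVariant)):
            if key in loss_d:
                loss_d[key] = enum_cls(loss_d[key])
        d["loss"] = L.LossConfig(**loss_d)
        d["augment"] = AugmentConfig(**d.get("augment", {}))
        d["network"] = NetworkConfig.from_dict(d["network"]) if "network" in d else NetworkConfig()
        return cls(**d)

    def save_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load_yaml(cls, path: str | Path) -> "TrainConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def tiny(cls, **overrides) -> "TrainConfig":
        """Desk-scale preset: tiny network on 96x96 frames, 20+20 epochs."""
        defaults = dict(epochs_total=40, epochs_phase1=20,
                        network=NetworkConfig.tiny())
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class ExperimentResult:
    fold_reports: list[M.MetricReport]
    aggregate: M.FoldAggregate
    config: TrainConfig
    loss_logs: list[pd.DataFrame]


class EngineExportUnavailableError(RuntimeError):
    """Raised when no GPU inference-engine runtime is installed."""


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Linear decay: lr_initial at epoch 0 down to lr_min at the final epoch."""
    if not 0 <= epoch < config.epochs_total:
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs_total})")
    if config.epochs_total == 1:
        return config.lr_initial
    frac = epoch / (config.epochs_total - 1)
    return max(config.lr_min,
               config.lr_initial + (config.lr_min - config.lr_initial) * frac)


# -- batching ------------------------------------------------------------------

def _frame_tensors(frames: list[AnnotatedFrame], size: tuple[int, int]):
    """Stack frames into network inputs and per-frame targets."""
    w, h = size
    images = np.stack([f.image for f in frames]).astype(np.float32) / 255.0
    images = (images - _IMG_MEAN) / _IMG_STD
    images = images.transpose(0, 3, 1, 2)
    labels = np.stack([f.mask.labels for f in frames])
    coords, ann = [], []
    for f in frames:
        xy, a = f.landmark_array()
        coords.append((xy / np.array([w, h], dtype=float)).reshape(-1))
        ann.append(a)
    flags = {c: all(f.mask.class_annotated.get(c, True) for f in frames)
             for c in REGION_CLASSES}
    return (images, labels, np.asarray(coords, dtype=np.float32),
            np.asarray(ann, dtype=bool), flags)


class _BatchTarget:
    """Duck-typed SegmentationMask for a whole batch (losses read .labels/.class_annotated)."""

    def __init__(self, labels: np.ndarray, class_annotated: dict[int, bool]):
        self.labels = labels
        self.class_annotated = class_annotated


def _step_loss(output: ModelOutput, labels, coords, ann, flags,
               config: TrainConfig, phase1: bool) -> L.LossBreakdown:
    probs = ag.softmax(output.seg_logits, axis=1)
    target = _BatchTarget(labels, flags)
    wts, lcfg = config.weights, config.loss
    if phase1:  # segmentation terms only; landmark terms excluded entirely
        dice = L.dice_loss(probs, target, smooth=lcfg.dice_smooth) \
            if lcfg.seg_variant is not L.SegVariant.CROSS_ENTROPY \
            else L.cross_entropy_loss(probs, target)
        if lcfg.seg_variant is L.SegVariant.GENERALIZED_DICE:
            dice = L.generalized_dice_loss(probs, target, smooth=lcfg.dice_smooth)
        bdl = (L.boundary_loss(probs, target)
               if lcfg.boundary_variant is L.BoundaryVariant.SIGNED_DISTANCE
               else Tensor(np.float32(0.0)))
        total = wts.w1 * dice + wts.w2 * bdl
        return L.LossBreakdown(dice=float(dice), bdl=float(bdl), wing=0.0,
                               focal=0.0, total=float(total), graph=total)
    return L.combined_loss(probs, target, output.landmark_coords, coords, ann,
                           presence_logits=output.presence_logits,
                           weights=wts, config=lcfg)


def _load_frames(manifest: DatasetManifest, frame_ids: list[str]) -> dict[str, AnnotatedFrame]:
    return {fid: load_frame(manifest, fid) for fid in frame_ids}


def train(config: TrainConfig, manifest: DatasetManifest, split: FoldSplit,
          fold: int, out_dir: str | Path) -> tuple[Path, pd.DataFrame]:
    """Train on every fold except `fold`; returns (checkpoint path, loss log).

    Writes checkpoints at the phase boundary and at the end, the config as
    YAML, and the per-epoch loss breakdown as CSV under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    train_ids = [fid for fid in manifest.frame_ids if split.fold_of(fid) != fold]
    if not train_ids:
        raise ValueError(f"no training frames outside fold {fold}")

    sub = DatasetManifest(
        records=manifest.records[manifest.records["frame_id"].isin(train_ids)].copy(),
        image_size=manifest.image_size, root=manifest.root)
    sampler = compute_sampler(sub)
    cache = _load_frames(manifest, train_ids)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, fold]))
    model = build_model(config.network, seed=config.seed)
    opt = SGD(model.parameters(), lr=config.lr_initial, momentum=config.momentum,
              weight_decay=config.weight_decay)
    set_landmark_head_frozen(model, True)

    log_rows = []
    size = config.network.input_size
    for epoch in range(config.epochs_total):
        phase1 = epoch < config.epochs_phase1
        if epoch == config.epochs_phase1:
            set_landmark_head_frozen(model, False)
            save_checkpoint(model, out_dir / "ckpt_phase1.npz")
        opt.lr = lr_at_epoch(config, epoch)
        ids = draw_epoch(sampler, rng)
        epoch_terms = []
        for start in range(0, len(ids), config.batch_size):
            batch = [augment_frame(cache[i], config.augment, rng)
                     for i in ids[start:start + config.batch_size]]
            images, labels, coords, ann, flags = _frame_tensors(batch, size)
            out = model(images)
            breakdown = _step_loss(out, labels, coords, ann, flags, config, phase1)
            if not np.isfinite(breakdown.total):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {breakdown}")
            opt.zero_grad()
            breakdown.graph.backward()
            opt.step()
            epoch_terms.append((breakdown.dice, breakdown.bdl, breakdown.wing,
                                breakdown.focal, breakdown.total))
        m = np.mean(epoch_terms, axis=0)
        log_rows.append({"epoch": epoch, "phase": 1 if phase1 else 2,
                         "lr": opt.lr, "dice": m[0], "bdl": m[1], "wing": m[2],
                         "focal": m[3], "total": m[4]})
    if config.epochs_phase1 == config.epochs_total:
        set_landmark_head_frozen(model, False)

    ckpt = out_dir / "ckpt_final.npz"
    save_checkpoint(model, ckpt)
    config.save_yaml(out_dir / "train_config.yaml")
    log = pd.DataFrame(log_rows)
    log.to_csv(out_dir / "loss_log.csv", index=False)
    return ckpt, log


# -- evaluation ----------------------------------------------------------------

def _predict_frame(model: MultiTaskHRNet, frame: AnnotatedFrame):
    w, h = model.config.input_size
    if frame.size != (w, h):
        raise ValueError(
            f"frame size {frame.size} != model input {model.config.input_size}")
    images, *_ = _frame_tensors([frame], (w, h))
    model.eval()
    with no_grad():
        out = model(images)
    seg = np.argmax(out.seg_logits.numpy()[0], axis=0)
    coords = out.landmark_coords.numpy()[0].reshape(-1, 2) * np.array([w, h])
    presence = (1.0 / (1.0 + np.exp(-out.presence_logits.numpy()[0]))
                if out.presence_logits is not None else None)
    return seg, coords, presence


def evaluate(model_or_ckpt, manifest: DatasetManifest,
             frame_ids: list[str] | None = None,
             metric_config: M.MetricConfig | None = None) -> M.MetricReport:
    """Run the model over frames and score against the visible annotations.

    Segmentation IoU/precision aggregate pixel counts across frames (per
    class, skipping frames where the class is unannotated); landmark metrics
    use only annotated instances.
    """
    model = (load_checkpoint(model_or_ckpt)
             if isinstance(model_or_ckpt, (str, Path)) else model_or_ckpt)
    frame_ids = frame_ids if frame_ids is not None else manifest.frame_ids
    mc = metric_config or M.MetricConfig(image_size=manifest.image_size)

    inter = {c: 0 for c in REGION_CLASSES}
    union = {c: 0 for c in REGION_CLASSES}
    tp = {c: 0 for c in REGION_CLASSES}
    pp = {c: 0 for c in REGION_CLASSES}
    preds, gts, anns = [], [], []
    for fid in frame_ids:
        frame = load_frame(manifest, fid)
        seg, coords, _ = _predict_frame(model, frame)
        for c in REGION_CLASSES:
            if not frame.mask.class_annotated.get(c, True):
                continue
            p = seg == c
            g = frame.mask.labels == c
            inter[c] += int(np.logical_and(p, g).sum())
            union[c] += int(np.logical_or(p, g).sum())
            tp[c] += int(np.logical_and(p, g).sum())
            pp[c] += int(p.sum())
        xy, a = frame.landmark_array()
        preds.append(coords)
        gts.append(xy)
        anns.append(a)

    names = [s.value for s in LANDMARK_STRUCTURES]
    pck, mpck_val = M.mpck(np.stack(preds), np.stack(gts), np.stack(anns),
                           config=mc, structure_names=names)
    _, mdist = M.mdistance(np.stack(preds), np.stack(gts), np.stack(anns),
                           structure_names=names)
    iou_pc = {name: (100.0 * inter[c] / union[c] if union[c] else float("nan"))
              for c, name in REGION_CLASSES.items()}
    prec_pc = {name: (100.0 * tp[c] / pp[c] if pp[c] else float("nan"))
               for c, name in REGION_CLASSES.items()}
    return M.MetricReport(iou_percent=iou_pc, precision_percent=prec_pc,
                          pck_percent=pck, mpck_percent=mpck_val,
                          mdistance_pixels=mdist, n_frames=len(frame_ids))


def cross_validate(config: TrainConfig, manifest: DatasetManifest, k: int,
                   out_dir: str | Path) -> ExperimentResult:
    """k-fold cross-validation by patient; aggregates fold reports as mean±std."""
    if k < 2:
        raise ValueError("cross-validation needs k >= 2")
    out_dir = Path(out_dir)
    split = split_by_patient(manifest, k, seed=config.seed)
    reports, logs = [], []
    for fold in range(k):
        ckpt, log = train(config, manifest, split, fold, out_dir / f"fold{fold}")
        report = evaluate(ckpt, manifest, frame_ids=split.frames_in_fold(fold))
        reports.append(report)
        logs.append(log)
    agg = M.aggregate_folds(reports)
    (out_dir / "crossval_report.txt").write_text(M.format_report_table(agg))
    return ExperimentResult(fold_reports=reports, aggregate=agg,
                            config=config, loss_logs=logs)


# -- prediction and export -----------------------------------------------------

def predict(checkpoint, image_path: str | Path, out_dir: str | Path) -> dict:
    """Predict one image: writes mask PNG, landmark JSON and an overlay PNG."""
    model = (checkpoint if isinstance(checkpoint, MultiTaskHRNet)
             else load_checkpoint(checkpoint))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    image_path = Path(image_path)
    if not image_path.exists():
        raise FileNotFoundError(image_path)
    orig = Image.open(image_path).convert("RGB")
    ow, oh = orig.size
    w, h = model.config.input_size
    resized = orig.resize((w, h), Image.BILINEAR) if (ow, oh) != (w, h) else orig

    arr = np.asarray(resized).astype(np.float32) / 255.0
    arr = ((arr - _IMG_MEAN) / _IMG_STD).transpose(2, 0, 1)[None]
    model.eval()
    with no_grad():
        out = model(arr)
    seg = np.argmax(out.seg_logits.numpy()[0], axis=0).astype(np.uint8)
    if (ow, oh) != (w, h):
        seg = np.asarray(Image.fromarray(seg).resize((ow, oh), Image.NEAREST))
    coords = out.landmark_coords.numpy()[0].reshape(-1, 2) * np.array([ow, oh])
    coords = np.clip(coords, 0, np.array([ow - 1, oh - 1]))

    stem = image_path.stem
    Image.fromarray(seg).save(out_dir / f"{stem}_mask.png")
    payload = {"image": image_path.name, "landmarks": [
        {"structure": s.value, "x": float(x), "y": float(y)}
        for s, (x, y) in zip(LANDMARK_STRUCTURES, coords)
    ]}
    (out_dir / f"{stem}_landmarks.json").write_text(json.dumps(payload, indent=2))

    overlay = orig.copy()
    draw = ImageDraw.Draw(overlay)
    palette = {1: (60, 120, 255), 2: (255, 220, 60)}
    for c, colour in palette.items():
        ys, xs = np.nonzero(seg == c)
        if len(xs):  # sparse contour-ish dots keep the overlay cheap
            for x, y in zip(xs[:: max(1, len(xs) // 4000)], ys[:: max(1, len(ys) // 4000)]):
                overlay.putpixel((int(x), int(y)), colour)
    r = max(2, min(ow, oh) // 80)
    for entry in payload["landmarks"]:
        x, y = entry["x"], entry["y"]
        draw.ellipse([x - r, y - r, x + r, y + r], outline=(255, 0, 0), width=2)
    overlay.save(out_dir / f"{stem}_overlay.png")
    return payload


def desk_scale_experiment(seed: int, work_dir: str | Path,
                          epochs_total: int = 40, epochs_phase1: int = 20) -> dict:
    """Train the tiny model on the easy synthetic preset and score it.

    The standing desk-scale benchmark: 250 easy-preset frames at 96x96 from
    10 synthetic patients, split by patient into 200 training and 50
    validation frames, two-phase schedule (segmentation-only, then joint).
    Returns validation metrics for the trained model and the untrained
    initialization for comparison.
    """
    from .synth import difficulty_presets, generate_dataset

    work_dir = Path(work_dir)
    spec = difficulty_presets(image_size=(96, 96), seed=seed)["easy"]
    manifest, _ = generate_dataset(spec, work_dir / "data")
    split = split_by_patient(manifest, 5, seed=seed)
    val_ids = split.frames_in_fold(0)

    config = TrainConfig.tiny(seed=seed, epochs_total=epochs_total,
                              epochs_phase1=epochs_phase1)
    untrained = build_model(config.network, seed=config.seed)
    before = evaluate(untrained, manifest, frame_ids=val_ids)
    ckpt, log = train(config, manifest, split, 0, work_dir / "run")
    after = evaluate(ckpt, manifest, frame_ids=val_ids)
    return {
        "n_train": len(manifest) - len(val_ids),
        "n_val": len(val_ids),
        "untrained": before,
        "trained": after,
        "loss_log": log,
        "checkpoint": ckpt,
    }


def export_engine(checkpoint, precision: str = "fp16"):
    """Export a checkpoint to a GPU-accelerated inference engine.

    Engine conversion needs an NVIDIA GPU runtime (TensorRT); none is
    available in a CPU-only installation, so this raises a capability error
    rather than silently returning an unusable artifact.
    """
    if precision not in ("fp32", "fp16"):
        raise ValueError(f"unsupported precision {precision!r}; use 'fp32' or 'fp16'")
    raise EngineExportUnavailableError(
        "accelerated-engine export requires an NVIDIA TensorRT runtime, which "
        "is not installed. Install TensorRT + a GPU build of the conversion "
        "toolchain and re-run; native inference remains available via "
        "evaluate()/predict()."
    )
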