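"""Synthetic sellar-phase scene generator with full ground truth.

Real sellar-phase endoscopy data is private and expensive to annotate, so
this module generates structurally analogous scenes for development and
testing: a dark frame with a bright circular endoscopic field of view, a
large central elliptical region (the sella analog), an elongated inferior
region (the clival-recess analog) and four subtle point protuberances laid
out like the paired carotid and optic landmarks — carotids lateral to the
sella near mid-height, optic protuberances superior-lateral.  Patients get
persistent appearance/geometry styles (base tissue colour, region shape and
position biases) so folds exhibit inter-patient variability, and per-frame
jitter and noise provide intra-patient variation.

The generator's contract is statistical structure, not photorealism: two
large regions, four small landmarks, partial annotation (per-structure
dropout of the *visible* labels while the truth is always stored), and
patient grouping.  Everything is deterministic given the spec seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .data import (
    LANDMARK_STRUCTURES,
    REGION_CLASSES,
    AnnotatedFrame,
    DatasetManifest,
    LandmarkAnnotation,
    SegmentationMask,
    write_manifest,
)

__all__ = ["SceneSpec", "PatientStyle", "generate_dataset", "render_scene",
           "difficulty_presets", "frame_counts"]


@dataclass(frozen=True)
class SceneSpec:
    image_size: tuple[int, int] = (1280, 720)  # (width, height)
    fov_radius_frac: float = 0.48              # of min(width, height)

    # sella analog: large central ellipse (semi-axes as fractions of min dim;
    # defaults give a diameter around a third of the image height)
    sella_axes_frac: tuple[float, float] = (0.17, 0.13)
    sella_center_frac: tuple[float, float] = (0.0, -0.02)
    patient_center_std_frac: float = 0.03      # patient-level position bias
    patient_axes_std_frac: float = 0.015       # patient-level shape bias
    sella_angle_std_deg: float = 8.0

    # clival-recess analog: elongated region inferior to the sella
    clival_offset_frac: tuple[float, float] = (0.0, 0.24)
    clival_axes_frac: tuple[float, float] = (0.13, 0.065)

    # landmark layout, as multiples of the sella semi-axes from its centre:
    # carotids lateral at mid-height, optic protuberances superior-lateral
    carotid_offset: tuple[float, float] = (1.45, 0.10)
    optic_offset: tuple[float, float] = (1.25, -1.15)
    landmark_jitter_std_px: float = 6.0        # per-frame positional jitter

    # appearance
    noise_amplitude: float = 6.0               # additive Gaussian, 8-bit units
    vignette_strength: float = 0.5
    specular_count: int = 3

    # annotation visibility (truth is always stored)
    landmark_dropout: float = 0.35
    region_dropout: float = 0.0

    n_patients: int = 64
    total_frames: int = 635
    frames_per_patient: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.landmark_dropout <= 1 and 0 <= self.region_dropout <= 1):
            raise ValueError("dropout probabilities must lie in [0, 1]")
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        # nominal layout must keep regions and landmarks inside the field of view
        a, b = self.sella_axes_frac
        reach = max(
            abs(self.sella_center_frac[0]) + self.carotid_offset[0] * a,
            abs(self.sella_center_frac[1]) + abs(self.optic_offset[1]) * b,
            abs(self.clival_offset_frac[1]) + self.clival_axes_frac[1],
        )
        if reach >= self.fov_radius_frac:
            raise ValueError("nominal layout extends outside the field of view")

    def counts(self) -> tuple[int, ...]:
        if self.frames_per_patient is not None:
            return tuple(self.frames_per_patient)
        return frame_counts(self.total_frames, self.n_patients)


def frame_counts(total: int, n_patients: int) -> tuple[int, ...]:
    """Distribute `total` frames over patients as evenly as possible."""
    base, extra = divmod(total, n_patients)
    return tuple(base + (1 if i < extra else 0) for i in range(n_patients))


@dataclass(frozen=True)
class PatientStyle:
    """Persistent per-patient appearance and geometry biases."""

    base_rgb: tuple[float, float, float]
    center_offset_px: tuple[float, float]   # sella-centre bias from nominal
    axes_px: tuple[float, float]            # sella semi-axes
    angle_deg: float
    clival_axes_px: tuple[float, float]
    lateral_scale: float                    # stretches the landmark layout

    def mirrored(self) -> "PatientStyle":
        return dataclasses.replace(
            self,
            center_offset_px=(-self.center_offset_px[0], self.center_offset_px[1]),
            angle_deg=-self.angle_deg,
        )


def _patient_style(spec: SceneSpec, rng: np.random.Generator) -> PatientStyle:
    m = min(spec.image_size)
    base = np.clip(np.array([180, 90, 80]) + rng.normal(0, 18, 3), 60, 230)
    return PatientStyle(
        base_rgb=tuple(float(v) for v in base),
        center_offset_px=tuple(rng.normal(0, spec.patient_center_std_frac * m, 2)),
        axes_px=(
            max(3.0, (spec.sella_axes_frac[0] + rng.normal(0, spec.patient_axes_std_frac)) * m),
            max(3.0, (spec.sella_axes_frac[1] + rng.normal(0, spec.patient_axes_std_frac)) * m),
        ),
        angle_deg=float(rng.normal(0, spec.sella_angle_std_deg)),
        clival_axes_px=(
            max(2.0, (spec.clival_axes_frac[0] + rng.normal(0, spec.patient_axes_std_frac)) * m),
            max(2.0, (spec.clival_axes_frac[1] + rng.normal(0, spec.patient_axes_std_frac / 2)) * m),
        ),
        lateral_scale=float(np.clip(rng.normal(1.0, 0.05), 0.85, 1.15)),
    )


def _ellipse_mask(xx, yy, cx, cy, a, b, angle_deg):
    th = np.deg2rad(angle_deg)
    dx, dy = xx - cx, yy - cy
    u = dx * np.cos(th) + dy * np.sin(th)
    v = -dx * np.sin(th) + dy * np.cos(th)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _landmark_truth(spec: SceneSpec, style: PatientStyle,
                    center: tuple[float, float]) -> np.ndarray:
    """Nominal (jitter-free) landmark xy positions, order = LANDMARK_STRUCTURES."""
    a, b = style.axes_px
    cx, cy = center
    ls = style.lateral_scale
    ca, cb = spec.carotid_offset
    oa, ob = spec.optic_offset
    return np.array([
        [cx - ls * ca * a, cy + cb * b],   # left carotid
        [cx + ls * ca * a, cy + cb * b],   # right carotid
        [cx - ls * oa * a, cy + ob * b],   # left optic protuberance
        [cx + ls * oa * a, cy + ob * b],   # right optic protuberance
    ])


def render_scene(spec: SceneSpec, style: PatientStyle,
                 frame_rng: np.random.Generator,
                 frame_id: str = "frame", patient_id: str = "patient") -> AnnotatedFrame:
    """Render one frame with exact mask/landmark ground truth."""
    w, h = spec.image_size
    m = min(w, h)
    fov_r = spec.fov_radius_frac * m
    icx, icy = (w - 1) / 2.0, (h - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    r = np.hypot(xx - icx, yy - icy)
    fov = r <= fov_r

    cx = icx + spec.sella_center_frac[0] * m + style.center_offset_px[0]
    cy = icy + spec.sella_center_frac[1] * m + style.center_offset_px[1]
    sella = _ellipse_mask(xx, yy, cx, cy, *style.axes_px, style.angle_deg)
    ccx = cx + spec.clival_offset_frac[0] * m
    ccy = cy + spec.clival_offset_frac[1] * m
    clival = _ellipse_mask(xx, yy, ccx, ccy, *style.clival_axes_px, 0.0)

    labels = np.zeros((h, w), dtype=np.int64)
    labels[sella & fov] = 1
    labels[clival & fov & (labels == 0)] = 2

    lm_xy = _landmark_truth(spec, style, (cx, cy))
    if spec.landmark_jitter_std_px > 0:
        lm_xy = lm_xy + frame_rng.normal(0, spec.landmark_jitter_std_px, lm_xy.shape)
    # keep landmarks inside the field of view (and hence the frame)
    dv = lm_xy - np.array([icx, icy])
    rad = np.linalg.norm(dv, axis=1)
    over = rad > 0.95 * fov_r
    lm_xy[over] = np.array([icx, icy]) + dv[over] * (0.95 * fov_r / rad[over])[:, None]

    # -- shading ---------------------------------------------------------------
    img = np.zeros((h, w, 3), dtype=np.float64)
    vignette = 1.0 - spec.vignette_strength * np.clip(r / fov_r, 0, 1) ** 2
    for c, base in enumerate(style.base_rgb):
        img[..., c] = base * vignette
    depth = np.clip(1.0 - ((xx - cx) ** 2 / style.axes_px[0] ** 2
                           + (yy - cy) ** 2 / style.axes_px[1] ** 2), 0, 1)
    img[sella] *= (1.0 - 0.45 * depth[sella])[:, None]      # recessed, darker
    img[sella, 0] *= 1.15                                   # reddish sella floor
    img[clival & ~sella] *= 0.7

    sigma = 0.025 * m
    for (lx, ly) in lm_xy:
        bump = 45.0 * np.exp(-((xx - lx) ** 2 + (yy - ly) ** 2) / (2 * sigma ** 2))
        img += bump[..., None]
    for _ in range(spec.specular_count):
        ang = frame_rng.uniform(0, 2 * np.pi)
        rr = frame_rng.uniform(0, 0.8) * fov_r
        sx, sy = icx + rr * np.cos(ang), icy + rr * np.sin(ang)
        ssig = frame_rng.uniform(0.005, 0.015) * m
        img += (80.0 * np.exp(-((xx - sx) ** 2 + (yy - sy) ** 2) / (2 * ssig ** 2)))[..., None]
    if spec.noise_amplitude > 0:
        img += frame_rng.normal(0, spec.noise_amplitude, img.shape)
    img[~fov] = 4.0  # near-black surround outside the endoscope optics
    image = np.clip(img, 0, 255).round().astype(np.uint8)

    landmarks = tuple(
        LandmarkAnnotation(s, float(x), float(y), True)
        for s, (x, y) in zip(LANDMARK_STRUCTURES, lm_xy)
    )
    return AnnotatedFrame(frame_id=frame_id, patient_id=patient_id, image=image,
                          mask=SegmentationMask(labels), landmarks=landmarks)


def generate_dataset(spec: SceneSpec, out_dir: str | Path,
                     materialize: bool = True) -> tuple[DatasetManifest, pd.DataFrame]:
    """Generate the dataset; returns (manifest, truth table).

    The manifest's landmark columns reflect *visible* annotations after
    dropout; the truth table always carries every coordinate.  With
    ``materialize=False`` only the tables are produced (fast, for statistics);
    otherwise PNG images/masks, ``manifest.csv`` and ``truth.csv`` are written
    under ``out_dir``.
    """
    out_dir = Path(out_dir)
    if materialize:
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    root_ss = np.random.SeedSequence(spec.seed)
    patient_seeds = root_ss.spawn(spec.n_patients)
    rows, truth_rows = [], []
    for p_idx, (count, pseed) in enumerate(zip(spec.counts(), patient_seeds)):
        style_rng = np.random.default_rng(pseed)
        style = _patient_style(spec, style_rng)
        frame_seeds = pseed.spawn(count)
        for f_idx, fseed in enumerate(frame_seeds):
            frame_rng = np.random.default_rng(fseed)
            pid = f"patient_{p_idx:03d}"
            fid = f"{pid}_frame_{f_idx:03d}"
            frame = render_scene(spec, style, frame_rng, frame_id=fid, patient_id=pid)
            img_path = f"images/{fid}.png"
            mask_path = f"masks/{fid}.png"
            if materialize:
                Image.fromarray(frame.image).save(out_dir / img_path)
                Image.fromarray(frame.mask.labels.astype(np.uint8)).save(out_dir / mask_path)

            row = {"frame_id": fid, "patient_id": pid,
                   "image_path": img_path, "mask_path": mask_path}
            truth = {"frame_id": fid}
            for name in REGION_CLASSES.values():
                row[f"{name}_annotated"] = bool(frame_rng.random() >= spec.region_dropout)
            for lm in frame.landmarks:
                visible = frame_rng.random() >= spec.landmark_dropout
                key = lm.structure_id.value
                row[f"{key}_x"] = round(lm.x, 2) if visible else np.nan
                row[f"{key}_y"] = round(lm.y, 2) if visible else np.nan
                row[f"{key}_annotated"] = visible
                truth[f"{key}_x"] = round(lm.x, 2)
                truth[f"{key}_y"] = round(lm.y, 2)
            rows.append(row)
            truth_rows.append(truth)

    manifest = DatasetManifest(records=pd.DataFrame(rows), image_size=spec.image_size,
                               root=out_dir)
    truth = pd.DataFrame(truth_rows)
    if materialize:
        write_manifest(manifest, out_dir / "manifest.csv")
        truth.to_csv(out_dir / "truth.csv", index=False)
    return manifest, truth


def difficulty_presets(image_size: tuple[int, int] = (96, 96),
                       seed: int = 0) -> dict[str, SceneSpec]:
    """Easy / medium / hard specs with increasing jitter, noise and dropout.

    The easy preset is clean enough that a constant-template predictor solves
    the landmarks; hard matches the real dataset's visibility (at most 65% of
    frames annotated per landmark, i.e. dropout 0.35).
    """
    m = min(image_size)
    common = dict(image_size=image_size, n_patients=10, total_frames=250, seed=seed)
    return {
        "easy": SceneSpec(landmark_jitter_std_px=0.015 * m, noise_amplitude=3.0,
                          landmark_dropout=0.0, patient_center_std_frac=0.02,
                          specular_count=1, **common),
        "medium": SceneSpec(landmark_jitter_std_px=0.04 * m, noise_amplitude=6.0,
                            landmark_dropout=0.15, **common),
        "hard": SceneSpec(landmark_jitter_std_px=0.065 * m, noise_amplitude=10.0,
                          landmark_dropout=0.35, patient_center_std_frac=0.04,
                          specular_count=5, **common),
    }
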