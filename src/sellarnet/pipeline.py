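"""Training-data pipeline: reciprocal-count weighted sampling and augmentation.

The sampler counters annotation imbalance: frames whose annotated-structure
count is rare get proportionally higher sampling probability (weight =
1 / number of frames sharing the same count), so frames carrying many
annotated structures — which are scarce — are seen more often.

Augmentation applies, with probability 0.5 per draw, one random affine
(shift up to 10%, zoom up to 30%, rotation up to 30 degrees about the image
centre) consistently to image, mask (nearest-neighbour) and landmark
coordinates, followed by photometric jitter (brightness/contrast/saturation
up to 30%, hue up to 10%) on the image only.  Vacated border regions are
filled black, matching the endoscope's circular black surround.  Landmarks
mapped outside the frame are flagged unannotated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor
from skimage.transform import AffineTransform, warp

from .data import AnnotatedFrame, DatasetManifest, LandmarkAnnotation, SegmentationMask

__all__ = [
    "SamplerSpec",
    "AugmentConfig",
    "compute_sampler",
    "draw_epoch",
    "augment_frame",
    "build_affine",
]


@dataclass
class SamplerSpec:
    frame_ids: list[str]
    probabilities: np.ndarray
    with_replacement: bool = True

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if np.any(self.probabilities < 0) or not np.isclose(self.probabilities.sum(), 1.0):
            raise ValueError("probabilities must be non-negative and sum to 1")


@dataclass(frozen=True)
class AugmentConfig:
    max_shift_frac: float = 0.10
    max_zoom_frac: float = 0.30
    max_rotation_deg: float = 30.0
    max_brightness_frac: float = 0.30
    max_contrast_frac: float = 0.30
    max_saturation_frac: float = 0.30
    max_hue_frac: float = 0.10
    augment_probability: float = 0.5

    def __post_init__(self) -> None:
        fracs = (self.max_shift_frac, self.max_zoom_frac, self.max_brightness_frac,
                 self.max_contrast_frac, self.max_saturation_frac, self.max_hue_frac,
                 self.augment_probability)
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if not 0 <= self.max_rotation_deg <= 180:
            raise ValueError("rotation bound must lie in [0, 180] degrees")


def compute_sampler(manifest: DatasetManifest, count_regions: bool = True) -> SamplerSpec:
    """Reciprocal-count sampling probabilities.

    For frame i with n_i annotated structures (over all 6 structures by
    default, or the 4 landmarks only with ``count_regions=False``), the
    unnormalized weight is 1 / #{frames j : n_j = n_i}.
    """
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    flags = manifest.annotation_flags()
    if not count_regions:
        flags = flags.iloc[:, 2:]
    counts = flags.sum(axis=1).to_numpy()
    _, inverse, group_sizes = np.unique(counts, return_inverse=True, return_counts=True)
    weights = 1.0 / group_sizes[inverse]
    return SamplerSpec(frame_ids=list(flags.index), probabilities=weights / weights.sum())


def draw_epoch(spec: SamplerSpec, rng: np.random.Generator, n: int | None = None) -> list[str]:
    """Sample one epoch of frame ids (default epoch length = dataset size)."""
    n = len(spec.frame_ids) if n is None else n
    idx = rng.choice(len(spec.frame_ids), size=n, replace=spec.with_replacement,
                     p=spec.probabilities)
    return [spec.frame_ids[i] for i in idx]


def build_affine(width: int, height: int, shift_xy: tuple[float, float],
                 zoom: float, rotation_deg: float) -> np.ndarray:
    """3x3 forward map: shift, then zoom and rotation about the image centre."""
    cx, cy = (width - 1) / 2.0, (height - 1) / 2.0
    t = np.array([[1, 0, shift_xy[0]], [0, 1, shift_xy[1]], [0, 0, 1]], dtype=float)
    to_c = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1]], dtype=float)
    from_c = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1]], dtype=float)
    th = np.deg2rad(rotation_deg)
    rz = np.array([[np.cos(th) * zoom, -np.sin(th) * zoom, 0],
                   [np.sin(th) * zoom, np.cos(th) * zoom, 0],
                   [0, 0, 1]], dtype=float)
    return from_c @ rz @ to_c @ t


def _apply_photometric(image: np.ndarray, rng: np.random.Generator,
                       config: AugmentConfig) -> np.ndarray:
    img = image.astype(np.float64) / 255.0
    b = rng.uniform(-config.max_brightness_frac, config.max_brightness_frac)
    c = rng.uniform(-config.max_contrast_frac, config.max_contrast_frac)
    s = rng.uniform(-config.max_saturation_frac, config.max_saturation_frac)
    h = rng.uniform(-config.max_hue_frac, config.max_hue_frac)
    img = np.clip(img * (1.0 + b), 0, 1)
    mean = img.mean()
    img = np.clip(mean + (img - mean) * (1.0 + c), 0, 1)
    hsv = skcolor.rgb2hsv(img)
    hsv[..., 0] = (hsv[..., 0] + h) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * (1.0 + s), 0, 1)
    img = skcolor.hsv2rgb(hsv)
    return (np.clip(img, 0, 1) * 255).round().astype(np.uint8)


def augment_frame(frame: AnnotatedFrame, config: AugmentConfig,
                  rng: np.random.Generator) -> AnnotatedFrame:
    """Randomly transform a frame; image, mask and landmarks move together.

    With probability ``1 - augment_probability`` the frame is returned
    unchanged.  Deterministic given the generator state.
    """
    if rng.random() >= config.augment_probability:
        return frame
    w, h = frame.size
    shift = (rng.uniform(-config.max_shift_frac, config.max_shift_frac) * w,
             rng.uniform(-config.max_shift_frac, config.max_shift_frac) * h)
    zoom = 1.0 + rng.uniform(-config.max_zoom_frac, config.max_zoom_frac)
    rot = rng.uniform(-config.max_rotation_deg, config.max_rotation_deg)
    fwd = build_affine(w, h, shift, zoom, rot)
    inv = AffineTransform(matrix=np.linalg.inv(fwd))

    identity = (shift == (0.0, 0.0) and zoom == 1.0 and rot == 0.0)
    if identity:
        image, labels = frame.image, frame.mask.labels
    else:
        image = warp(frame.image, inv, order=1, preserve_range=True,
                     mode="constant", cval=0.0).round().astype(np.uint8)
        labels = warp(frame.mask.labels.astype(float), inv, order=0,
                      preserve_range=True, mode="constant", cval=0.0)
        labels = labels.round().astype(frame.mask.labels.dtype)

    landmarks = []
    for lm in frame.landmarks:
        p = fwd @ np.array([lm.x, lm.y, 1.0])
        x, y = float(p[0]), float(p[1])
        inside = 0 <= x < w and 0 <= y < h
        landmarks.append(LandmarkAnnotation(lm.structure_id, x, y,
                                            lm.annotated and inside))

    photometric_any = any((config.max_brightness_frac, config.max_contrast_frac,
                           config.max_saturation_frac, config.max_hue_frac))
    if photometric_any:
        image = _apply_photometric(image, rng, config)

    return AnnotatedFrame(
        frame_id=frame.frame_id,
        patient_id=frame.patient_id,
        image=image,
        mask=SegmentationMask(labels, class_annotated=dict(frame.mask.class_annotated)),
        landmarks=tuple(landmarks),
    )
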