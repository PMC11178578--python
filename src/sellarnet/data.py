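"""Frame/mask/landmark data model, manifest I/O and patient-wise fold splitting.

The unit of data is an :class:`AnnotatedFrame`: one RGB endoscopic frame, an
indexed segmentation mask (0 background, 1 sella, 2 clival recess) and exactly
four point landmarks (left/right carotid, left/right optic protuberance), each
carrying an ``annotated`` flag because only a fraction of frames have every
structure labelled.  A dataset is described by a CSV manifest; frames from the
same patient are never separated across cross-validation folds.

Coordinates are 0-based image coordinates (origin top-left, x rightward,
y downward), stored as floats at pixel centers.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "Structure",
    "LANDMARK_STRUCTURES",
    "REGION_CLASSES",
    "LandmarkAnnotation",
    "SegmentationMask",
    "AnnotatedFrame",
    "DatasetManifest",
    "FoldSplit",
    "read_manifest",
    "write_manifest",
    "load_frame",
    "split_by_patient",
    "class_distribution",
]


class Structure(str, enum.Enum):
    """The four point landmarks regressed by the model, in fixed output order."""

    LEFT_CAROTID = "left_carotid"
    RIGHT_CAROTID = "right_carotid"
    LEFT_OPTIC_PROTUBERANCE = "left_optic_protuberance"
    RIGHT_OPTIC_PROTUBERANCE = "right_optic_protuberance"


#: Fixed landmark order used everywhere (model output, losses, metrics).
LANDMARK_STRUCTURES: tuple[Structure, ...] = tuple(Structure)

#: Segmentation label -> region name. 0 is background.
REGION_CLASSES: dict[int, str] = {1: "sella", 2: "clival_recess"}


@dataclass(frozen=True)
class LandmarkAnnotation:
    """One landmark: which structure, where, and whether it was labelled."""

    structure_id: Structure
    x: float
    y: float
    annotated: bool

    def validate(self, width: int, height: int) -> None:
        if self.annotated and not (0 <= self.x < width and 0 <= self.y < height):
            raise ValueError(
                f"annotated landmark {self.structure_id.value} at "
                f"({self.x}, {self.y}) outside {width}x{height} image"
            )


@dataclass
class SegmentationMask:
    """Indexed mask (H, W) with labels {0, 1, 2} and per-class annotated flags.

    ``class_annotated`` distinguishes "region absent from this frame" (label
    never appears but the class was checked) from "region never labelled";
    unannotated classes are skipped by losses and metrics.
    """

    labels: np.ndarray
    class_annotated: dict[int, bool] = field(
        default_factory=lambda: {c: True for c in REGION_CLASSES}
    )

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("mask labels must be a 2-D grid")
        bad = set(np.unique(self.labels)) - ({0} | set(REGION_CLASSES))
        if bad:
            raise ValueError(f"mask contains labels outside {{0,1,2}}: {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]


@dataclass
class AnnotatedFrame:
    frame_id: str
    patient_id: str
    image: np.ndarray  # (H, W, 3) uint8
    mask: SegmentationMask
    landmarks: tuple[LandmarkAnnotation, ...]

    def __post_init__(self) -> None:
        ids = [lm.structure_id for lm in self.landmarks]
        if tuple(ids) != LANDMARK_STRUCTURES:
            raise ValueError(
                "frame must carry exactly one annotation per structure, in "
                f"fixed order {[s.value for s in LANDMARK_STRUCTURES]}"
            )
        h, w = self.image.shape[:2]
        if self.mask.shape != (h, w):
            raise ValueError(
                f"mask shape {self.mask.shape} does not match image {(h, w)}"
            )
        for lm in self.landmarks:
            lm.validate(w, h)

    @property
    def size(self) -> tuple[int, int]:
        """(width, height) in pixels."""
        h, w = self.image.shape[:2]
        return w, h

    def landmark_array(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ((4, 2) float xy coords, (4,) bool annotated)."""
        xy = np.array([[lm.x, lm.y] for lm in self.landmarks], dtype=float)
        ann = np.array([lm.annotated for lm in self.landmarks], dtype=bool)
        return xy, ann


_BASE_COLUMNS = ["frame_id", "patient_id", "image_path", "mask_path"]
_REGION_FLAG_COLUMNS = [f"{name}_annotated" for name in REGION_CLASSES.values()]


def _landmark_columns() -> list[str]:
    cols: list[str] = []
    for s in LANDMARK_STRUCTURES:
        cols += [f"{s.value}_x", f"{s.value}_y", f"{s.value}_annotated"]
    return cols


@dataclass
class DatasetManifest:
    """A table of frames: paths plus the landmark row and per-class flags.

    ``records`` is a DataFrame with the exact column layout written to CSV;
    ``root`` is the directory that relative image/mask paths resolve against.
    """

    records: pd.DataFrame
    image_size: tuple[int, int]  # (width, height)
    root: Path = Path(".")

    def __post_init__(self) -> None:
        missing = [c for c in _BASE_COLUMNS + _landmark_columns() if c not in self.records.columns]
        if missing:
            raise ValueError(f"manifest missing required columns: {missing}")
        dup = self.records["frame_id"][self.records["frame_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate frame_id(s): {sorted(set(dup))}")
        for col in _REGION_FLAG_COLUMNS:  # per-class flags default to annotated
            if col not in self.records.columns:
                self.records[col] = True
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def frame_ids(self) -> list[str]:
        return list(self.records["frame_id"])

    @property
    def patient_ids(self) -> list[str]:
        return sorted(set(self.records["patient_id"]))

    def row(self, frame_id: str) -> pd.Series:
        hits = self.records.index[self.records["frame_id"] == frame_id]
        if len(hits) == 0:
            raise KeyError(f"frame_id {frame_id!r} not in manifest")
        return self.records.loc[hits[0]]

    def annotation_flags(self) -> pd.DataFrame:
        """Per-frame boolean table over all 6 structures (2 regions + 4 landmarks)."""
        out = pd.DataFrame(index=self.records.index)
        for name in REGION_CLASSES.values():
            out[name] = self.records[f"{name}_annotated"].astype(bool)
        for s in LANDMARK_STRUCTURES:
            out[s.value] = self.records[f"{s.value}_annotated"].astype(bool)
        out.index = self.records["frame_id"]
        return out


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    path = Path(path)
    df = manifest.records.copy()
    header = f"# image_size={manifest.image_size[0]}x{manifest.image_size[1]}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_manifest(path: str | Path) -> DatasetManifest:
    """Read a manifest CSV (written by :func:`write_manifest` or compatible)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# image_size="):
            w, h = first.strip().removeprefix("# image_size=").split("x")
            size = (int(w), int(h))
            df = pd.read_csv(fh, dtype={"frame_id": str, "patient_id": str})
        else:
            raise ValueError("manifest missing '# image_size=WxH' header line")
    return DatasetManifest(records=df, image_size=size, root=path.parent)


def load_frame(manifest: DatasetManifest, frame_id: str) -> AnnotatedFrame:
    """Materialize one frame: read image + mask, assemble landmark records."""
    row = manifest.row(frame_id)
    image = np.asarray(Image.open(manifest.root / row["image_path"]).convert("RGB"))
    mask_arr = np.asarray(Image.open(manifest.root / row["mask_path"]))
    if mask_arr.ndim != 2:
        raise ValueError(f"mask for {frame_id} is not a single-channel indexed image")
    if mask_arr.shape != image.shape[:2]:
        raise ValueError(
            f"mask/image size mismatch for {frame_id}: {mask_arr.shape} vs {image.shape[:2]}"
        )
    flags = {c: bool(row[f"{name}_annotated"]) for c, name in REGION_CLASSES.items()}
    mask = SegmentationMask(mask_arr.astype(np.int64), class_annotated=flags)
    landmarks = []
    for s in LANDMARK_STRUCTURES:
        ann = bool(row[f"{s.value}_annotated"])
        x, y = row[f"{s.value}_x"], row[f"{s.value}_y"]
        if ann and (pd.isna(x) or pd.isna(y)):
            raise ValueError(f"{frame_id}: {s.value} flagged annotated but coordinates blank")
        landmarks.append(
            LandmarkAnnotation(s, float(x) if not pd.isna(x) else 0.0,
                               float(y) if not pd.isna(y) else 0.0, ann)
        )
    return AnnotatedFrame(
        frame_id=str(row["frame_id"]),
        patient_id=str(row["patient_id"]),
        image=image,
        mask=mask,
        landmarks=tuple(landmarks),
    )


@dataclass(frozen=True)
class FoldSplit:
    """frame_id -> fold index, with all frames of a patient in one fold."""

    assignment: dict[str, int]
    k: int

    def fold_of(self, frame_id: str) -> int:
        return self.assignment[frame_id]

    def frames_in_fold(self, fold: int) -> list[str]:
        return [f for f, i in self.assignment.items() if i == fold]


def split_by_patient(manifest: DatasetManifest, k: int, seed: int = 0) -> FoldSplit:
    """Patient-disjoint k-fold split balancing per-structure annotation counts.

    Patients are assigned greedily in decreasing order of total annotation
    count, each to the fold with the currently smallest total; ties among
    patients with equal counts are broken by a seed-shuffled order, so the
    split is deterministic given (manifest, k, seed).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    patients = manifest.patient_ids
    if len(patients) < k:
        raise ValueError(f"need at least k={k} patients, got {len(patients)}")
    flags = manifest.annotation_flags()
    frame_patient = dict(zip(manifest.records["frame_id"], manifest.records["patient_id"]))
    counts = {p: np.zeros(flags.shape[1], dtype=int) for p in patients}
    for fid in flags.index:
        counts[frame_patient[fid]] += flags.loc[fid].to_numpy(dtype=int)

    rng = np.random.default_rng(seed)
    order = list(rng.permutation(patients))
    order.sort(key=lambda p: -int(counts[p].sum()))

    fold_totals = np.zeros(k, dtype=int)
    patient_fold: dict[str, int] = {}
    for p in order:
        fold = int(np.argmin(fold_totals))
        patient_fold[p] = fold
        fold_totals[fold] += int(counts[p].sum())
    assignment = {fid: patient_fold[frame_patient[fid]] for fid in manifest.frame_ids}
    return FoldSplit(assignment=assignment, k=k)


def class_distribution(manifest: DatasetManifest, split: FoldSplit) -> pd.DataFrame:
    """Annotated-instance counts per structure (columns) per fold (rows)."""
    flags = manifest.annotation_flags()
    missing = [f for f in flags.index if f not in split.assignment]
    if missing:
        raise ValueError(f"frames missing from split: {missing[:5]}")
    table = pd.DataFrame(
        0, index=pd.RangeIndex(split.k, name="fold"), columns=flags.columns
    )
    for fid in flags.index:
        table.loc[split.assignment[fid]] += flags.loc[fid].to_numpy(dtype=int)
    return table
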