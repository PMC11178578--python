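import numpy as np
import pandas as pd
import pytest

from sellarnet.data import (
    LANDMARK_STRUCTURES,
    DatasetManifest,
    SegmentationMask,
    AnnotatedFrame,
    LandmarkAnnotation,
)


def make_manifest_df(rows):
    """Build a manifest records DataFrame from (frame_id, patient_id, lm_flags) rows."""
    out = []
    for frame_id, patient_id, lm_flags in rows:
        row = {
            "frame_id": frame_id,
            "patient_id": patient_id,
            "image_path": f"images/{frame_id}.png",
            "mask_path": f"masks/{frame_id}.png",
            "sella_annotated": True,
            "clival_recess_annotated": True,
        }
        for s, flag in zip(LANDMARK_STRUCTURES, lm_flags):
            row[f"{s.value}_x"] = 10.0 if flag else np.nan
            row[f"{s.value}_y"] = 12.0 if flag else np.nan
            row[f"{s.value}_annotated"] = flag
        out.append(row)
    return pd.DataFrame(out)


@pytest.fixture
def toy_manifest():
    rows = [
        ("f0", "p0", [True, True, False, False]),
        ("f1", "p0", [True, False, False, False]),
        ("f2", "p1", [True, True, True, True]),
        ("f3", "p2", [False, False, False, False]),
        ("f4", "p2", [True, True, True, False]),
        ("f5", "p3", [True, True, False, True]),
    ]
    return DatasetManifest(records=make_manifest_df(rows), image_size=(64, 64))


def make_frame(width=32, height=32, landmarks=None, labels=None,
               frame_id="f", patient_id="p"):
    if labels is None:
        labels = np.zeros((height, width), dtype=np.int64)
        labels[10:20, 8:22] = 1
        labels[24:28, 12:20] = 2
    if landmarks is None:
        landmarks = [(6.0, 15.0, True), (26.0, 15.0, True),
                     (8.0, 6.0, True), (24.0, 6.0, True)]
    lms = tuple(
        LandmarkAnnotation(s, x, y, a)
        for s, (x, y, a) in zip(LANDMARK_STRUCTURES, landmarks)
    )
    rng = np.random.default_rng(0)
    image = rng.integers(0, 255, size=(height, width, 3), dtype=np.uint8)
    return AnnotatedFrame(frame_id=frame_id, patient_id=patient_id, image=image,
                          mask=SegmentationMask(labels), landmarks=lms)


@pytest.fixture
def simple_frame():
    return make_frame()
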