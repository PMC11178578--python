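"""Learning-rate schedule, two-phase training contracts, evaluation oracles."""

import hashlib

import numpy as np
import pandas as pd
import pytest

from sellarnet.data import read_manifest, split_by_patient
from sellarnet.network import ModelOutput, NetworkConfig, build_model
from sellarnet.nn import Tensor
from sellarnet.synth import SceneSpec, generate_dataset
from sellarnet.train import (
    EngineExportUnavailableError,
    TrainConfig,
    cross_validate,
    evaluate,
    export_engine,
    lr_at_epoch,
    predict,
    train,
)


class TestSchedule:
    def test_published_anchor_points(self):
        cfg = TrainConfig()
        assert lr_at_epoch(cfg, 0) == pytest.approx(0.01)
        assert lr_at_epoch(cfg, cfg.epochs_total - 1) == pytest.approx(0.0001)

    def test_three_epoch_midpoint(self):
        cfg = TrainConfig(epochs_total=3, epochs_phase1=0)
        assert lr_at_epoch(cfg, 1) == pytest.approx(0.00505)

    def test_monotone_and_bounded(self):
        cfg = TrainConfig(epochs_total=50, epochs_phase1=10)
        lrs = [lr_at_epoch(cfg, e) for e in range(50)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))
        assert all(cfg.lr_min <= lr <= cfg.lr_initial for lr in lrs)

    def test_epoch_out_of_range_rejected(self):
        cfg = TrainConfig(epochs_total=10, epochs_phase1=5)
        with pytest.raises(ValueError):
            lr_at_epoch(cfg, 10)
        with pytest.raises(ValueError):
            lr_at_epoch(cfg, -1)

    def test_invalid_phase_split_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs_total=10, epochs_phase1=11)


@pytest.fixture(scope="module")
def micro_dataset(tmp_path_factory):
    """Tiny 64x64 dataset: 4 patients x 6 frames, everything annotated."""
    root = tmp_path_factory.mktemp("micro")
    spec = SceneSpec(image_size=(64, 64), n_patients=4, total_frames=24,
                     landmark_jitter_std_px=1.0, noise_amplitude=3.0,
                     landmark_dropout=0.0, specular_count=1, seed=5)
    generate_dataset(spec, root)
    return read_manifest(root / "manifest.csv")


def micro_config(**over):
    net = NetworkConfig.tiny(input_size=(64, 64))
    defaults = dict(epochs_total=4, epochs_phase1=2, batch_size=8, seed=0,
                    network=net)
    defaults.update(over)
    return TrainConfig(**defaults)


def _head_digest(model):
    h = hashlib.sha256()
    for p in model.landmark_head_parameters():
        h.update(p.data.tobytes())
    return h.hexdigest()


@pytest.fixture(scope="module")
def run(micro_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("run")
    split = split_by_patient(micro_dataset, 4, seed=0)
    cfg = micro_config()
    ckpt, log = train(cfg, micro_dataset, split, 0, out)
    return cfg, split, ckpt, log, out


class TestTwoPhaseTraining:
    def test_loss_log_has_two_phases(self, run):
        _, _, _, log, _ = run
        assert list(log["phase"]) == [1, 1, 2, 2]
        # landmark terms excluded from phase 1, active in phase 2
        assert (log.loc[log["phase"] == 1, "wing"] == 0).all()
        assert (log.loc[log["phase"] == 2, "wing"] > 0).all()

    def test_landmark_head_frozen_through_phase1(self, run, micro_dataset):
        cfg, _, _, _, out = run
        from sellarnet.network import load_checkpoint

        init = build_model(cfg.network, seed=cfg.seed)
        phase1 = load_checkpoint(out / "ckpt_phase1.npz")
        assert _head_digest(init) == _head_digest(phase1)
        final = load_checkpoint(out / "ckpt_final.npz")
        assert _head_digest(init) != _head_digest(final)

    def test_loss_decreases_within_each_phase(self, run):
        # totals are not comparable across phases (phase 2 adds the landmark
        # terms), so the sanity check is per phase
        _, _, _, log, _ = run
        p1 = log[log["phase"] == 1]["total"]
        p2 = log[log["phase"] == 2]["total"]
        assert p1.iloc[-1] < p1.iloc[0]
        assert p2.iloc[-1] < p2.iloc[0]

    def test_loss_trajectory_reproducible(self, micro_dataset, tmp_path):
        split = split_by_patient(micro_dataset, 4, seed=0)
        cfg = micro_config(epochs_total=2, epochs_phase1=1)
        _, log1 = train(cfg, micro_dataset, split, 0, tmp_path / "a")
        _, log2 = train(cfg, micro_dataset, split, 0, tmp_path / "b")
        pd.testing.assert_frame_equal(log1, log2)

    def test_empty_training_fold_rejected(self, micro_dataset):
        split = split_by_patient(micro_dataset, 1, seed=0)
        with pytest.raises(ValueError):
            train(micro_config(), micro_dataset, split, 0, "/tmp/unused")


class _OracleModel:
    """Emits the ground truth for every frame it is shown (keyed by pixels)."""

    def __init__(self, manifest, config, jitter_px=0.0):
        from sellarnet.data import load_frame
        from sellarnet.train import _frame_tensors

        self.config = config
        self.table = {}
        w, h = config.input_size
        for fid in manifest.frame_ids:
            frame = load_frame(manifest, fid)
            images, labels, coords, ann, _ = _frame_tensors([frame], (w, h))
            onehot = np.stack([(labels[0] == c).astype(np.float32) for c in range(3)])
            key = hashlib.sha256(images.tobytes()).hexdigest()
            self.table[key] = (onehot, coords[0] + jitter_px / w)

    def eval(self):
        return self

    def __call__(self, images):
        key = hashlib.sha256(np.asarray(images, dtype=np.float32).tobytes()).hexdigest()
        onehot, coords = self.table[key]
        return ModelOutput(seg_logits=Tensor(onehot[None] * 50.0),
                           landmark_coords=Tensor(coords[None]))


class _ConstantCentreModel:
    def __init__(self, config):
        self.config = config

    def eval(self):
        return self

    def __call__(self, images):
        n = np.asarray(images).shape[0]
        return ModelOutput(seg_logits=Tensor(np.zeros((n, 3, *self.config.input_size[::-1]))),
                           landmark_coords=Tensor(np.full((n, 8), 0.5)))


class TestEvaluate:
    def test_oracle_model_scores_perfectly(self, micro_dataset):
        cfg = NetworkConfig.tiny(input_size=(64, 64))
        oracle = _OracleModel(micro_dataset, cfg)
        report = evaluate(oracle, micro_dataset)
        assert report.iou_percent["sella"] == pytest.approx(100.0)
        assert report.mpck_percent == pytest.approx(100.0)
        assert report.mdistance_pixels == pytest.approx(0.0, abs=1e-4)

    def test_constant_centre_matches_brute_force_distance(self, micro_dataset):
        from sellarnet.data import load_frame

        cfg = NetworkConfig.tiny(input_size=(64, 64))
        model = _ConstantCentreModel(cfg)
        report = evaluate(model, micro_dataset)
        per_structure = [[] for _ in range(4)]
        for fid in micro_dataset.frame_ids:
            frame = load_frame(micro_dataset, fid)
            xy, ann = frame.landmark_array()
            for s in range(4):
                if ann[s]:
                    per_structure[s].append(np.hypot(xy[s, 0] - 32.0, xy[s, 1] - 32.0))
        expected = np.mean([np.mean(v) for v in per_structure])
        assert report.mdistance_pixels == pytest.approx(expected, rel=1e-3)

    def test_held_out_and_training_folds_both_evaluable(self, micro_dataset):
        cfg = NetworkConfig.tiny(input_size=(64, 64))
        oracle = _OracleModel(micro_dataset, cfg)
        split = split_by_patient(micro_dataset, 2, seed=0)
        for fold in (0, 1):
            report = evaluate(oracle, micro_dataset,
                              frame_ids=split.frames_in_fold(fold))
            assert report.n_frames == len(split.frames_in_fold(fold))
            assert np.isfinite(report.mpck_percent)


class TestCrossValidation:
    def test_two_fold_report_and_aggregate(self, micro_dataset, tmp_path):
        cfg = micro_config(epochs_total=2, epochs_phase1=1)
        result = cross_validate(cfg, micro_dataset, 2, tmp_path)
        assert len(result.fold_reports) == 2
        for key, value in result.aggregate.mean.items():
            vals = [r.flat()[key] for r in result.fold_reports]
            vals = [v for v in vals if not np.isnan(v)]
            if vals:
                assert value == pytest.approx(np.mean(vals))
                assert result.aggregate.std[key] == pytest.approx(np.std(vals))
        assert result.config is cfg
        assert (tmp_path / "crossval_report.txt").exists()

    def test_k_below_two_rejected(self, micro_dataset, tmp_path):
        with pytest.raises(ValueError):
            cross_validate(micro_config(), micro_dataset, 1, tmp_path)


@pytest.fixture(scope="module")
def trained(micro_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("predict_run")
    split = split_by_patient(micro_dataset, 4, seed=0)
    ckpt, _ = train(micro_config(epochs_total=2, epochs_phase1=1),
                    micro_dataset, split, 0, out)
    return ckpt


class TestPredict:
    def test_outputs_complete_and_in_bounds(self, trained, micro_dataset, tmp_path):
        from PIL import Image

        image_path = micro_dataset.root / micro_dataset.records.loc[0, "image_path"]
        payload = predict(trained, image_path, tmp_path)
        assert len(payload["landmarks"]) == 4
        for lm in payload["landmarks"]:
            assert 0 <= lm["x"] < 64 and 0 <= lm["y"] < 64
        mask = np.asarray(Image.open(tmp_path / f"{image_path.stem}_mask.png"))
        assert set(np.unique(mask)) <= {0, 1, 2}
        overlay = Image.open(tmp_path / f"{image_path.stem}_overlay.png")
        assert overlay.size == (64, 64)

    def test_unreadable_image_rejected(self, trained, tmp_path):
        with pytest.raises(FileNotFoundError):
            predict(trained, tmp_path / "missing.png", tmp_path)


class TestExport:
    def test_runtime_absent_gives_capability_error(self):
        with pytest.raises(EngineExportUnavailableError, match="TensorRT"):
            export_engine("ckpt.npz", "fp32")

    def test_unsupported_precision_rejected(self):
        with pytest.raises(ValueError, match="precision"):
            export_engine("ckpt.npz", "int8")
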