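"""High-resolution multi-branch backbone with segmentation and landmark heads.

The backbone keeps parallel feature streams at 1/4, 1/8, 1/16 and 1/32 of the
input resolution and repeatedly exchanges information between them, so the
1/4-resolution stream retains the spatial precision that point-landmark
regression needs.  With base width ``w`` the four branch widths are
``(w, 2w, 4w, 8w)``; after the last stage every branch is upsampled to 1/4
resolution and concatenated into a ``15w``-channel map (720 channels at the
reference width 48).

Two heads share that fused map:

* a segmentation head (1x1 conv + BN + ReLU, 1x1 conv to class scores,
  bilinear upsampling back to input resolution; argmax only at prediction
  time) for the sella and clival-recess regions, and
* a landmark head (1x1 conv, global average pooling, ReLU, fully connected
  layers) emitting eight sigmoid-bounded values read as the four landmark
  coordinates normalized to [0, 1] by image width/height, plus an optional
  presence head of four logits predicting whether each structure is labelled.

Stage depths follow the published high-resolution-network convention
(stage 1: four bottleneck units; stages 2-4: 1/4/3 exchange modules of four
basic residual blocks per branch) and are fully configurable; a ``tiny``
preset shrinks widths and depths so the model trains on one CPU core.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .nn import Tensor
from .nn import autograd as ag

__all__ = [
    "NetworkConfig",
    "ModelOutput",
    "MultiTaskHRNet",
    "build_model",
    "set_landmark_head_frozen",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class NetworkConfig:
    base_width: int = 48
    input_size: tuple[int, int] = (1280, 736)  # (width, height), divisible by 32
    num_seg_classes: int = 3
    num_landmarks: int = 4
    landmark_hidden_units: int = 256
    presence_head: bool = True
    stem_width: int = 64
    stage1_blocks: int = 4          # bottleneck units in stage 1
    stage_modules: tuple[int, int, int] = (1, 4, 3)  # exchange modules in stages 2-4
    blocks_per_module: int = 4      # basic residual blocks per branch per module

    @property
    def branch_widths(self) -> tuple[int, int, int, int]:
        w = self.base_width
        return (w, 2 * w, 4 * w, 8 * w)

    @property
    def fused_channels(self) -> int:
        return sum(self.branch_widths)  # = 15 * base_width

    def validate(self) -> None:
        if self.base_width < 1:
            raise ValueError("base_width must be >= 1")
        w, h = self.input_size
        if w % 32 or h % 32:
            raise ValueError(f"input size {self.input_size} must be divisible by 32")
        widths = self.branch_widths
        assert all(widths[i + 1] == 2 * widths[i] for i in range(3))

    @classmethod
    def tiny(cls, input_size: tuple[int, int] = (96, 96)) -> "NetworkConfig":
        """CPU-scale preset: width 8, one exchange module and one block per stage."""
        return cls(
            base_width=8,
            input_size=input_size,
            landmark_hidden_units=64,
            stem_width=16,
            stage1_blocks=1,
            stage_modules=(1, 1, 1),
            blocks_per_module=1,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_size"] = list(self.input_size)
        d["stage_modules"] = list(self.stage_modules)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["input_size"] = tuple(d["input_size"])
        d["stage_modules"] = tuple(d["stage_modules"])
        return cls(**d)


@dataclass
class ModelOutput:
    """seg_logits (N, C, H, W); landmark_coords (N, 8) in [0,1]; presence_logits (N, 4)."""

    seg_logits: Tensor
    landmark_coords: Tensor
    presence_logits: Tensor | None = None


def _conv_bn_relu(in_ch: int, out_ch: int, k: int, stride: int = 1) -> nn.Sequential:
    return nn.Sequential(nn.Conv2d(in_ch, out_ch, k, stride=stride),
                         nn.BatchNorm2d(out_ch), nn.ReLU())


class BasicBlock(nn.Module):
    def __init__(self, channels: int):
        super().__init__()
        self.conv1 = nn.Conv2d(channels, channels, 3)
        self.bn1 = nn.BatchNorm2d(channels)
        self.conv2 = nn.Conv2d(channels, channels, 3)
        self.bn2 = nn.BatchNorm2d(channels)

    def forward(self, x: Tensor) -> Tensor:
        out = ag.relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        return ag.relu(out + x)


class Bottleneck(nn.Module):
    expansion = 4

    def __init__(self, in_ch: int, planes: int):
        super().__init__()
        out_ch = planes * self.expansion
        self.conv1 = nn.Conv2d(in_ch, planes, 1)
        self.bn1 = nn.BatchNorm2d(planes)
        self.conv2 = nn.Conv2d(planes, planes, 3)
        self.bn2 = nn.BatchNorm2d(planes)
        self.conv3 = nn.Conv2d(planes, out_ch, 1)
        self.bn3 = nn.BatchNorm2d(out_ch)
        self.down = None
        if in_ch != out_ch:
            self.down = nn.Sequential(nn.Conv2d(in_ch, out_ch, 1), nn.BatchNorm2d(out_ch))

    def forward(self, x: Tensor) -> Tensor:
        out = ag.relu(self.bn1(self.conv1(x)))
        out = ag.relu(self.bn2(self.conv2(out)))
        out = self.bn3(self.conv3(out))
        skip = self.down(x) if self.down is not None else x
        return ag.relu(out + skip)


class ExchangeModule(nn.Module):
    """Per-branch residual blocks followed by all-to-all cross-resolution fusion.

    Fusion from a lower-resolution branch uses 1x1 conv + BN + bilinear
    upsampling; fusion to a lower resolution uses repeated stride-2 3x3
    convolutions.  Contributions are summed and passed through ReLU.
    """

    def __init__(self, widths: tuple[int, ...], n_blocks: int):
        super().__init__()
        self.n = len(widths)
        self.branches = nn.ModuleList(
            nn.Sequential(*[BasicBlock(w) for _ in range(n_blocks)]) for w in widths
        )
        fuse = []
        for i in range(self.n):          # output branch
            row = []
            for j in range(self.n):      # input branch
                if j == i:
                    row.append(None)
                elif j > i:  # lower res -> channel-match then upsample
                    row.append(nn.Sequential(
                        nn.Conv2d(widths[j], widths[i], 1), nn.BatchNorm2d(widths[i])))
                else:        # higher res -> repeated strided conv
                    ops: list[nn.Module] = []
                    ch = widths[j]
                    for step in range(i - j):
                        last = step == i - j - 1
                        out_ch = widths[i] if last else widths[j]
                        ops.append(nn.Conv2d(ch, out_ch, 3, stride=2))
                        ops.append(nn.BatchNorm2d(out_ch))
                        if not last:
                            ops.append(nn.ReLU())
                        ch = out_ch
                    row.append(nn.Sequential(*ops))
            fuse.append(nn.ModuleList([m for m in row if m is not None]))
        self.fuse = nn.ModuleList(fuse)
        self._fuse_index = [
            [None if j == i else sum(1 for jj in range(j) if jj != i) for j in range(self.n)]
            for i in range(self.n)
        ]

    def forward(self, xs: list[Tensor]) -> list[Tensor]:
        xs = [branch(x) for branch, x in zip(self.branches, xs)]
        outs = []
        for i in range(self.n):
            acc = xs[i]
            for j in range(self.n):
                if j == i:
                    continue
                m = self.fuse[i][self._fuse_index[i][j]]
                y = m(xs[j])
                if j > i:
                    y = ag.upsample_bilinear(y, 2 ** (j - i))
                acc = acc + y
            outs.append(ag.relu(acc))
        return outs


class MultiTaskHRNet(nn.Module):
    def __init__(self, config: NetworkConfig):
        super().__init__()
        config.validate()
        self.config = config
        w = config.base_width
        widths = config.branch_widths

        # stem: two stride-2 3x3 convs -> 1/4 resolution
        self.stem = nn.Sequential(
            _conv_bn_relu(3, config.stem_width, 3, stride=2),
            _conv_bn_relu(config.stem_width, config.stem_width, 3, stride=2),
        )

        # stage 1: bottleneck residual units at 1/4 resolution
        blocks = [Bottleneck(config.stem_width, w)]
        for _ in range(config.stage1_blocks - 1):
            blocks.append(Bottleneck(w * Bottleneck.expansion, w))
        self.stage1 = nn.Sequential(*blocks)
        stage1_out = w * Bottleneck.expansion

        # transitions create one extra (half-resolution, double-width) branch
        self.transition1 = nn.ModuleList([
            _conv_bn_relu(stage1_out, widths[0], 3),
            _conv_bn_relu(stage1_out, widths[1], 3, stride=2),
        ])
        self.transition2 = _conv_bn_relu(widths[1], widths[2], 3, stride=2)
        self.transition3 = _conv_bn_relu(widths[2], widths[3], 3, stride=2)

        m2, m3, m4 = config.stage_modules
        nb = config.blocks_per_module
        self.stage2 = nn.ModuleList(ExchangeModule(widths[:2], nb) for _ in range(m2))
        self.stage3 = nn.ModuleList(ExchangeModule(widths[:3], nb) for _ in range(m3))
        self.stage4 = nn.ModuleList(ExchangeModule(widths[:4], nb) for _ in range(m4))

        fused = config.fused_channels
        self.seg_head = nn.Sequential(
            nn.Conv2d(fused, fused, 1), nn.BatchNorm2d(fused), nn.ReLU(),
            nn.Conv2d(fused, config.num_seg_classes, 1, bias=True),
        )
        self.landmark_conv = nn.Conv2d(fused, fused, 1, bias=True)
        self.landmark_fc1 = nn.Linear(fused, config.landmark_hidden_units)
        self.landmark_fc2 = nn.Linear(config.landmark_hidden_units, 2 * config.num_landmarks)
        self.presence_fc = (
            nn.Linear(fused, config.num_landmarks) if config.presence_head else None
        )

    # -- forward ---------------------------------------------------------------
    def forward(self, images) -> ModelOutput:
        x = images if isinstance(images, Tensor) else Tensor(images)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (N, 3, H, W) input, got {x.shape}")
        wexp, hexp = self.config.input_size
        if (x.shape[2], x.shape[3]) != (hexp, wexp):
            raise ValueError(
                f"input spatial size {x.shape[2:]} != configured (H, W)=({hexp}, {wexp})"
            )
        x = self.stem(x)
        x = self.stage1(x)
        xs = [t(x) for t in self.transition1]
        for m in self.stage2:
            xs = m(xs)
        xs = xs + [self.transition2(xs[-1])]
        for m in self.stage3:
            xs = m(xs)
        xs = xs + [self.transition3(xs[-1])]
        for m in self.stage4:
            xs = m(xs)
        fused = ag.concatenate(
            [xs[0]] + [ag.upsample_bilinear(t, 2 ** i) for i, t in enumerate(xs[1:], 1)],
            axis=1,
        )
        assert fused.shape[1] == self.config.fused_channels
        assert fused.shape[2] == hexp // 4 and fused.shape[3] == wexp // 4

        seg = ag.upsample_bilinear(self.seg_head(fused), 4)

        lm = self.landmark_conv(fused)
        pooled = ag.relu(lm.mean(axis=(2, 3)))  # adaptive average pool to 1x1
        hidden = ag.relu(self.landmark_fc1(pooled))
        coords = ag.sigmoid(self.landmark_fc2(hidden))
        presence = self.presence_fc(pooled) if self.presence_fc is not None else None
        return ModelOutput(seg_logits=seg, landmark_coords=coords, presence_logits=presence)

    # -- landmark-head freezing ------------------------------------------------
    def landmark_head_modules(self) -> list[nn.Module]:
        mods = [self.landmark_conv, self.landmark_fc1, self.landmark_fc2]
        if self.presence_fc is not None:
            mods.append(self.presence_fc)
        return mods

    def landmark_head_parameters(self) -> list[Tensor]:
        return [p for m in self.landmark_head_modules() for p in m.parameters()]


def build_model(config: NetworkConfig, seed: int | None = None) -> MultiTaskHRNet:
    """Construct the model; `seed` makes weight initialization reproducible."""
    if seed is not None:
        nn.set_init_seed(seed)
    return MultiTaskHRNet(config)


def set_landmark_head_frozen(model: MultiTaskHRNet, frozen: bool) -> None:
    """Freeze/unfreeze landmark (and presence) head parameters.

    Frozen parameters receive no optimizer updates; the backbone and the
    segmentation head keep training.  Forward outputs are unaffected.
    """
    for m in model.landmark_head_modules():
        m.set_requires_grad(not frozen)


def save_checkpoint(model: MultiTaskHRNet, path: str | Path) -> None:
    """Write weights to `<path>` (npz) and the NetworkConfig to `<path>.yaml`."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    actual = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    cfg_path = Path(str(actual) + ".yaml")
    cfg_path.write_text(yaml.safe_dump(model.config.to_dict()))


def load_checkpoint(path: str | Path) -> MultiTaskHRNet:
    path = Path(path)
    if not path.exists():
        path = path.with_suffix(path.suffix + ".npz")
    cfg = NetworkConfig.from_dict(yaml.safe_load(Path(str(path) + ".yaml").read_text()))
    model = MultiTaskHRNet(cfg)
    with np.load(path) as state:
        model.load_state_dict(dict(state))
    return model
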