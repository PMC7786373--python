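"""Two-view compressed 2D residual classifiers and 3D residual baselines.

The central idea: a 3D lesion volume ``x(h, w, l)`` is folded along one
spatial axis so that axis becomes the channel axis of a 2D image
(``x(h,w,l) -> x1(c=h, w, l)``), then a single strided 2D convolution +
batch normalisation + ReLU compresses it to a 32-channel 2D map.  Doing this
along two different axes and concatenating the maps ("two-view fusion")
retains cross-axis structure that a single view would lose, and produces a
64-channel 2D input that a standard 18/34-layer residual backbone can
consume — which makes 2D pretrained weights directly transferable and cuts
the learnable-parameter total to roughly a third of the 3D baseline's.

Reference configurations
------------------------
two_view_2d: per-view compression convolution with 98 input channels
(volumes are 100³; the folded axes are centre-cropped by one voxel per side),
32 output channels, 7×7 kernel, stride 3, no bias, non-affine normalisation.
The backbone's 7×7 stem convolution and its normalisation are omitted; the
fused 64-channel map enters at the first pooling stage, whose following
residual stage natively expects 64 channels.  Output head: global average
pool, dropout, a 2-unit affine layer.

resnet3d: a standard 18/34-layer residual network with 3×3×3 block
convolutions without bias, a single-channel 7×7×7 stem WITH bias, 1×1×1
downsample projections WITH bias, and affine normalisation throughout.

These choices reproduce the published complexity totals exactly:
11,475,330 / 21,583,490 parameters for the two-view models at depths 18/34
and 33,161,986 / 63,471,618 for the 3D baselines.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .errors import ShapeError, TransferError, ValidationError
from .io_formats import SubjectRecord

_STAGE_BLOCKS = {18: (2, 2, 2, 2), 34: (3, 4, 6, 3)}
_STAGE_CHANNELS = (64, 128, 256, 512)

INPUT_MODES = ("mask", "flair", "masked_flair")


@dataclass(frozen=True)
class ConvSpec:
    """Shape/bias contract of one convolution, with exact parameter count."""

    in_channels: int
    out_channels: int
    kernel: int
    stride: int = 1
    has_bias: bool = False
    dimensionality: str = "2d"

    def __post_init__(self):
        if self.dimensionality not in ("2d", "3d"):
            raise ValidationError(f"dimensionality must be 2d or 3d, got {self.dimensionality}")
        if min(self.in_channels, self.out_channels, self.kernel, self.stride) < 1:
            raise ValidationError("ConvSpec fields must be positive")

    @property
    def ndim(self) -> int:
        return 2 if self.dimensionality == "2d" else 3

    def param_count(self) -> int:
        n = self.kernel ** self.ndim * self.in_channels * self.out_channels
        return n + (self.out_channels if self.has_bias else 0)

    def output_extent(self, spatial: int, padding: int = 0) -> int:
        return (spatial + 2 * padding - self.kernel) // self.stride + 1


@dataclass(frozen=True)
class CompressionConfig:
    """Configuration of one axis-folding compression branch."""

    kernel: int = 7
    stride: int = 3
    out_channels: int = 32
    per_view_in_channels: int = 98
    conv_bias: bool = False
    norm_affine: bool = False

    def conv_spec(self) -> ConvSpec:
        return ConvSpec(self.per_view_in_channels, self.out_channels, self.kernel,
                        self.stride, self.conv_bias, "2d")

    def output_extent(self, spatial: int) -> int:
        return (spatial - self.kernel) // self.stride + 1

    @property
    def input_side(self) -> int:
        """Cube side compatible with this config (folded axes lose 2 voxels)."""
        return self.per_view_in_channels + 2


@dataclass(frozen=True)
class ModelSpec:
    family: str = "two_view_2d"
    depth: int = 18
    num_classes: int = 2
    dropout_rate: float = 0.15
    pretrained: bool = False
    compression: CompressionConfig = field(default_factory=CompressionConfig)

    def __post_init__(self):
        if self.family not in ("two_view_2d", "resnet3d"):
            raise ValidationError(f"unknown model family {self.family!r}")
        if self.depth not in _STAGE_BLOCKS:
            raise ValidationError(f"depth must be one of {sorted(_STAGE_BLOCKS)}, got {self.depth}")

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "ModelSpec":
        d = dict(d)
        if isinstance(d.get("compression"), dict):
            d["compression"] = CompressionConfig(**d["compression"])
        return ModelSpec(**d)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class BasicBlock(nn.Module):
    """Residual block y = F(x) + x with two 3^d convolutions."""

    def __init__(self, ndim: int, in_channels: int, out_channels: int, stride: int,
                 rng: np.random.Generator, conv_bias: bool = False, ds_bias: bool = False):
        super().__init__()
        conv = nn.Conv2d if ndim == 2 else nn.Conv3d
        self.add_module("conv1", conv(in_channels, out_channels, 3, stride=stride,
                                      padding=1, bias=conv_bias, rng=rng))
        self.add_module("bn1", nn.BatchNorm(out_channels))
        self.add_module("relu1", nn.ReLU())
        self.add_module("conv2", conv(out_channels, out_channels, 3, stride=1,
                                      padding=1, bias=conv_bias, rng=rng))
        self.add_module("bn2", nn.BatchNorm(out_channels))
        # zero-init the residual branch's final gain: each block starts as the
        # identity, which keeps deep stacks trainable at lr 0.01 with small batches
        self.bn2.weight.data[...] = 0.0
        if stride != 1 or in_channels != out_channels:
            self.add_module("downsample", nn.Sequential(
                conv(in_channels, out_channels, 1, stride=stride, bias=ds_bias, rng=rng),
                nn.BatchNorm(out_channels),
            ))
        else:
            self.downsample = None
        self._out_mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.bn2(self.conv2(self.relu1(self.bn1(self.conv1(x)))))
        identity = self.downsample(x) if self.downsample is not None else x
        y = h + identity
        if self.training:
            self._out_mask = y > 0
        return np.maximum(y, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad * self._out_mask
        self._out_mask = None
        g_main = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(g)))))
        g_id = self.downsample.backward(g) if self.downsample is not None else g
        return g_main + g_id


def _make_stage(ndim, in_channels, out_channels, blocks, stride, rng,
                conv_bias=False, ds_bias=False) -> nn.Sequential:
    layers = [BasicBlock(ndim, in_channels, out_channels, stride, rng,
                         conv_bias=conv_bias, ds_bias=ds_bias)]
    for _ in range(blocks - 1):
        layers.append(BasicBlock(ndim, out_channels, out_channels, 1, rng,
                                 conv_bias=conv_bias, ds_bias=ds_bias))
    return nn.Sequential(*layers)


class ResNetBackbone2d(nn.Module):
    """Stem-less 2D residual backbone: maxpool -> 4 stages -> GAP -> dropout -> fc.

    Sub-module names mirror the conventional 2D residual-network layout
    (``layer1`` … ``layer4``, ``fc``) so pretrained weight archives using
    those names transfer without renaming.
    """

    def __init__(self, depth: int, num_classes: int, dropout_rate: float,
                 rng: np.random.Generator):
        super().__init__()
        blocks = _STAGE_BLOCKS[depth]
        self.add_module("maxpool", nn.MaxPool2d(3, 2, 1))
        in_ch = 64
        for i, (out_ch, n) in enumerate(zip(_STAGE_CHANNELS, blocks), start=1):
            stride = 1 if i == 1 else 2
            self.add_module(f"layer{i}", _make_stage(2, in_ch, out_ch, n, stride, rng))
            in_ch = out_ch
        self.add_module("avgpool", nn.GlobalAvgPool())
        self.add_module("dropout", nn.Dropout(dropout_rate))
        self.add_module("fc", nn.Linear(512, num_classes, bias=True, rng=rng))

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = self.maxpool(x)
        for i in range(1, 5):
            x = self._modules[f"layer{i}"](x)
        return self.fc(self.dropout(self.avgpool(x)))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.avgpool.backward(self.dropout.backward(self.fc.backward(grad)))
        for i in range(4, 0, -1):
            g = self._modules[f"layer{i}"].backward(g)
        return self.maxpool.backward(g)


class CompressionBranch(nn.Module):
    """conv2d(folded volume) -> batch norm -> ReLU for one view."""

    def __init__(self, cfg: CompressionConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.add_module("conv", nn.Conv2d(cfg.per_view_in_channels, cfg.out_channels,
                                          cfg.kernel, stride=cfg.stride,
                                          bias=cfg.conv_bias, first_layer=True, rng=rng))
        self.add_module("bn", nn.BatchNorm(cfg.out_channels, affine=cfg.norm_affine))
        self.add_module("relu", nn.ReLU())

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.relu(self.bn(self.conv(x)))

    def backward(self, grad: np.ndarray) -> None:
        return self.conv.backward(self.bn.backward(self.relu.backward(grad)))


class TwoViewResNet(nn.Module):
    """Two compression branches (folding h and w), fused, into a 2D backbone.

    Input: a batch of cube volumes ``(N, S, S, S)`` with
    ``S = per_view_in_channels + 2``; the folded axis of each view is
    centre-cropped by one voxel per side before folding.
    """

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        cfg = spec.compression
        if 2 * cfg.out_channels != 64:
            raise ValidationError("fused channel count must be 64 to enter the backbone")
        self.add_module("compress_h", CompressionBranch(cfg, rng))
        self.add_module("compress_w", CompressionBranch(cfg, rng))
        self.add_module("backbone", ResNetBackbone2d(spec.depth, spec.num_classes,
                                                     spec.dropout_rate, rng))

    def _fold(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cfg = self.spec.compression
        c = cfg.per_view_in_channels
        s = x.shape[1]
        if x.ndim != 4 or x.shape[1:] != (s, s, s) or s < c:
            raise ShapeError(f"expected (N, S, S, S) cube with S >= {c}, got {x.shape}")
        lo = (s - c) // 2
        x1 = x[:, lo:lo + c, :, :]                      # fold h -> (N, c, w, l)
        x2 = np.swapaxes(x[:, :, lo:lo + c, :], 1, 2)   # fold w -> (N, c, h, l)
        return np.ascontiguousarray(x1), np.ascontiguousarray(x2)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x1, x2 = self._fold(x)
        y1 = self.compress_h(x1)
        y2 = self.compress_w(x2)
        fused = np.concatenate([y1, y2], axis=1)
        return self.backbone(fused)

    def backward(self, grad: np.ndarray) -> None:
        g = self.backbone.backward(grad)
        c = self.spec.compression.out_channels
        self.compress_h.backward(np.ascontiguousarray(g[:, :c]))
        self.compress_w.backward(np.ascontiguousarray(g[:, c:]))
        return None


class ResNet3d(nn.Module):
    """3D residual baseline on single-channel volumes ``(N, 1, h, w, l)``."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        blocks = _STAGE_BLOCKS[spec.depth]
        self.add_module("conv1", nn.Conv3d(1, 64, 7, stride=2, padding=3,
                                           bias=True, first_layer=True, rng=rng))
        self.add_module("bn1", nn.BatchNorm(64))
        self.add_module("relu", nn.ReLU())
        self.add_module("maxpool", nn.MaxPool3d(3, 2, 1))
        in_ch = 64
        for i, (out_ch, n) in enumerate(zip(_STAGE_CHANNELS, blocks), start=1):
            stride = 1 if i == 1 else 2
            self.add_module(f"layer{i}", _make_stage(3, in_ch, out_ch, n, stride, rng,
                                                     conv_bias=False, ds_bias=True))
            in_ch = out_ch
        self.add_module("avgpool", nn.GlobalAvgPool())
        self.add_module("dropout", nn.Dropout(spec.dropout_rate))
        self.add_module("fc", nn.Linear(512, spec.num_classes, bias=True, rng=rng))

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim == 4:  # allow (N, h, w, l)
            x = x[:, None]
        x = self.maxpool(self.relu(self.bn1(self.conv1(x))))
        for i in range(1, 5):
            x = self._modules[f"layer{i}"](x)
        return self.fc(self.dropout(self.avgpool(x)))

    def backward(self, grad: np.ndarray) -> None:
        g = self.avgpool.backward(self.dropout.backward(self.fc.backward(grad)))
        for i in range(4, 0, -1):
            g = self._modules[f"layer{i}"].backward(g)
        self.conv1.backward(self.bn1.backward(self.relu.backward(self.maxpool.backward(g))))
        return None


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def build_model(spec: ModelSpec, seed: int = 0) -> nn.Module:
    """Deterministically build a classifier for the given spec."""
    rng = np.random.default_rng(seed)
    if spec.family == "two_view_2d":
        model = TwoViewResNet(spec, rng)
    else:
        model = ResNet3d(spec, rng)
    model.set_rng(np.random.default_rng(np.random.SeedSequence([seed, 0xD0]).generate_state(1)[0]))
    return model


def count_learnable_parameters(model: nn.Module) -> int:
    """Sum of element counts over trainable arrays (buffers excluded)."""
    return sum(p.size for _, p in model.named_parameters())


def compress_view(x: np.ndarray, folded_axis: str, cfg: CompressionConfig,
                  state: CompressionBranch | None = None, seed: int = 0) -> np.ndarray:
    """Fold one axis of a rank-3 volume into channels and compress to a 2D map.

    ``folded_axis`` is ``"h"`` (axis 0) or ``"w"`` (axis 1); its extent must
    equal ``cfg.per_view_in_channels``.  ``state`` supplies learned weights
    and running normalisation statistics; if omitted a freshly initialised
    branch is used.  Normalisation runs in inference mode (stored statistics).
    """
    if folded_axis not in ("h", "w"):
        raise ValidationError(f"folded_axis must be 'h' or 'w', got {folded_axis!r}")
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 3:
        raise ShapeError(f"expected a rank-3 volume, got shape {x.shape}")
    axis = 0 if folded_axis == "h" else 1
    if x.shape[axis] != cfg.per_view_in_channels:
        raise ShapeError(
            f"extent of folded axis {folded_axis} is {x.shape[axis]}, "
            f"expected {cfg.per_view_in_channels}")
    folded = np.moveaxis(x, axis, 0)
    spatial = folded.shape[1:]
    if min(spatial) < cfg.kernel:
        raise ShapeError(f"non-folded extents {spatial} smaller than kernel {cfg.kernel}")
    branch = state if state is not None else CompressionBranch(cfg, np.random.default_rng(seed))
    was_training = branch.training
    branch.eval()
    y = branch(folded[None])[0]
    branch.train(was_training)
    return y


def fuse_views(y1: np.ndarray, y2: np.ndarray) -> np.ndarray:
    """Channel-axis concatenation of two view features, view 1 first."""
    y1 = np.asarray(y1)
    y2 = np.asarray(y2)
    if y1.ndim != 3 or y2.ndim != 3 or y1.shape[1:] != y2.shape[1:]:
        raise ShapeError(f"spatial extents differ: {y1.shape} vs {y2.shape}")
    return np.concatenate([y1, y2], axis=0)


def load_pretrained_backbone(model: nn.Module, weight_source) -> nn.Module:
    """Copy residual-stage and normalisation weights into a two-view model.

    ``weight_source`` is a mapping from conventional 2D residual-network
    array names (``layer1.0.conv1.weight`` …) to arrays, or a path to an
    ``.npz`` archive of such arrays.  The compression branches and the final
    output layer are left untouched; every backbone stage array must be
    present with a matching shape.
    """
    if not isinstance(model, TwoViewResNet):
        raise ValidationError("pretrained loading applies to two_view_2d models only")
    if isinstance(weight_source, (str, Path)):
        p = Path(weight_source)
        if not p.exists():
            raise IOError(f"weight source not found: {p}")
        weight_source = dict(np.load(str(p)))
    targets = [(name, param, True) for name, param in model.backbone.named_parameters()]
    targets += [(name, buf, False) for name, buf in model.backbone.named_buffers()]
    consumed = set()
    for name, arr, is_param in targets:
        if name.startswith("fc."):
            continue
        if name not in weight_source:
            raise TransferError(f"weight source missing array {name!r}")
        src = np.asarray(weight_source[name], dtype=np.float32)
        dst = arr.data if is_param else arr
        if src.shape != dst.shape:
            raise TransferError(
                f"shape mismatch for {name!r}: source {src.shape} vs model {dst.shape}")
        if is_param:
            arr.data[...] = src
        else:
            model.backbone._assign_buffer(name, src)
        consumed.add(name)
    # a deeper source (extra residual blocks) must not load silently
    extra = sorted(k for k in weight_source
                   if k.startswith("layer") and k not in consumed
                   and not k.endswith("num_batches_tracked"))
    if extra:
        raise TransferError(f"source has residual-stage arrays the model lacks: {extra[:4]}")
    return model


def _subject_input(s: SubjectRecord, input_mode: str) -> np.ndarray:
    if input_mode not in INPUT_MODES:
        raise ValidationError(f"input_mode must be one of {INPUT_MODES}, got {input_mode!r}")
    if input_mode == "mask":
        return s.mask.data.astype(np.float32)
    if input_mode == "flair":
        return s.flair.data.astype(np.float32)
    return (s.flair.data * s.mask.data).astype(np.float32)


def forward_classify(model: nn.Module, s: SubjectRecord, input_mode: str = "mask") -> np.ndarray:
    """Class probabilities (softmax over the 2 logits) for one subject."""
    x = _subject_input(s, input_mode)[None]
    was_training = model.training
    model.eval()
    logits = model(x)
    model.train(was_training)
    return nn.softmax(logits)[0]


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: nn.Module, spec: ModelSpec, path) -> Path:
    """Named-array archive plus a JSON sidecar with the spec and config hash."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    spec_dict = spec.to_dict()
    digest = hashlib.sha256(json.dumps(spec_dict, sort_keys=True).encode()).hexdigest()
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"spec": spec_dict, "config_sha256": digest}, indent=2))
    return path


def load_checkpoint(path) -> tuple[nn.Module, ModelSpec]:
    path = Path(path)
    spec = ModelSpec.from_dict(json.loads(path.with_suffix(".json").read_text())["spec"])
    model = build_model(spec)
    model.load_state_dict(dict(np.load(str(path))))
    return model, spec
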