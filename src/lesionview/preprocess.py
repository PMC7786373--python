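"""Preprocessing: background crop, paired crop, cube resize, normalisation,
shift/flip augmentation.

The pipeline mirrors the standard route from a skull-stripped FLAIR export
to network-ready cubes: (i) a tight foreground bounding box ("crop kernel")
is computed on the FLAIR volume, (ii) the same kernel is reused to crop the
paired lesion mask, (iii) both are resized to a 100³ cube — each in-plane
section first, then the stack along the first axis — and (iv) the training
set is expanded with random integer shifts and flips applied identically to
image and mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import NoForegroundError, ValidationError
from .io_formats import SubjectRecord, Volume

AXES = ("h", "w", "l")


@dataclass(frozen=True)
class CropKernel:
    """Axis-aligned bounding box; 0-based, half-open on every axis."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self):
        if len(self.lo) != 3 or len(self.hi) != 3:
            raise ValidationError("CropKernel lo/hi must be 3-vectors")
        if any(l < 0 or l >= h for l, h in zip(self.lo, self.hi)):
            raise ValidationError(f"invalid crop kernel lo={self.lo} hi={self.hi}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))


@dataclass(frozen=True)
class AugmentSpec:
    """Random shift/flip augmentation parameters.

    Defaults: shifts up to 2 voxels per axis and flips on the ``w`` axis
    only (left–right anatomical symmetry), 4 augmented copies per subject.
    """

    max_shift: int = 2
    flip_axes: tuple[str, ...] = ("w",)
    n_per_subject: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.max_shift < 0:
            raise ValidationError("max_shift must be non-negative")
        if self.n_per_subject < 1:
            raise ValidationError("n_per_subject must be positive")
        bad = set(self.flip_axes) - set(AXES)
        if bad:
            raise ValidationError(f"unknown flip axes {sorted(bad)}; valid: {AXES}")


def compute_crop_kernel(v: Volume, background_threshold: float = 0.0) -> CropKernel:
    """Tightest box containing every voxel strictly above the threshold.

    Computed on the FLAIR volume; the same kernel is then reused for the
    subject's lesion mask so both stay aligned.
    """
    fg = v.data > background_threshold
    if not fg.any():
        raise NoForegroundError(
            f"no voxel above threshold {background_threshold} in {v.subject_id or 'volume'}")
    lo, hi = [], []
    for axis in range(3):
        other = tuple(a for a in range(3) if a != axis)
        prof = fg.any(axis=other)
        idx = np.flatnonzero(prof)
        lo.append(int(idx[0]))
        hi.append(int(idx[-1]) + 1)
    return CropKernel(tuple(lo), tuple(hi))


def apply_crop(v: Volume, k: CropKernel) -> Volume:
    if any(h > s for h, s in zip(k.hi, v.data.shape)):
        raise ValidationError(f"crop kernel {k} exceeds volume shape {v.data.shape}")
    sl = tuple(slice(l, h) for l, h in zip(k.lo, k.hi))
    return v.with_data(v.data[sl].copy())


def resize_to_cube(v: Volume, side: int = 100) -> Volume:
    """Resize to ``(side, side, side)``: every (w, l) section in-plane first,
    then the section stack along h.  Masks use nearest-neighbour resampling
    and stay binary; intensity volumes use linear interpolation.
    """
    if side < 1:
        raise ValidationError(f"side must be >= 1, got {side}")
    is_mask = v.modality == "wmh_mask"
    order = 0 if is_mask else 1
    data = v.data.astype(np.uint8 if is_mask else np.float32)
    h = data.shape[0]
    inplane = _sk_resize(data, (h, side, side), order=order, preserve_range=True,
                         anti_aliasing=False)
    cube = _sk_resize(inplane, (side, side, side), order=order, preserve_range=True,
                      anti_aliasing=False)
    cube = cube.astype(np.uint8 if is_mask else np.float32)
    return v.with_data(cube)


def normalize_intensity(v: Volume) -> Volume:
    """Per-volume min–max scaling to [0, 1]; constant volumes map to 0."""
    data = v.data.astype(np.float32)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        return v.with_data(np.zeros_like(data))
    return v.with_data((data - lo) / (hi - lo))


def _shift_zero_fill(data: np.ndarray, offsets: tuple[int, int, int]) -> np.ndarray:
    """Integer translation; vacated voxels are zero-filled."""
    out = np.zeros_like(data)
    src, dst = [], []
    for n, off in zip(data.shape, offsets):
        if abs(off) >= n:
            return out
        if off >= 0:
            src.append(slice(0, n - off))
            dst.append(slice(off, n))
        else:
            src.append(slice(-off, n))
            dst.append(slice(0, n + off))
    out[tuple(dst)] = data[tuple(src)]
    return out


def augment(s: SubjectRecord, spec: AugmentSpec) -> list[SubjectRecord]:
    """Random shifted/flipped copies; flair and mask get identical transforms."""
    side = min(s.flair.data.shape)
    if spec.max_shift >= side:
        raise ValidationError(f"max_shift {spec.max_shift} >= smallest dimension {side}")
    if s.flair.data.shape != s.mask.data.shape:
        raise ValidationError("flair and mask must share dimensions before augmentation")
    rng = np.random.default_rng(spec.seed)
    flip_axes = [AXES.index(a) for a in spec.flip_axes]
    out = []
    for i in range(spec.n_per_subject):
        offsets = tuple(int(o) for o in rng.integers(-spec.max_shift, spec.max_shift + 1, 3))
        flips = [a for a in flip_axes if rng.random() < 0.5]
        flair = _shift_zero_fill(s.flair.data, offsets)
        mask = _shift_zero_fill(s.mask.data, offsets)
        if flips:
            flair = np.flip(flair, axis=flips).copy()
            mask = np.flip(mask, axis=flips).copy()
        sid = f"{s.subject_id}_aug{i}"
        out.append(SubjectRecord(
            sid,
            s.flair.with_data(flair, subject_id=sid),
            s.mask.with_data(mask, subject_id=sid),
            s.label,
        ))
    return out


def preprocess_subject(s: SubjectRecord, side: int = 100,
                       background_threshold: float = 0.0) -> SubjectRecord:
    """Crop (kernel from the FLAIR, reused on the mask), resize, normalise."""
    kernel = compute_crop_kernel(s.flair, background_threshold)
    flair = normalize_intensity(resize_to_cube(apply_crop(s.flair, kernel), side))
    mask = resize_to_cube(apply_crop(s.mask, kernel), side)
    return SubjectRecord(s.subject_id, flair, mask, s.label)
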