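"""Volumes, subject records and cohort manifests.

Volumes are rank-3 arrays indexed ``(h, w, l)`` with voxel spacing in mm,
stored as NIfTI-1 (.nii / .nii.gz).  Array axis order is taken exactly as
stored in the file — no reorientation is attempted.  Manifests are UTF-8
CSV files with header ``subject_id,flair_path,mask_path,label``; relative
paths are resolved against the manifest's own directory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ValidationError, VolumeFormatError

MODALITIES = ("flair", "wmh_mask")

#: stored mask values above this are lesion, below are background;
#: segmentation exports vary between {0,1} and {0,255} coding.
MASK_BINARIZE_THRESHOLD = 0.5


@dataclass
class Volume:
    """One subject's intensity or binary-mask volume with spacing metadata."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subject_id: str = ""
    modality: str = "flair"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValidationError(f"volume data must be rank 3, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or min(self.spacing) <= 0:
            raise ValidationError(f"spacing must be 3 positive lengths, got {self.spacing}")
        if self.modality not in MODALITIES:
            raise ValidationError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if self.modality == "wmh_mask":
            vals = np.unique(self.data)
            if not np.isin(vals, (0, 1)).all():
                raise ValidationError("wmh_mask volumes must contain only {0, 1}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, **kw) -> "Volume":
        return replace(self, data=data, **kw)


@dataclass
class SubjectRecord:
    """Paired FLAIR-like volume and lesion mask with a class label."""

    subject_id: str
    flair: Volume
    mask: Volume
    label: str


@dataclass
class Manifest:
    """Ordered cohort table: one row per subject, exactly two class labels."""

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("subject_id", "flair_path", "mask_path", "label")

    def __post_init__(self):
        if len(self.rows):
            missing = [c for c in self.REQUIRED if c not in self.rows.columns]
            if missing:
                raise ValidationError(f"manifest missing columns {missing}")
            ids = self.rows["subject_id"]
            if ids.duplicated().any():
                dupes = sorted(ids[ids.duplicated()].unique())
                raise ValidationError(f"duplicate subject_id values: {dupes}")
            labels = sorted(self.rows["label"].unique())
            if len(labels) > 2:
                raise ValidationError(f"manifest must use at most two labels, got {labels}")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def labels(self) -> list[str]:
        return sorted(self.rows["label"].unique())

    def load_subject(self, subject_id: str) -> SubjectRecord:
        row = self.rows.loc[self.rows["subject_id"] == subject_id]
        if row.empty:
            raise ValidationError(f"subject {subject_id!r} not in manifest")
        row = row.iloc[0]
        flair = read_volume(row["flair_path"], "flair")
        mask = read_volume(row["mask_path"], "wmh_mask")
        flair.subject_id = mask.subject_id = subject_id
        return SubjectRecord(subject_id, flair, mask, row["label"])

    def load_all(self) -> list[SubjectRecord]:
        return [self.load_subject(sid) for sid in self.rows["subject_id"]]


def read_volume(path, modality: str) -> Volume:
    """Read a NIfTI volume; masks are binarized at the stored-value threshold."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected rank-3 data, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if modality == "wmh_mask":
        if data.min() < -1e-6:
            raise ValidationError(f"{path}: mask contains negative values, cannot binarize")
        data = (data > MASK_BINARIZE_THRESHOLD).astype(np.uint8)
    return Volume(data=data, spacing=spacing, modality=modality, subject_id=path.stem.split(".")[0])


def write_volume(v: Volume, path) -> Path:
    """Write a Volume to NIfTI with a diagonal affine carrying the spacing."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    data = v.data
    if v.modality == "wmh_mask":
        data = data.astype(np.uint8)
    affine = np.diag(list(v.spacing) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))
    return path


def read_manifest(path) -> Manifest:
    """Read and validate a cohort CSV; relative paths resolve to its directory."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"manifest not found: {path}")
    rows = pd.read_csv(path, dtype=str)
    missing = [c for c in Manifest.REQUIRED if c not in rows.columns]
    if missing:
        raise ValidationError(f"{path}: manifest missing columns {missing}")
    base = path.parent
    for col in ("flair_path", "mask_path"):
        rows[col] = [str(p) if Path(p).is_absolute() else str(base / p) for p in rows[col]]
    return Manifest(rows=rows.reset_index(drop=True))


def write_manifest(m: Manifest, path) -> Path:
    path = Path(path)
    m.rows.to_csv(path, index=False)
    return path
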