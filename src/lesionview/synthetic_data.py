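"""Two-class synthetic lesion phantoms.

Patient FLAIR/lesion-mask cohorts for the NMOSD-vs-MS problem are not
publicly shareable, so this module generates stand-in subjects with the two
properties that drive the classification task: per-class lesion burden
(normalized lesion volume ≈ 0.66% of intracranial volume for MS vs 0.26%
for NMOSD, with large spread) and partially overlapping spatial
distributions (NMOSD lesions sit preferentially near the ventricles).

Each phantom is an ellipsoidal "brain" with a central ventricle proxy;
lesions are irregular confluent blobs obtained by smoothing a union of
random spheres and thresholding the smoothed field so the lesion voxel
count hits the drawn target exactly.  The lesion-volume fraction is drawn
from a gamma distribution moment-matched to the configured per-class
mean/sd — a zero-truncated normal cannot realise a coefficient of
variation above 1, and both cohorts' spreads exceed their means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GenerationError, ValidationError
from .io_formats import Manifest, SubjectRecord, Volume, write_manifest, write_volume

CLASSES = ("MS", "NMOSD")

#: minimum FLAIR intensity inside the brain, so the brain mask is exactly
#: recoverable as (flair > 0) and lesion fractions are exact identities
_TISSUE_FLOOR = 0.01


@dataclass(frozen=True)
class PhantomParams:
    """Generator configuration.

    ``class_lesion_fraction`` maps class -> (mean, sd) of lesion volume as a
    fraction of brain volume; defaults follow the published cohort burdens
    (MS 0.66% ± 0.65%, NMOSD 0.26% ± 0.37% of intracranial volume).
    ``periventricular_affinity`` in [0, 1] is the probability that a lesion
    seed is placed in the periventricular shell rather than anywhere in the
    white matter; the defaults overlap deliberately, making the default task
    hard, as in the clinical setting.
    """

    side: int = 100
    class_lesion_fraction: dict = field(default_factory=lambda: {
        "MS": (0.0066, 0.0065), "NMOSD": (0.0026, 0.0037)})
    periventricular_affinity: dict = field(default_factory=lambda: {
        "MS": 0.5, "NMOSD": 0.7})
    lesion_count_range: tuple[int, int] = (3, 12)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.side < 16:
            raise ValidationError(f"side must be >= 16, got {self.side}")
        for cls, (m, s) in self.class_lesion_fraction.items():
            if m < 0 or s < 0 or m >= 1:
                raise ValidationError(f"bad lesion fraction for {cls}: mean {m}, sd {s}")
        for cls, a in self.periventricular_affinity.items():
            if not 0.0 <= a <= 1.0:
                raise ValidationError(f"affinity for {cls} must be in [0,1], got {a}")
        if self.lesion_count_range[0] < 1 or self.lesion_count_range[0] > self.lesion_count_range[1]:
            raise ValidationError(f"bad lesion_count_range {self.lesion_count_range}")

    @staticmethod
    def easy(side: int = 100, seed: int = 0) -> "PhantomParams":
        """Strongly separated classes: 10x lesion-load gap and opposite
        spatial affinities.  A sound classifier must find this easy."""
        return PhantomParams(
            side=side,
            class_lesion_fraction={"MS": (0.02, 0.004), "NMOSD": (0.002, 0.0008)},
            periventricular_affinity={"MS": 0.0, "NMOSD": 1.0},
            seed=seed,
        )


@lru_cache(maxsize=4)
def _geometry(side: int):
    """Brain / ventricle / white-matter / periventricular-shell masks."""
    ax = [(np.arange(side) - (side - 1) / 2) / (side / 2) for _ in range(3)]
    u0, u1, u2 = np.meshgrid(*ax, indexing="ij")
    brain = (u0 / 0.90) ** 2 + (u1 / 0.80) ** 2 + (u2 / 0.85) ** 2 <= 1.0
    ventricle = (u0 / 0.12) ** 2 + (u1 / 0.32) ** 2 + (u2 / 0.16) ** 2 <= 1.0
    inner = (u0 / (0.90 * 0.88)) ** 2 + (u1 / (0.80 * 0.88)) ** 2 + (u2 / (0.85 * 0.88)) ** 2 <= 1.0
    wm = inner & ~ventricle
    dist = ndimage.distance_transform_edt(~ventricle)
    shell = wm & (dist <= 0.10 * side)
    return brain, ventricle, wm, shell


def _draw_fraction(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Gamma draw with the requested mean and sd (constant when sd == 0)."""
    if mean == 0:
        return 0.0
    if sd == 0:
        return mean
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return float(rng.gamma(shape, scale))


def generate_phantom(p: PhantomParams, label: str, seed: int) -> SubjectRecord:
    """One synthetic subject: FLAIR-like volume + binary lesion mask."""
    if label not in p.class_lesion_fraction:
        raise ValidationError(f"label {label!r} not configured in class_lesion_fraction")
    rng = np.random.default_rng(seed)
    brain, ventricle, wm, shell = _geometry(p.side)
    brain_n = int(brain.sum())
    wm_idx = np.argwhere(wm)
    shell_idx = np.argwhere(shell)

    mean, sd = p.class_lesion_fraction[label]
    frac = _draw_fraction(rng, mean, sd)
    target = int(round(frac * brain_n))
    if target > wm_idx.shape[0] // 2:
        raise GenerationError(
            f"requested lesion volume ({target} voxels) exceeds half the white matter")

    affinity = p.periventricular_affinity.get(label, 0.5)
    spheres = np.zeros((p.side,) * 3, dtype=np.float32)
    grid = np.indices(spheres.shape, sparse=True)

    def add_blobs(n):
        for _ in range(n):
            pool = shell_idx if rng.random() < affinity else wm_idx
            c = pool[rng.integers(len(pool))]
            r = max(1.5, rng.uniform(0.02, 0.055) * p.side)
            d2 = sum((g - ci) ** 2 for g, ci in zip(grid, c))
            spheres[d2 <= r * r] = 1.0

    mask = np.zeros_like(spheres, dtype=np.uint8)
    if target > 0:
        add_blobs(int(rng.integers(p.lesion_count_range[0], p.lesion_count_range[1] + 1)))
        flat_wm = np.flatnonzero(wm)
        for attempt in range(60):
            field = ndimage.gaussian_filter(spheres, sigma=0.015 * p.side + 0.8)
            field += rng.uniform(0.0, 1e-5, size=field.shape).astype(np.float32)  # tie-break
            vals = field.ravel()[flat_wm]
            eligible = vals > 0.05
            if int(eligible.sum()) >= target:
                break
            add_blobs(2)
        else:
            raise GenerationError(f"could not place {target} lesion voxels")
        scored = np.where(eligible, vals, -np.inf)
        top = np.argpartition(-scored, target - 1)[:target]
        mask.ravel()[flat_wm[top]] = 1

    texture = ndimage.gaussian_filter(
        rng.normal(0.0, 1.0, mask.shape).astype(np.float32), sigma=0.03 * p.side) * 0.3
    flair = np.zeros(mask.shape, dtype=np.float32)
    flair[brain] = 0.55
    flair[ventricle] = 0.18
    flair += texture * brain
    flair[mask == 1] = 0.95
    flair += rng.normal(0.0, p.noise_sd, mask.shape).astype(np.float32) * brain
    flair = np.where(brain, np.maximum(flair, _TISSUE_FLOOR), 0.0).astype(np.float32)

    sid = f"{label}{seed & 0xFFFF:05d}"
    return SubjectRecord(
        sid,
        Volume(flair, subject_id=sid, modality="flair"),
        Volume(mask, subject_id=sid, modality="wmh_mask"),
        label,
    )


def generate_cohort(p: PhantomParams, n_ms: int = 47, n_nmosd: int = 41,
                    seed: int | None = None, out_dir=None
                    ) -> tuple[list[SubjectRecord], Manifest]:
    """A two-class cohort with per-subject seeds derived from the master seed.

    When ``out_dir`` is given, NIfTI pairs and a ``manifest.csv`` are written
    there; otherwise the manifest carries empty path columns and the records
    live in memory only.
    """
    if n_ms < 1 or n_nmosd < 1:
        raise ValidationError("cohort needs at least one subject per class")
    master = p.seed if seed is None else seed
    n_total = n_ms + n_nmosd
    sub_seeds = np.random.SeedSequence(master).generate_state(n_total)
    labels = ["MS"] * n_ms + ["NMOSD"] * n_nmosd
    records, rows = [], []
    for i, label in enumerate(labels):
        sub_seed = int(sub_seeds[i])
        try:
            rec = generate_phantom(p, label, sub_seed)
        except GenerationError as e:
            raise GenerationError(f"subject {label}#{i}: {e}") from e
        rec = replace_id(rec, f"{label}{i:03d}")
        records.append(rec)
        rows.append({"subject_id": rec.subject_id, "flair_path": "", "mask_path": "",
                     "label": label})

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec, row in zip(records, rows):
            row["flair_path"] = str(write_volume(rec.flair, out_dir / f"{rec.subject_id}_flair.nii.gz"))
            row["mask_path"] = str(write_volume(rec.mask, out_dir / f"{rec.subject_id}_mask.nii.gz"))
    manifest = Manifest(rows=pd.DataFrame(rows))
    if out_dir is not None:
        write_manifest(manifest, Path(out_dir) / "manifest.csv")
    return records, manifest


def replace_id(rec: SubjectRecord, new_id: str) -> SubjectRecord:
    return SubjectRecord(
        new_id,
        replace(rec.flair, subject_id=new_id),
        replace(rec.mask, subject_id=new_id),
        rec.label,
    )


def lesion_fraction(rec: SubjectRecord) -> float:
    """Lesion voxels / brain voxels; the brain mask is exactly (flair > 0)."""
    brain_n = int((rec.flair.data > 0).sum())
    return float(rec.mask.data.sum()) / brain_n


def cohort_summary(cohort: list[SubjectRecord]) -> pd.DataFrame:
    """Per-class n, lesion voxel count and lesion fraction (mean ± sd, ddof=0)."""
    if not cohort:
        raise ValidationError("cohort_summary needs a nonempty cohort")
    rows = [{"label": r.label,
             "lesion_voxels": int(r.mask.data.sum()),
             "lesion_fraction": lesion_fraction(r)} for r in cohort]
    df = pd.DataFrame(rows)
    out = df.groupby("label").agg(
        n=("label", "size"),
        lesion_voxels_mean=("lesion_voxels", "mean"),
        lesion_voxels_sd=("lesion_voxels", lambda x: float(np.std(x, ddof=0))),
        lesion_fraction_mean=("lesion_fraction", "mean"),
        lesion_fraction_sd=("lesion_fraction", lambda x: float(np.std(x, ddof=0))),
    )
    return out
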