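"""Reading and writing lesion masks, template spaces and cohort tables.

All volumes live on a single shared template grid.  Inputs are NIfTI-1
volumes (masks, white-matter reference, statistic maps) and RFC-4180 CSV
files with a header row (cohort tables).  No resampling is performed here:
a volume whose grid or affine disagrees with the template space is an
error, not something to be fixed silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

#: absolute per-element tolerance when comparing affines
AFFINE_ATOL = 1e-4

#: default threshold for binarizing fractional (resampled) masks
DEFAULT_BINARIZE_THRESHOLD = 0.5

COHORT_COLUMNS = ("id", "edss", "age", "sex", "duration")


class GridMismatchError(ValueError):
    """A volume does not live on the expected template grid."""


class MaskDataError(ValueError):
    """A volume contains invalid data (non-finite values, ...)."""


class CohortTableError(ValueError):
    """A cohort CSV violates the schema (duplicate ids, bad scores, ...)."""


def _as_binary(arr: np.ndarray, what: str) -> np.ndarray:
    out = np.asarray(arr)
    vals = np.unique(out)
    if not np.all(np.isin(vals, (0, 1))):
        raise MaskDataError(f"{what} must contain only {{0,1}}, found values {vals[:10]}")
    return out.astype(np.uint8)


@dataclass(frozen=True)
class TemplateSpace:
    """The common voxel grid plus the binary white-matter reference mask.

    Parameters
    ----------
    shape : tuple of int
        Grid size along each of the three axes.
    voxel_dims : tuple of float
        Voxel edge lengths in mm.
    affine : (4, 4) ndarray
        Voxel-to-world transform.
    wm_mask : ndarray
        Binary white-matter mask on ``shape``.
    """

    shape: tuple[int, int, int]
    voxel_dims: tuple[float, float, float]
    affine: np.ndarray
    wm_mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        dims = tuple(float(d) for d in self.voxel_dims)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {shape}")
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ValueError(f"voxel_dims must be 3 positive lengths, got {dims}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        wm = _as_binary(self.wm_mask, "wm_mask")
        if wm.shape != shape:
            raise GridMismatchError(
                f"wm_mask shape {wm.shape} does not match template shape {shape}"
            )
        det = abs(float(np.linalg.det(affine[:3, :3])))
        volume = dims[0] * dims[1] * dims[2]
        if not math.isclose(det, volume, rel_tol=1e-3):
            raise ValueError(
                f"voxel volume {volume} mm^3 inconsistent with |det(affine)| = {det}"
            )
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_dims", dims)
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "wm_mask", wm)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        a, b, c = self.voxel_dims
        return a * b * c

    def validate_grid(self, arr: np.ndarray, what: str = "volume") -> None:
        if tuple(arr.shape) != self.shape:
            raise GridMismatchError(
                f"{what} shape {tuple(arr.shape)} does not match template {self.shape}"
            )


def _missing(value: float | None) -> float:
    return math.nan if value is None else float(value)


@dataclass(frozen=True)
class SubjectRecord:
    """One row of the cohort table; NaN encodes a missing value."""

    subject_id: str
    edss: float = math.nan
    age: float = math.nan
    sex: float = math.nan
    duration: float = math.nan

    def __post_init__(self) -> None:
        object.__setattr__(self, "subject_id", str(self.subject_id))
        for name in ("edss", "age", "sex", "duration"):
            object.__setattr__(self, name, _missing(getattr(self, name)))
        if not math.isnan(self.edss):
            if not (0.0 <= self.edss <= 10.0):
                raise CohortTableError(
                    f"subject {self.subject_id}: EDSS {self.edss} outside [0, 10]"
                )
            if not math.isclose(round(self.edss * 2) / 2, self.edss, abs_tol=1e-9):
                raise CohortTableError(
                    f"subject {self.subject_id}: EDSS {self.edss} is not a half-point multiple"
                )
        if not math.isnan(self.age) and self.age < 0:
            raise CohortTableError(f"subject {self.subject_id}: negative age {self.age}")
        if not math.isnan(self.duration) and self.duration < 0:
            raise CohortTableError(
                f"subject {self.subject_id}: negative duration {self.duration}"
            )
        if not math.isnan(self.sex) and self.sex not in (0.0, 1.0):
            raise CohortTableError(
                f"subject {self.subject_id}: sex must be 0/1, got {self.sex}"
            )


@dataclass
class LesionCohort:
    """Per-subject binary lesion masks on a shared template grid.

    ``masks[i]`` is the binary lesion mask of ``subjects[i]``; the cohort is
    tagged with the registration that produced the masks.
    """

    space: TemplateSpace
    subjects: tuple[SubjectRecord, ...]
    masks: np.ndarray
    registration_label: str = "original"

    def __post_init__(self) -> None:
        self.subjects = tuple(self.subjects)
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortTableError(f"duplicate subject ids: {dupes}")
        masks = np.asarray(self.masks)
        if masks.ndim != 4 or masks.shape[0] != len(self.subjects):
            raise GridMismatchError(
                f"expected one mask per subject ({len(self.subjects)}), got array of "
                f"shape {masks.shape}"
            )
        if tuple(masks.shape[1:]) != self.space.shape:
            raise GridMismatchError(
                f"mask grid {tuple(masks.shape[1:])} does not match template "
                f"{self.space.shape}"
            )
        self.masks = _as_binary(masks, "lesion masks")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(s.subject_id for s in self.subjects)

    def mask_for(self, subject_id: str) -> np.ndarray:
        idx = self.subject_ids.index(subject_id)
        return self.masks[idx]

    def relabel(self, registration_label: str) -> "LesionCohort":
        return LesionCohort(self.space, self.subjects, self.masks.copy(), registration_label)


# ---------------------------------------------------------------------------
# I/O operations
# ---------------------------------------------------------------------------

def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume, returning ``(data, affine)``."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), np.asarray(img.affine, dtype=float)


def read_mask(
    path: str | Path,
    space: TemplateSpace,
    binarize_threshold: float = DEFAULT_BINARIZE_THRESHOLD,
) -> np.ndarray:
    """Read a (possibly fractional) mask and binarize it onto the template grid.

    Values strictly greater than ``binarize_threshold`` map to 1.  The grid
    and affine must match the template space.
    """
    data, affine = read_volume(path)
    space.validate_grid(data, what=str(path))
    if not np.allclose(affine, space.affine, atol=AFFINE_ATOL, rtol=0.0):
        raise GridMismatchError(
            f"{path}: affine differs from template beyond tolerance {AFFINE_ATOL}"
        )
    if not np.all(np.isfinite(data)):
        raise MaskDataError(f"{path}: mask contains non-finite voxels")
    return (data > binarize_threshold).astype(np.uint8)


def read_template_space(
    wm_path: str | Path, binarize_threshold: float = DEFAULT_BINARIZE_THRESHOLD
) -> TemplateSpace:
    """Build a :class:`TemplateSpace` from a white-matter mask volume."""
    data, affine = read_volume(wm_path)
    if data.ndim != 3:
        raise GridMismatchError(f"{wm_path}: expected a 3-D volume, got ndim={data.ndim}")
    if not np.all(np.isfinite(data)):
        raise MaskDataError(f"{wm_path}: WM mask contains non-finite voxels")
    voxel_dims = tuple(float(d) for d in nib.affines.voxel_sizes(affine))
    wm = (data > binarize_threshold).astype(np.uint8)
    return TemplateSpace(tuple(data.shape), voxel_dims, affine, wm)


def read_cohort(path: str | Path) -> list[SubjectRecord]:
    """Parse a cohort CSV (columns id, edss, age, sex, duration).

    Empty cells are preserved as missing values; nothing is imputed.
    """
    df = pd.read_csv(path, dtype={"id": str})
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortTableError(f"{path}: missing columns {missing_cols}")
    if df["id"].duplicated().any():
        dupes = sorted(df.loc[df["id"].duplicated(), "id"].unique())
        raise CohortTableError(f"{path}: duplicate subject ids {dupes}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SubjectRecord(
                subject_id=row.id,
                edss=_nan_if_empty(row.edss),
                age=_nan_if_empty(row.age),
                sex=_nan_if_empty(row.sex),
                duration=_nan_if_empty(row.duration),
            )
        )
    return records


def _nan_if_empty(value) -> float:
    if value is None or (isinstance(value, str) and value.strip() == ""):
        return math.nan
    return float(value)


def write_cohort(records: Sequence[SubjectRecord], path: str | Path) -> None:
    """Write subject records back to CSV with empty cells for missing values."""
    df = pd.DataFrame(
        {
            "id": [r.subject_id for r in records],
            "edss": [r.edss for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "duration": [r.duration for r in records],
        }
    )
    df.to_csv(path, index=False)


def write_map(arr: np.ndarray, space: TemplateSpace, path: str | Path) -> None:
    """Write a 3-D map on the template grid as NIfTI, preserving NaN voxels."""
    data = np.asarray(arr)
    space.validate_grid(data, what="map")
    if data.dtype == np.bool_:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, space.affine)
    nib.save(img, str(path))
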