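"""Per-subject lesion metrics: TLV, GLSR and the location-discrepancy index.

GLSR (goodness of lesion spatial registration) is the proportion of a
subject's lesion voxels that fall outside template white matter after
registration: 0 means every lesion voxel landed in WM, 1 means none did.
The LDI (location-discrepancy index) is the fraction of a subject's lesion
voxels that are "rare" in the cohort — shared with at most ``rarity_k``
other subjects — so large values flag atypical lesion patterns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .mask_io import LesionCohort, TemplateSpace
from .prevalence import PrevalenceMap


@dataclass(frozen=True)
class GLSRRecord:
    subject_id: str
    registration_label: str
    glsr: float  # NaN iff denominator is 0
    lesion_voxels_registered: int
    lesion_voxels_native: int | None = None

    def __post_init__(self) -> None:
        if not math.isnan(self.glsr) and not 0.0 <= self.glsr <= 1.0:
            raise ValueError(f"GLSR {self.glsr} outside [0, 1]")


@dataclass(frozen=True)
class GLSRSummary:
    registration_label: str
    mean: float
    median: float
    sd: float  # sample SD, denominator n - 1
    mse: float  # mean of squared per-subject GLSR (truth is GLSR = 0)
    mean_rank: float
    n: int


@dataclass(frozen=True)
class LDIResult:
    subject_id: str
    rare_voxels: int
    tlv_voxels: int
    tlv_mm3: float
    ldi: float  # NaN iff TLV is 0

    def __post_init__(self) -> None:
        if not 0 <= self.rare_voxels <= max(self.tlv_voxels, 0):
            raise ValueError("rare_voxels must lie in [0, tlv_voxels]")
        if not math.isnan(self.ldi) and not 0.0 <= self.ldi <= 1.0:
            raise ValueError(f"LDI {self.ldi} outside [0, 1]")


def tlv(mask: np.ndarray, space: TemplateSpace) -> tuple[int, float]:
    """Total lesion volume: (voxel count, volume in mm^3)."""
    space.validate_grid(np.asarray(mask), what="lesion mask")
    count = int(np.count_nonzero(mask))
    return count, count * space.voxel_volume


def glsr(
    registered_mask: np.ndarray,
    space: TemplateSpace,
    subject_id: str = "",
    registration_label: str = "",
    denominator: str = "registered",
    native_voxels: int | None = None,
) -> GLSRRecord:
    """Proportion of lesion voxels outside template white matter.

    ``denominator`` selects the reference lesion-voxel count: the mask in
    template space (``"registered"``, default) or the supplied native-space
    count (``"native"``).  A zero denominator yields a flagged (NaN) record
    rather than an error — empty masks carry no registration information.
    """
    space.validate_grid(np.asarray(registered_mask), what="registered mask")
    mask = np.asarray(registered_mask).astype(bool)
    registered_count = int(mask.sum())
    outside = int(np.count_nonzero(mask & (space.wm_mask == 0)))
    if denominator == "registered":
        denom = registered_count
    elif denominator == "native":
        if native_voxels is None or native_voxels <= 0:
            raise ValueError("denominator='native' requires native_voxels > 0")
        denom = int(native_voxels)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    value = outside / denom if denom > 0 else math.nan
    if not math.isnan(value):
        value = min(value, 1.0)  # native denominators can be exceeded by dilation
    return GLSRRecord(
        subject_id=subject_id,
        registration_label=registration_label,
        glsr=value,
        lesion_voxels_registered=registered_count,
        lesion_voxels_native=native_voxels,
    )


def glsr_table(cohort: LesionCohort, denominator: str = "registered") -> list[GLSRRecord]:
    """GLSR records for every subject of one registered cohort."""
    return [
        glsr(
            cohort.masks[i],
            cohort.space,
            subject_id=rec.subject_id,
            registration_label=cohort.registration_label,
            denominator=denominator,
        )
        for i, rec in enumerate(cohort.subjects)
    ]


def glsr_matrix(records: list[GLSRRecord]) -> pd.DataFrame:
    """Pivot GLSR records into a subjects x registrations table."""
    df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "registration_label": [r.registration_label for r in records],
            "glsr": [r.glsr for r in records],
        }
    )
    return df.pivot(index="subject_id", columns="registration_label", values="glsr")


def mse_from_mean_sd(mean: float, sd: float) -> float:
    """Reconstruct the cohort MSE of GLSR from printed summary statistics.

    With truth GLSR = 0 the mean squared error decomposes into squared mean
    plus squared spread; for published tables where only rounded mean/SD are
    available this is the standard consistency reconstruction.
    """
    return mean * mean + sd * sd


def summarize_glsr(
    registration_label: str,
    table: pd.DataFrame,
) -> GLSRSummary:
    """Cohort summary of GLSR for one registration.

    ``table`` is a subjects x registrations matrix (see :func:`glsr_matrix`);
    the extra columns are needed for the mean rank, the average over
    subjects of the within-subject rank of this registration (rank 1 =
    smallest GLSR, ties get average ranks).
    """
    if registration_label not in table.columns:
        raise KeyError(f"no GLSR column for registration {registration_label!r}")
    col = table[registration_label].dropna()
    if len(col) < 2:
        raise ValueError("need at least 2 subjects to summarize GLSR")
    values = col.to_numpy(dtype=float)
    complete = table.dropna(axis=0, how="any")
    if complete.empty:
        raise ValueError("no subject has GLSR defined for all registrations")
    ranks = rankdata(complete.to_numpy(dtype=float), axis=1)
    mean_rank = float(ranks[:, list(complete.columns).index(registration_label)].mean())
    return GLSRSummary(
        registration_label=registration_label,
        mean=float(values.mean()),
        median=float(np.median(values)),
        sd=float(values.std(ddof=1)),
        mse=float(np.mean(values**2)),
        mean_rank=mean_rank,
        n=len(values),
    )


def glsr_summary_table(table: pd.DataFrame) -> pd.DataFrame:
    """Summaries for every registration, one row per label."""
    rows = [summarize_glsr(label, table) for label in table.columns]
    out = pd.DataFrame(
        {
            "registration_label": [r.registration_label for r in rows],
            "mean": [r.mean for r in rows],
            "median": [r.median for r in rows],
            "sd": [r.sd for r in rows],
            "mse": [r.mse for r in rows],
            "mean_rank": [r.mean_rank for r in rows],
            "n": [r.n for r in rows],
        }
    )
    return out.set_index("registration_label")


def default_rarity_k(n_subjects: int, fraction: float = 0.05) -> int:
    """Default rarity threshold: ceil(fraction * (n - 1)) other subjects."""
    return int(math.ceil(fraction * (n_subjects - 1)))


def ldi(
    cohort: LesionCohort,
    prev: PrevalenceMap,
    rarity_k: int | None = None,
) -> list[LDIResult]:
    """Location-discrepancy index for every subject.

    A lesion voxel of subject i is *rare* when no more than ``rarity_k``
    *other* subjects carry a lesion there; LDI = rare voxels / TLV.  Subjects
    with empty masks get a NaN LDI.
    """
    if prev.n_subjects != cohort.n_subjects:
        raise ValueError("prevalence map was not computed from this cohort")
    if prev.counts.shape != cohort.space.shape:
        raise ValueError("prevalence map grid does not match the cohort template")
    if int(prev.counts.sum()) != int(cohort.masks.sum()):
        raise ValueError("prevalence counts are inconsistent with the cohort masks")
    if rarity_k is None:
        rarity_k = default_rarity_k(cohort.n_subjects)
    if rarity_k < 0:
        raise ValueError("rarity_k must be >= 0")

    results = []
    for i, rec in enumerate(cohort.subjects):
        mask = cohort.masks[i].astype(bool)
        count, mm3 = tlv(cohort.masks[i], cohort.space)
        # self excluded: counts includes subject i wherever mask is 1
        rare = int(np.count_nonzero(mask & (prev.counts - 1 <= rarity_k)))
        value = rare / count if count > 0 else math.nan
        results.append(
            LDIResult(
                subject_id=rec.subject_id,
                rare_voxels=rare,
                tlv_voxels=count,
                tlv_mm3=mm3,
                ldi=value,
            )
        )
    return results


def subject_metrics(
    cohort: LesionCohort,
    prev: PrevalenceMap,
    rarity_k: int | None = None,
) -> pd.DataFrame:
    """Per-subject TLV/LDI table indexed by subject id (model covariates)."""
    rows = ldi(cohort, prev, rarity_k=rarity_k)
    return pd.DataFrame(
        {
            "tlv_voxels": [r.tlv_voxels for r in rows],
            "tlv_mm3": [r.tlv_mm3 for r in rows],
            "rare_voxels": [r.rare_voxels for r in rows],
            "ldi": [r.ldi for r in rows],
        },
        index=pd.Index([r.subject_id for r in rows], name="subject_id"),
    )
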