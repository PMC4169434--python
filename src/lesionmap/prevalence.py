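"""Lesion prevalence maps (3-D lesion histograms) and the analysis mask."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mask_io import LesionCohort


@dataclass(frozen=True)
class PrevalenceMap:
    """Per-voxel count of subjects with a lesion at that voxel."""

    counts: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.min(initial=0) < 0 or counts.max(initial=0) > self.n_subjects:
            raise ValueError("counts must lie in [0, n_subjects]")
        object.__setattr__(self, "counts", counts.astype(np.int32))

    @property
    def proportions(self) -> np.ndarray:
        """Counts divided by cohort size (derived view, not stored)."""
        return self.counts / float(self.n_subjects)


def lesion_count_map(cohort: LesionCohort) -> PrevalenceMap:
    """Count, at every voxel, how many subjects carry a lesion there."""
    if cohort.n_subjects == 0:
        raise ValueError("cannot build a prevalence map from an empty cohort")
    counts = cohort.masks.sum(axis=0, dtype=np.int32)
    return PrevalenceMap(counts=counts, n_subjects=cohort.n_subjects)


def analysis_mask(prev: PrevalenceMap, min_subjects: int) -> np.ndarray:
    """Voxels with *more than* ``min_subjects`` lesion carriers (strict).

    The returned binary mask is the domain of all voxel-wise testing; its
    sum is the number of tests performed.
    """
    if not 0 <= min_subjects < prev.n_subjects:
        raise ValueError(
            f"min_subjects must lie in [0, {prev.n_subjects}), got {min_subjects}"
        )
    return (prev.counts > min_subjects).astype(np.uint8)
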