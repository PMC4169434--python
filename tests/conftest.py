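import numpy as np
import pytest

from lesionmap import LesionCohort, SubjectRecord, TemplateSpace


@pytest.fixture
def unit_space():
    """8^3 grid, 1 mm isotropic, WM everywhere."""
    shape = (8, 8, 8)
    return TemplateSpace(
        shape=shape,
        voxel_dims=(1.0, 1.0, 1.0),
        affine=np.eye(4),
        wm_mask=np.ones(shape, dtype=np.uint8),
    )


@pytest.fixture
def shell_space():
    """10^3 grid whose WM is a border-free box with a 2^3 'ventricle' hole."""
    shape = (10, 10, 10)
    wm = np.zeros(shape, dtype=np.uint8)
    wm[1:9, 1:9, 1:9] = 1
    wm[4:6, 4:6, 4:6] = 0
    return TemplateSpace(
        shape=shape, voxel_dims=(1.0, 1.0, 1.0), affine=np.eye(4), wm_mask=wm
    )


def make_cohort(space, masks, edss=None, label="original", **covs):
    """Assemble a cohort from explicit masks and per-subject covariates."""
    masks = np.asarray(masks, dtype=np.uint8)
    n = masks.shape[0]
    edss = [np.nan] * n if edss is None else edss
    age = covs.get("age", [40.0] * n)
    sex = covs.get("sex", [0.0] * n)
    duration = covs.get("duration", [5.0] * n)
    subjects = tuple(
        SubjectRecord(
            subject_id=f"s{i+1}",
            edss=edss[i],
            age=age[i],
            sex=sex[i],
            duration=duration[i],
        )
        for i in range(n)
    )
    return LesionCohort(space=space, subjects=subjects, masks=masks, registration_label=label)


@pytest.fixture
def toy_cohort(unit_space):
    """3 subjects with overlapping hand-placed lesions."""
    masks = np.zeros((3, 8, 8, 8), dtype=np.uint8)
    masks[0, 2:4, 2:4, 2] = 1  # 4 voxels
    masks[1, 3:5, 2:4, 2] = 1  # overlaps subject 0 at 2 voxels
    masks[2, 3, 3, 2] = 1  # single voxel shared by all three
    masks[0, 3, 3, 2] = 1
    masks[1, 3, 3, 2] = 1
    return make_cohort(unit_space, masks, edss=[2.0, 4.5, 6.0])
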