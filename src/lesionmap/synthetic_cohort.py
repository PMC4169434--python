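"""Synthetic template spaces and lesion-mask cohorts.

The generator produces everything the analysis modules consume without any
external data: an ellipsoidal-shell "white matter" template around an inner
"ventricle", spatially clustered lesions whose center intensity peaks next
to the ventricle, subject covariates with configurable marginals, a
disability score driven by a linear effect specification, and
misregistration perturbations (translation, dilation/erosion, scaling)
that mimic the failure modes of real registration pipelines: lesions
displaced out of white matter and lesion-volume inflation.

Everything is reproducible from the seed in the configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .mask_io import LesionCohort, SubjectRecord, TemplateSpace


@dataclass(frozen=True)
class EffectSpec:
    """Linear generative model for the disability score.

    ``n_effect_voxels`` white-matter voxels nearest to ``effect_center``
    form the effect region; a subject carries it with probability
    ``carrier_prob`` and carriers get the region added to their mask, so the
    per-voxel lesion indicator at effect voxels equals the carrier flag.
    """

    n_effect_voxels: int = 0
    effect_center: tuple[int, int, int] | None = None
    carrier_prob: float = 0.5
    intercept: float = 3.5
    beta_lesion: float = 0.0
    beta_tlv: float = 0.0
    beta_age: float = 0.0
    beta_sex: float = 0.0
    beta_duration: float = 0.0
    noise_sd: float = 2.0
    #: "rounded_gaussian" (clip to [0,10], round to 0.5) or "latent_ordinal"
    #: (logistic latent variable cut into 3 representative scores)
    edss_mode: str = "rounded_gaussian"
    latent_cutpoints: tuple[float, ...] = (0.0, 1.5)

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0.0 <= self.carrier_prob <= 1.0:
            raise ValueError("carrier_prob must lie in [0, 1]")
        if self.edss_mode not in ("rounded_gaussian", "latent_ordinal"):
            raise ValueError(f"unknown edss_mode {self.edss_mode!r}")


@dataclass(frozen=True)
class SimConfig:
    """Full description of one simulated cohort (defaults mimic n=98 study)."""

    n_subjects: int = 98
    shape: tuple[int, int, int] = (32, 32, 32)
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)
    outer_semiaxes: tuple[float, float, float] = (14.0, 14.0, 14.0)
    inner_semiaxes: tuple[float, float, float] = (5.0, 5.0, 5.0)
    periventricular_rate: float = 20.0
    background_rate: float = 1.0
    decay_mm: float = 3.0
    mean_lesions: float = 8.0
    lesion_radius_range: tuple[float, float] = (1.0, 2.5)
    age_mean: float = 43.5
    age_sd: float = 12.5
    duration_mean: float = 11.4
    duration_sd: float = 9.2
    female_frac: float = 0.7  # placeholder; keep configurable
    edss_missing_frac: float = 7.0 / 98.0
    effect: EffectSpec = field(default_factory=EffectSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.periventricular_rate < 0 or self.background_rate < 0:
            raise ValueError("rates must be >= 0")
        if any(
            i >= o for i, o in zip(self.inner_semiaxes, self.outer_semiaxes) if i > 0
        ):
            raise ValueError("inner ellipsoid must lie strictly inside the outer one")
        if self.lesion_radius_range[0] > self.lesion_radius_range[1]:
            raise ValueError("lesion_radius_range must be (low, high)")


def _ellipsoid(shape: Sequence[int], semiaxes: Sequence[float]) -> np.ndarray:
    """Boolean membership of the ellipsoid centered at the grid midpoint."""
    semiaxes = np.asarray(semiaxes, dtype=float)
    if np.all(semiaxes == 0):
        return np.zeros(tuple(shape), dtype=bool)
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    rho2 = sum(
        ((g - c) / max(a, 1e-12)) ** 2 for g, c, a in zip(grids, center, semiaxes)
    )
    return rho2 <= 1.0


def make_template(config: SimConfig) -> TemplateSpace:
    """Ellipsoidal-shell WM template: outer ellipsoid minus inner ventricle."""
    outer = _ellipsoid(config.shape, config.outer_semiaxes)
    inner = _ellipsoid(config.shape, config.inner_semiaxes)
    wm = outer & ~inner
    if not wm.any():
        raise ValueError("infeasible geometry: white-matter shell is empty")
    affine = np.diag((*config.voxel_dims, 1.0))
    return TemplateSpace(
        shape=tuple(config.shape),
        voxel_dims=tuple(config.voxel_dims),
        affine=affine,
        wm_mask=wm.astype(np.uint8),
    )


def periventricular_intensity(space: TemplateSpace, config: SimConfig) -> np.ndarray:
    """Unnormalized lesion-center intensity on WM, peaked next to the ventricle."""
    center = (np.asarray(space.shape, dtype=float) - 1.0) / 2.0
    grids = np.ogrid[tuple(slice(0, s) for s in space.shape)]
    inner = np.asarray(config.inner_semiaxes, dtype=float)
    dims = np.asarray(space.voxel_dims, dtype=float)
    if np.all(inner == 0):
        dist_mm = np.sqrt(sum(((g - c) * d) ** 2 for g, c, d in zip(grids, center, dims)))
    else:
        rho = np.sqrt(
            sum(((g - c) / max(a, 1e-12)) ** 2 for g, c, a in zip(grids, center, inner))
        )
        mean_radius_mm = float(np.mean(inner * dims))
        dist_mm = np.clip(rho - 1.0, 0.0, None) * mean_radius_mm
    w = config.background_rate + config.periventricular_rate * np.exp(
        -dist_mm / config.decay_mm
    )
    w = w * (space.wm_mask > 0)
    # np.ogrid broadcasting gives full shape only after the multiplication
    return np.ascontiguousarray(np.broadcast_to(w, space.shape))


def _ball_offsets(radius: float) -> np.ndarray:
    r = int(math.floor(radius))
    rng = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(rng, rng, rng, indexing="ij")
    keep = dx * dx + dy * dy + dz * dz <= radius * radius
    return np.stack([dx[keep], dy[keep], dz[keep]], axis=1)


def effect_region(space: TemplateSpace, config: SimConfig) -> np.ndarray:
    """Boolean mask of the effect voxels: nearest WM voxels to the center.

    The default center sits midway through the WM shell on the +x axis, a
    "periventricular" location.  Ties in distance break lexicographically,
    so the region is deterministic.
    """
    eff = config.effect
    if eff.n_effect_voxels <= 0:
        return np.zeros(space.shape, dtype=bool)
    if eff.effect_center is None:
        cx, cy, cz = ((s - 1) / 2.0 for s in space.shape)
        x = cx + (config.inner_semiaxes[0] + config.outer_semiaxes[0]) / 2.0
        center = (int(round(x)), int(round(cy)), int(round(cz)))
    else:
        center = tuple(int(c) for c in eff.effect_center)
    wm_idx = np.argwhere(space.wm_mask > 0)
    d2 = ((wm_idx - np.asarray(center)) ** 2).sum(axis=1)
    order = np.lexsort((wm_idx[:, 2], wm_idx[:, 1], wm_idx[:, 0], d2))
    chosen = wm_idx[order[: eff.n_effect_voxels]]
    if len(chosen) < eff.n_effect_voxels:
        raise ValueError("not enough WM voxels for the requested effect region")
    region = np.zeros(space.shape, dtype=bool)
    region[tuple(chosen.T)] = True
    return region


def _paint_lesions(
    mask: np.ndarray,
    centers: np.ndarray,
    radii: np.ndarray,
    shape: tuple[int, int, int],
) -> None:
    for center, radius in zip(centers, radii):
        off = _ball_offsets(radius)
        pts = off + center
        keep = np.all((pts >= 0) & (pts < np.asarray(shape)), axis=1)
        pts = pts[keep]
        mask[pts[:, 0], pts[:, 1], pts[:, 2]] = 1


def _round_half(x: np.ndarray) -> np.ndarray:
    return np.round(np.asarray(x) * 2.0) / 2.0


#: representative score for each latent ordinal category (low / mid / high)
_ORDINAL_SCORES = (3.0, 5.0, 6.5)


def simulate_cohort(
    space: TemplateSpace,
    config: SimConfig,
    seed: int | None = None,
    registration_label: str = "original",
) -> LesionCohort:
    """Draw a full cohort: masks, covariates and disability scores.

    Lesion centers are sampled from the periventricular intensity field,
    grown as spheres and clipped to WM.  The score is generated from the
    linear effect specification plus noise, clipped to [0, 10] and rounded
    to the half-point grid (or produced through a latent logistic ordinal
    process when ``edss_mode='latent_ordinal'``), then thinned by the
    configured missingness fraction.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_subjects
    eff = config.effect

    weights = periventricular_intensity(space, config)
    total = weights.sum()
    region = effect_region(space, config)
    if eff.n_effect_voxels > 0 and total == 0:
        raise ValueError("zero-rate intensity field with effect voxels requested")
    wm_flat = np.flatnonzero(weights.ravel() > 0)
    probs = weights.ravel()[wm_flat]
    probs = probs / probs.sum() if probs.size else probs

    age = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 0.0, None)
    sex = (rng.random(n) < config.female_frac).astype(float)
    duration = np.clip(
        rng.normal(config.duration_mean, config.duration_sd, size=n), 0.0, None
    )
    carriers = (
        rng.random(n) < eff.carrier_prob if eff.n_effect_voxels > 0 else np.zeros(n, bool)
    )

    masks = np.zeros((n, *space.shape), dtype=np.uint8)
    shape = space.shape
    for i in range(n):
        n_lesions = rng.poisson(config.mean_lesions)
        if n_lesions > 0 and probs.size:
            flat_centers = rng.choice(wm_flat, size=n_lesions, p=probs)
            centers = np.column_stack(np.unravel_index(flat_centers, shape))
            radii = rng.uniform(*config.lesion_radius_range, size=n_lesions)
            _paint_lesions(masks[i], centers, radii, shape)
        masks[i] &= space.wm_mask  # lesions clipped to WM
        if eff.n_effect_voxels > 0:
            # the effect region is controlled by the carrier flag alone, so
            # the per-voxel lesion indicator there equals the carrier flag
            masks[i][region] = 1 if carriers[i] else 0

    tlv_mm3 = masks.reshape(n, -1).sum(axis=1) * space.voxel_volume
    predictor = (
        eff.intercept
        + eff.beta_lesion * carriers.astype(float)
        + eff.beta_tlv * tlv_mm3
        + eff.beta_age * age
        + eff.beta_sex * sex
        + eff.beta_duration * duration
    )
    if eff.edss_mode == "latent_ordinal":
        latent = predictor + rng.logistic(0.0, 1.0, size=n)
        cats = np.zeros(n, dtype=int)
        for c in eff.latent_cutpoints:
            cats += (latent >= c).astype(int)
        edss = np.asarray(_ORDINAL_SCORES)[np.clip(cats, 0, len(_ORDINAL_SCORES) - 1)]
    else:
        edss = _round_half(np.clip(predictor + rng.normal(0.0, eff.noise_sd, size=n), 0, 10))
    n_missing = int(round(config.edss_missing_frac * n))
    if n_missing > 0:
        gone = rng.choice(n, size=n_missing, replace=False)
        edss = edss.astype(float)
        edss[gone] = np.nan

    subjects = tuple(
        SubjectRecord(
            subject_id=f"s{i+1:03d}",
            edss=float(edss[i]),
            age=float(age[i]),
            sex=float(sex[i]),
            duration=float(duration[i]),
        )
        for i in range(n)
    )
    return LesionCohort(
        space=space, subjects=subjects, masks=masks, registration_label=registration_label
    )


# ---------------------------------------------------------------------------
# misregistration perturbations
# ---------------------------------------------------------------------------

_PERTURB_MODES = ("translate", "dilate", "erode", "scale")


def _translate_mask(mask: np.ndarray, shift: Sequence[int]) -> np.ndarray:
    out = np.zeros_like(mask)
    src = []
    dst = []
    for s, size in zip(shift, mask.shape):
        s = int(s)
        if abs(s) >= size:
            return out
        if s >= 0:
            src.append(slice(0, size - s))
            dst.append(slice(s, size))
        else:
            src.append(slice(-s, size))
            dst.append(slice(0, size + s))
    out[tuple(dst)] = mask[tuple(src)]
    return out


def _scale_mask(mask: np.ndarray, factor: float) -> np.ndarray:
    """Zoom about the grid center and re-binarize at 0.5."""
    center = (np.asarray(mask.shape, dtype=float) - 1.0) / 2.0
    matrix = np.eye(3) / factor
    offset = center - matrix @ center
    warped = ndimage.affine_transform(
        mask.astype(float), matrix, offset=offset, order=1, mode="constant", cval=0.0
    )
    return (warped > 0.5).astype(np.uint8)


def perturb_registration(
    cohort: LesionCohort,
    mode: str,
    magnitude: float | Sequence[int],
    seed: int | None = None,
    registration_label: str | None = None,
) -> LesionCohort:
    """Emulate a misregistration by transforming every lesion mask.

    Modes: integer-voxel ``translate`` (scalar = shift along x, or a 3-vector;
    with a seed, per-subject random shifts uniform in [-m, m] per axis),
    morphological ``dilate``/``erode`` with a ball of the given radius, and
    center ``scale`` by the given factor with re-binarization.  A translation
    that pushes any non-empty mask fully off-grid is an error.
    """
    if mode not in _PERTURB_MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {_PERTURB_MODES}")
    masks = cohort.masks
    n = cohort.n_subjects
    out = np.zeros_like(masks)

    if mode == "translate":
        if seed is not None and np.isscalar(magnitude):
            rng = np.random.default_rng(seed)
            m = int(magnitude)
            shifts = rng.integers(-m, m + 1, size=(n, 3))
        else:
            vec = (
                (int(magnitude), 0, 0)
                if np.isscalar(magnitude)
                else tuple(int(v) for v in magnitude)
            )
            shifts = np.tile(vec, (n, 1))
        for i in range(n):
            out[i] = _translate_mask(masks[i], shifts[i])
            if masks[i].any() and not out[i].any():
                raise ValueError(
                    f"translation {tuple(shifts[i])} pushes subject "
                    f"{cohort.subjects[i].subject_id}'s mask fully off-grid"
                )
    elif mode in ("dilate", "erode"):
        radius = float(magnitude)
        structure = np.zeros((3, 3, 3), dtype=bool)
        off = _ball_offsets(min(radius, 1.0)) + 1
        structure[off[:, 0], off[:, 1], off[:, 2]] = True
        iterations = max(int(round(radius)), 1)
        op = ndimage.binary_dilation if mode == "dilate" else ndimage.binary_erosion
        for i in range(n):
            out[i] = op(masks[i], structure=structure, iterations=iterations)
    else:  # scale
        factor = float(magnitude)
        if factor <= 0:
            raise ValueError("scale factor must be > 0")
        for i in range(n):
            out[i] = _scale_mask(masks[i], factor)

    label = registration_label or f"{cohort.registration_label}+{mode}{magnitude}"
    return LesionCohort(
        space=cohort.space, subjects=cohort.subjects, masks=out, registration_label=label
    )


def with_effect(config: SimConfig, **effect_kwargs) -> SimConfig:
    """Convenience: a copy of ``config`` with updated effect parameters."""
    return replace(config, effect=replace(config.effect, **effect_kwargs))
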