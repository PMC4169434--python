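"""Mass-univariate regression of disability on voxel-wise lesion presence.

The model ledger M1-M5 regresses the disability score on the per-voxel
lesion indicator with a growing set of confounders:

    M1: lesion
    M2: lesion + TLV
    M3: lesion + LDI
    M4: lesion + age + sex + duration
    M5: lesion + TLV + LDI + age + sex + duration

Every voxel in the analysis mask gets an OLS fit with independent
homoscedastic errors; only the lesion-indicator column changes between
voxels, so the fits are vectorized through the Frisch-Waugh-Lovell
partition: residualize the outcome and the lesion columns against the
confounders once, then each voxel's slope/SE/t/p follows from scalar
cross-products.  This is algebraically identical to a per-voxel
normal-equations solve (the unit tests check this to 1e-8).

Also here: Bonferroni and Benjamini-Hochberg corrections, the sample-size
extrapolation that rescales standard errors by sqrt(n_target/n_actual),
the proportional-odds (cumulative logit) ordinal variant, and simple
cohort-level regressions (disability ~ TLV, disability ~ LDI).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .mask_io import LesionCohort

MODEL_COVARIATES: dict[str, tuple[str, ...]] = {
    "M1": ("lesion",),
    "M2": ("lesion", "tlv"),
    "M3": ("lesion", "ldi"),
    "M4": ("lesion", "age", "sex", "duration"),
    "M5": ("lesion", "tlv", "ldi", "age", "sex", "duration"),
}

DEFAULT_ORDINAL_CUTPOINTS = (4.0, 6.0)

#: confounders read from the metrics table rather than the cohort table
_METRIC_COLUMNS = {"tlv": "tlv_mm3", "ldi": "ldi"}

#: voxels whose residualized lesion column has smaller sum of squares are
#: treated as rank-deficient (lesion collinear with a confounder)
_RANK_TOL = 1e-10

#: coefficient norm beyond which an ordinal fit is declared separated
_SEPARATION_NORM = 1e3


class DegenerateDesignError(ValueError):
    """The design matrix cannot support the requested fit."""


@dataclass(frozen=True)
class ModelSpec:
    """One entry of the model ledger."""

    name: str
    covariates: tuple[str, ...]
    outcome_mode: str = "continuous"
    ordinal_cutpoints: tuple[float, ...] = DEFAULT_ORDINAL_CUTPOINTS

    def __post_init__(self) -> None:
        if "lesion" not in self.covariates:
            raise ValueError("the lesion indicator is always part of the model")
        if self.outcome_mode not in ("continuous", "ordinal"):
            raise ValueError(f"unknown outcome_mode {self.outcome_mode!r}")
        if tuple(sorted(self.ordinal_cutpoints)) != tuple(self.ordinal_cutpoints):
            raise ValueError("ordinal cutpoints must be ascending")

    @classmethod
    def preset(cls, name: str, outcome_mode: str = "continuous") -> "ModelSpec":
        if name not in MODEL_COVARIATES:
            raise KeyError(f"unknown model {name!r}; presets are {sorted(MODEL_COVARIATES)}")
        return cls(name=name, covariates=MODEL_COVARIATES[name], outcome_mode=outcome_mode)

    @property
    def confounders(self) -> tuple[str, ...]:
        return tuple(c for c in self.covariates if c != "lesion")

    @property
    def n_params(self) -> int:
        """Parameters of the continuous fit: intercept + lesion + confounders."""
        return 2 + len(self.confounders)


@dataclass
class StatMap:
    """Per-voxel lesion-coefficient statistics on the analysis mask.

    Arrays are NaN outside the analysis mask and at flagged voxels
    (degenerate lesion contrast, rank deficiency, ordinal non-convergence).
    """

    coef: np.ndarray
    se: np.ndarray
    tstat: np.ndarray
    pvalue: np.ndarray
    df: int
    n_params: int
    n_used: int
    n_tests: int
    analysis_mask: np.ndarray
    model: str
    registration_label: str = ""
    n_flagged: int = 0
    n_zero_variance: int = 0
    flag_reasons: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class CorrectionResult:
    method: str
    alpha: float
    significant: np.ndarray
    n_significant: int
    n_tests: int


def categorize_edss(edss: np.ndarray, cutpoints: Sequence[float] = DEFAULT_ORDINAL_CUTPOINTS) -> np.ndarray:
    """Ordinal category of each score: number of cutpoints at or below it.

    With the default cutpoints (4, 6): category 0 for scores < 4, category 1
    for 4 <= score <= 5.5, category 2 for scores >= 6.  Missing scores stay NaN.
    """
    edss = np.asarray(edss, dtype=float)
    cats = np.zeros(edss.shape, dtype=float)
    for c in cutpoints:
        cats += (edss >= c).astype(float)
    cats[np.isnan(edss)] = np.nan
    return cats


def _covariate_frame(cohort: LesionCohort, metrics: pd.DataFrame | None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "edss": [s.edss for s in cohort.subjects],
            "age": [s.age for s in cohort.subjects],
            "sex": [s.sex for s in cohort.subjects],
            "duration": [s.duration for s in cohort.subjects],
        },
        index=pd.Index(cohort.subject_ids, name="subject_id"),
    )
    if metrics is not None:
        aligned = metrics.reindex(df.index)
        df["tlv"] = aligned[_METRIC_COLUMNS["tlv"]]
        df["ldi"] = aligned[_METRIC_COLUMNS["ldi"]]
    return df


def _usable_rows(
    cohort: LesionCohort, metrics: pd.DataFrame | None, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Listwise deletion on the modelled variables only.

    Returns (row indices into the cohort, outcome vector, confounder matrix
    with leading intercept column).
    """
    needed = ["edss", *spec.confounders]
    for name in spec.confounders:
        if name in _METRIC_COLUMNS and metrics is None:
            raise ValueError(f"model {spec.name} needs a metrics table for {name!r}")
    frame = _covariate_frame(cohort, metrics)
    usable = frame[needed].notna().all(axis=1).to_numpy()
    rows = np.flatnonzero(usable)
    y = frame["edss"].to_numpy(dtype=float)[rows]
    Z = np.column_stack(
        [np.ones(len(rows))]
        + [frame[name].to_numpy(dtype=float)[rows] for name in spec.confounders]
    )
    return rows, y, Z


def fit_voxelwise(
    cohort: LesionCohort,
    metrics: pd.DataFrame | None,
    spec: ModelSpec,
    analysis_mask: np.ndarray,
    chunk_voxels: int = 20000,
) -> StatMap:
    """OLS of the disability score on [1, lesion_v, confounders] at each voxel.

    Subjects missing any modelled variable are dropped listwise (for this
    model only).  Voxels where the usable subjects all share the same lesion
    status, or where the lesion indicator is collinear with the confounders,
    are flagged missing and not counted as tests.
    """
    cohort.space.validate_grid(np.asarray(analysis_mask), what="analysis mask")
    rows, y, Z = _usable_rows(cohort, metrics, spec)
    n_used = len(rows)
    p = Z.shape[1] + 1  # + lesion column
    if n_used < p + 1:
        raise DegenerateDesignError(
            f"model {spec.name}: only {n_used} usable subjects for {p} parameters"
        )
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise DegenerateDesignError(f"model {spec.name}: confounders are collinear")
    df = n_used - p

    # residualize outcome against confounders once
    Q, _ = np.linalg.qr(Z)
    ry = y - Q @ (Q.T @ y)
    syy = float(ry @ ry)

    vox = np.flatnonzero(np.asarray(analysis_mask).ravel() > 0)
    flat_masks = cohort.masks.reshape(cohort.n_subjects, -1)[rows]

    nvox = len(vox)
    coef = np.full(nvox, np.nan)
    se = np.full(nvox, np.nan)
    n_zero_variance = 0
    flag_degenerate = 0
    flag_collinear = 0

    for start in range(0, nvox, chunk_voxels):
        sl = slice(start, min(start + chunk_voxels, nvox))
        X = flat_masks[:, vox[sl]].astype(float)
        ones = X.sum(axis=0)
        valid = (ones > 0) & (ones < n_used)
        flag_degenerate += int(np.count_nonzero(~valid))
        rX = X - Q @ (Q.T @ X)
        sxx = np.einsum("ij,ij->j", rX, rX)
        collinear = valid & (sxx <= _RANK_TOL * n_used)
        flag_collinear += int(np.count_nonzero(collinear))
        valid &= ~collinear
        sxy = ry @ rX
        with np.errstate(divide="ignore", invalid="ignore"):
            b = sxy / sxx
            rss = syy - b * sxy
            rss = np.maximum(rss, 0.0)
            s = np.sqrt(rss / df / sxx)
        b[~valid] = np.nan
        s[~valid] = np.nan
        n_zero_variance += int(np.count_nonzero(valid & (rss <= 1e-12 * max(syy, 1.0))))
        coef[sl] = b
        se[sl] = s

    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    pvals[~np.isfinite(t)] = np.nan
    # zero residual variance: infinite t, p -> 0
    pvals[np.isinf(t)] = 0.0

    shape = cohort.space.shape
    out = {}
    for name, flat in (("coef", coef), ("se", se), ("tstat", t), ("pvalue", pvals)):
        full = np.full(int(np.prod(shape)), np.nan)
        full[vox] = flat
        out[name] = full.reshape(shape)

    n_tests = int(np.count_nonzero(np.isfinite(out["pvalue"])))
    return StatMap(
        coef=out["coef"],
        se=out["se"],
        tstat=out["tstat"],
        pvalue=out["pvalue"],
        df=df,
        n_params=p,
        n_used=n_used,
        n_tests=n_tests,
        analysis_mask=np.asarray(analysis_mask).astype(np.uint8),
        model=spec.name,
        registration_label=cohort.registration_label,
        n_flagged=flag_degenerate + flag_collinear,
        n_zero_variance=n_zero_variance,
        flag_reasons={"degenerate_contrast": flag_degenerate, "collinear": flag_collinear},
    )


# ---------------------------------------------------------------------------
# multiplicity corrections
# ---------------------------------------------------------------------------

def correct_pvalues(stat: StatMap, method: str, alpha: float = 0.05) -> CorrectionResult:
    """Threshold the p-value map controlling FWER (Bonferroni) or FDR (BH).

    Only non-missing p-values count as tests.  The BH step-up rule is the
    independence variant: reject all p <= p_(k) where k is the largest index
    with p_(k) <= k * alpha / m.
    """
    if method not in ("bonferroni", "bh_fdr"):
        raise ValueError(f"unknown correction method {method!r}")
    pmap = stat.pvalue
    finite = np.isfinite(pmap)
    m = int(np.count_nonzero(finite))
    significant = np.zeros(pmap.shape, dtype=np.uint8)
    if m > 0:
        pv = pmap[finite]
        if method == "bonferroni":
            reject = pv <= alpha / m
        else:
            order = np.argsort(pv, kind="stable")
            sorted_p = pv[order]
            thresh = alpha * np.arange(1, m + 1) / m
            passing = np.flatnonzero(sorted_p <= thresh)
            if passing.size:
                cutoff = sorted_p[passing[-1]]
                reject = pv <= cutoff
            else:
                reject = np.zeros(m, dtype=bool)
        significant[finite] = reject.astype(np.uint8)
    return CorrectionResult(
        method=method,
        alpha=alpha,
        significant=significant,
        n_significant=int(significant.sum()),
        n_tests=m,
    )


def extrapolate_sample_size(stat: StatMap, n_actual: int, n_target: int) -> StatMap:
    """Approximate the p-value map at a larger sample size.

    Coefficients stay fixed; standard errors shrink by sqrt(n_target /
    n_actual) and degrees of freedom are recomputed at the target size.
    """
    if not 2 <= n_actual <= n_target:
        raise ValueError("need n_target >= n_actual >= 2")
    if n_target == n_actual:
        return stat
    factor = math.sqrt(n_target / n_actual)
    se = stat.se / factor
    with np.errstate(divide="ignore", invalid="ignore"):
        t = stat.coef / se
    df = n_target - stat.n_params
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    pvals[~np.isfinite(t)] = np.nan
    pvals[np.isinf(t)] = 0.0
    return replace(
        stat,
        se=se,
        tstat=t,
        pvalue=pvals,
        df=df,
        n_used=n_target,
        coef=stat.coef.copy(),
    )


# ---------------------------------------------------------------------------
# proportional-odds ordinal variant
# ---------------------------------------------------------------------------

def _po_unpack(params: np.ndarray, n_thresh: int) -> tuple[np.ndarray, np.ndarray]:
    """Thresholds are parameterized as (a1, a1+exp(g2), ...) to stay ordered."""
    raw = params[:n_thresh]
    thresholds = np.empty(n_thresh)
    thresholds[0] = raw[0]
    if n_thresh > 1:
        thresholds[1:] = raw[0] + np.cumsum(np.exp(raw[1:]))
    return thresholds, params[n_thresh:]


def _po_nll(params: np.ndarray, X: np.ndarray, ycat: np.ndarray, n_cat: int) -> float:
    n_thresh = n_cat - 1
    thresholds, beta = _po_unpack(params, n_thresh)
    eta = X @ beta
    # cumulative P(Y <= k) = sigmoid(theta_{k+1} - eta)
    cum = np.empty((len(eta), n_cat + 1))
    cum[:, 0] = 0.0
    cum[:, -1] = 1.0
    for k in range(n_thresh):
        cum[:, k + 1] = stats.logistic.cdf(thresholds[k] - eta)
    probs = cum[np.arange(len(eta)), ycat + 1] - cum[np.arange(len(eta)), ycat]
    probs = np.clip(probs, 1e-300, None)
    return -float(np.log(probs).sum())


def _numeric_hessian(f, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    k = len(x)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = step
            ej[j] = step
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * step * step)
    return H


def fit_proportional_odds(
    ycat: np.ndarray,
    X: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, bool, str]:
    """Cumulative-logit proportional-odds fit by maximum likelihood.

    ``ycat`` holds integer categories 0..K-1; ``X`` has no intercept column
    (the thresholds absorb it).  Positive coefficients push probability mass
    toward higher categories.  Returns (beta, se_beta, converged, reason).
    """
    ycat = np.asarray(ycat, dtype=int)
    X = np.asarray(X, dtype=float)
    cats = np.unique(ycat)
    n_cat = int(cats.max()) + 1
    if len(cats) < 2:
        raise DegenerateDesignError("fewer than 2 populated outcome categories")
    n_thresh = n_cat - 1
    p = X.shape[1]

    # start: empirical cumulative logits, zero slopes
    cumfreq = np.cumsum(np.bincount(ycat, minlength=n_cat)) / len(ycat)
    cumfreq = np.clip(cumfreq[:-1], 1e-3, 1 - 1e-3)
    theta0 = np.log(cumfreq / (1 - cumfreq))
    x0 = np.zeros(n_thresh + p)
    x0[0] = theta0[0]
    if n_thresh > 1:
        gaps = np.clip(np.diff(theta0), 1e-3, None)
        x0[1:n_thresh] = np.log(gaps)

    res = optimize.minimize(
        _po_nll,
        x0,
        args=(X, ycat, n_cat),
        method="BFGS",
        options={"maxiter": max_iter, "gtol": tol},
    )
    thresholds, beta = _po_unpack(res.x, n_thresh)
    norm = float(np.linalg.norm(np.concatenate([thresholds, beta])))
    # a log-odds beyond ~20 is numerically indistinguishable from (quasi-)
    # separation: the likelihood is flat there and BFGS stops at whatever
    # finite norm the gradient first vanished at
    if norm > _SEPARATION_NORM or float(np.abs(beta).max(initial=0)) > 20:
        return beta, np.full(p, np.nan), False, "separation"
    if not res.success and float(np.linalg.norm(res.jac)) > 1e-3:
        return beta, np.full(p, np.nan), False, "non_convergence"

    H = _numeric_hessian(lambda z: _po_nll(z, X, ycat, n_cat), res.x)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = None
    if cov is None or np.any(np.diag(cov)[n_thresh:] <= 0):
        # a flat likelihood with a huge coefficient is (quasi-)separation:
        # BFGS stops at a finite norm because the gradient vanishes there
        reason = "separation" if float(np.abs(beta).max(initial=0)) > 20 else "singular_hessian"
        return beta, np.full(p, np.nan), False, reason
    return beta, np.sqrt(np.diag(cov)[n_thresh:]), True, "converged"


def fit_ordinal_voxelwise(
    cohort: LesionCohort,
    metrics: pd.DataFrame | None,
    spec: ModelSpec,
    analysis_mask: np.ndarray,
) -> StatMap:
    """Proportional-odds fit of the categorized score at each voxel.

    The disability score is cut into ordered categories at
    ``spec.ordinal_cutpoints`` and the cumulative-logit model is maximized
    per voxel; the map holds the lesion log-odds coefficient and its Wald
    two-sided p-value.  Non-convergence or separation flags the voxel.
    """
    if spec.outcome_mode != "ordinal":
        raise ValueError("spec.outcome_mode must be 'ordinal'")
    cohort.space.validate_grid(np.asarray(analysis_mask), what="analysis mask")
    rows, y, Z = _usable_rows(cohort, metrics, spec)
    n_used = len(rows)
    ycat_f = categorize_edss(y, spec.ordinal_cutpoints)
    ycat = ycat_f.astype(int)
    populated = np.unique(ycat)
    if len(populated) < 2:
        raise DegenerateDesignError("fewer than 2 populated outcome categories")
    # compact category labels in case an intermediate category is empty
    remap = {c: i for i, c in enumerate(sorted(populated))}
    ycat = np.vectorize(remap.get)(ycat)

    confs = Z[:, 1:]  # thresholds play the intercept role
    vox = np.flatnonzero(np.asarray(analysis_mask).ravel() > 0)
    flat_masks = cohort.masks.reshape(cohort.n_subjects, -1)[rows]

    coef = np.full(len(vox), np.nan)
    se = np.full(len(vox), np.nan)
    reasons: dict[str, int] = {"degenerate_contrast": 0}
    for j, v in enumerate(vox):
        x = flat_masks[:, v].astype(float)
        ones = x.sum()
        if ones == 0 or ones == n_used:
            reasons["degenerate_contrast"] += 1
            continue
        X = np.column_stack([x, confs])
        b, s, ok, reason = fit_proportional_odds(ycat, X)
        if not ok:
            reasons[reason] = reasons.get(reason, 0) + 1
            continue
        coef[j] = b[0]
        se[j] = s[0]

    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se
    pvals = 2.0 * stats.norm.sf(np.abs(t))
    pvals[~np.isfinite(t)] = np.nan

    shape = cohort.space.shape
    out = {}
    for name, flat in (("coef", coef), ("se", se), ("tstat", t), ("pvalue", pvals)):
        full = np.full(int(np.prod(shape)), np.nan)
        full[vox] = flat
        out[name] = full.reshape(shape)
    n_params = 1 + confs.shape[1] + (len(populated) - 1)
    return StatMap(
        coef=out["coef"],
        se=out["se"],
        tstat=out["tstat"],
        pvalue=out["pvalue"],
        df=n_used - n_params,
        n_params=n_params,
        n_used=n_used,
        n_tests=int(np.count_nonzero(np.isfinite(out["pvalue"]))),
        analysis_mask=np.asarray(analysis_mask).astype(np.uint8),
        model=spec.name,
        registration_label=cohort.registration_label,
        n_flagged=sum(reasons.values()),
        flag_reasons=reasons,
    )


# ---------------------------------------------------------------------------
# cohort-level screens
# ---------------------------------------------------------------------------

def cohort_regression(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """Simple OLS of y on x over complete pairs: (slope, SE, two-sided p)."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    keep = np.isfinite(y) & np.isfinite(x)
    y, x = y[keep], x[keep]
    if len(y) < 3:
        raise DegenerateDesignError("need at least 3 complete (y, x) pairs")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("predictor has zero variance")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.stderr), float(res.pvalue)
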