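import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from lesionmap import (
    ModelSpec,
    StatMap,
    categorize_edss,
    cohort_regression,
    correct_pvalues,
    extrapolate_sample_size,
    fit_ordinal_voxelwise,
    fit_proportional_odds,
    fit_voxelwise,
    lesion_count_map,
    subject_metrics,
)
from lesionmap.voxelwise_models import DegenerateDesignError

from conftest import make_cohort


def ols_oracle(y, X):
    """Explicit normal-equations solve: beta, SE, t, two-sided p."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta, se, t, p, df


def random_cohort(space, n, seed, missing_edss=0):
    rng = np.random.default_rng(seed)
    masks = (rng.random((n, *space.shape)) < 0.35).astype(np.uint8)
    edss = np.round(np.clip(rng.normal(4, 2, n), 0, 10) * 2) / 2
    edss = edss.astype(float)
    if missing_edss:
        edss[rng.choice(n, missing_edss, replace=False)] = np.nan
    return make_cohort(
        space,
        masks,
        edss=edss,
        age=rng.normal(43, 12, n),
        sex=(rng.random(n) < 0.7).astype(float),
        duration=np.clip(rng.normal(11, 9, n), 0, None),
    )


def stat_from_pvalues(pvals):
    """Wrap a 1-D p-value vector into a minimal StatMap for corrections."""
    pvals = np.asarray(pvals, dtype=float)
    shape = (len(pvals), 1, 1)
    arr = pvals.reshape(shape)
    return StatMap(
        coef=np.zeros(shape),
        se=np.ones(shape),
        tstat=np.zeros(shape),
        pvalue=arr,
        df=10,
        n_params=2,
        n_used=12,
        n_tests=int(np.isfinite(arr).sum()),
        analysis_mask=np.ones(shape, np.uint8),
        model="M1",
    )


class TestFitVoxelwise:
    def test_noiseless_recovery(self, unit_space):
        n = 12
        masks = np.zeros((n, 8, 8, 8), np.uint8)
        masks[: n // 2, 3, 3, 3] = 1
        edss = 2.0 + 3.0 * masks[:, 3, 3, 3].astype(float)
        cohort = make_cohort(unit_space, masks, edss=edss)
        amask = np.zeros((8, 8, 8), np.uint8)
        amask[3, 3, 3] = 1
        stat = fit_voxelwise(cohort, None, ModelSpec.preset("M1"), amask)
        assert stat.coef[3, 3, 3] == pytest.approx(3.0)
        assert stat.n_zero_variance == 1
        assert stat.pvalue[3, 3, 3] == 0.0

    @pytest.mark.parametrize("model", ["M1", "M2", "M3", "M4", "M5"])
    def test_matches_normal_equations_oracle(self, unit_space, model):
        cohort = random_cohort(unit_space, n=30, seed=101)
        prev = lesion_count_map(cohort)
        metrics = subject_metrics(cohort, prev, rarity_k=2)
        amask = (prev.counts > 2).astype(np.uint8)
        spec = ModelSpec.preset(model)
        stat = fit_voxelwise(cohort, metrics, spec, amask)

        frame_cols = []
        for c in spec.confounders:
            if c == "tlv":
                frame_cols.append(metrics["tlv_mm3"].to_numpy())
            elif c == "ldi":
                frame_cols.append(metrics["ldi"].to_numpy())
            else:
                frame_cols.append(
                    np.array([getattr(s, c) for s in cohort.subjects], float)
                )
        y_all = np.array([s.edss for s in cohort.subjects], float)

        checked = 0
        for v in np.argwhere(amask)[:50]:
            i, j, k = v
            if not np.isfinite(stat.pvalue[i, j, k]):
                continue
            x = cohort.masks[:, i, j, k].astype(float)
            X = np.column_stack([np.ones(30), x, *frame_cols])
            beta, se, t, p, df = ols_oracle(y_all, X)
            assert stat.coef[i, j, k] == pytest.approx(beta[1], abs=1e-8)
            assert stat.se[i, j, k] == pytest.approx(se[1], abs=1e-8)
            assert stat.tstat[i, j, k] == pytest.approx(t[1], abs=1e-8)
            assert stat.pvalue[i, j, k] == pytest.approx(p[1], abs=1e-8)
            assert stat.df == df
            checked += 1
        assert checked >= 20

    def test_listwise_deletion_per_model(self, unit_space):
        n = 20
        rng = np.random.default_rng(5)
        masks = (rng.random((n, 8, 8, 8)) < 0.4).astype(np.uint8)
        edss = np.round(np.clip(rng.normal(4, 2, n), 0, 10) * 2) / 2
        duration = np.clip(rng.normal(10, 5, n), 0, None)
        duration[3] = np.nan  # missing duration: dropped only by M4/M5
        cohort = make_cohort(
            unit_space,
            masks,
            edss=edss,
            age=rng.normal(43, 12, n),
            sex=(rng.random(n) < 0.5).astype(float),
            duration=duration,
        )
        amask = np.ones((8, 8, 8), np.uint8)
        m1 = fit_voxelwise(cohort, None, ModelSpec.preset("M1"), amask)
        m4 = fit_voxelwise(cohort, None, ModelSpec.preset("M4"), amask)
        assert m1.n_used == n
        assert m4.n_used == n - 1

    def test_missing_edss_dropped(self, unit_space):
        cohort = random_cohort(unit_space, n=25, seed=6, missing_edss=4)
        amask = np.ones((8, 8, 8), np.uint8)
        stat = fit_voxelwise(cohort, None, ModelSpec.preset("M1"), amask)
        assert stat.n_used == 21

    def test_degenerate_voxels_flagged_and_excluded(self, unit_space):
        n = 10
        masks = np.zeros((n, 8, 8, 8), np.uint8)
        masks[:, 0, 0, 0] = 1  # all lesioned: no contrast
        masks[: n // 2, 1, 1, 1] = 1  # valid contrast
        edss = np.round(np.linspace(1, 8, n) * 2) / 2
        cohort = make_cohort(unit_space, masks, edss=edss)
        amask = np.zeros((8, 8, 8), np.uint8)
        amask[0, 0, 0] = 1
        amask[1, 1, 1] = 1
        amask[2, 2, 2] = 1  # nobody lesioned
        stat = fit_voxelwise(cohort, None, ModelSpec.preset("M1"), amask)
        assert math.isnan(stat.pvalue[0, 0, 0])
        assert math.isnan(stat.pvalue[2, 2, 2])
        assert np.isfinite(stat.pvalue[1, 1, 1])
        assert stat.n_tests == 1
        assert stat.flag_reasons["degenerate_contrast"] == 2

    def test_collinear_lesion_flagged(self, unit_space):
        # lesion indicator exactly equal to the sex confounder
        n = 10
        masks = np.zeros((n, 8, 8, 8), np.uint8)
        sex = np.array([1.0] * 5 + [0.0] * 5)
        masks[sex == 1, 2, 2, 2] = 1
        edss = np.round(np.linspace(1, 8, n) * 2) / 2
        cohort = make_cohort(unit_space, masks, edss=edss, sex=sex)
        amask = np.zeros((8, 8, 8), np.uint8)
        amask[2, 2, 2] = 1
        spec = ModelSpec(name="M4", covariates=("lesion", "sex"))
        stat = fit_voxelwise(cohort, None, spec, amask)
        assert math.isnan(stat.pvalue[2, 2, 2])
        assert stat.flag_reasons["collinear"] == 1

    def test_too_few_subjects(self, unit_space):
        cohort = random_cohort(unit_space, n=4, seed=8)
        amask = np.ones((8, 8, 8), np.uint8)
        with pytest.raises(DegenerateDesignError):
            fit_voxelwise(cohort, None, ModelSpec.preset("M4"), amask)


class TestCorrections:
    def test_hand_step_up(self):
        stat = stat_from_pvalues([0.001, 0.02, 0.9])
        bonf = correct_pvalues(stat, "bonferroni", 0.05)
        bh = correct_pvalues(stat, "bh_fdr", 0.05)
        assert bonf.n_significant == 1
        assert bh.n_significant == 2

    def test_all_ones(self):
        stat = stat_from_pvalues([1.0, 1.0, 1.0])
        for method in ("bonferroni", "bh_fdr"):
            assert correct_pvalues(stat, method, 0.05).n_significant == 0

    def test_missing_pvalues_not_counted(self):
        stat = stat_from_pvalues([0.01, np.nan, 0.04])
        bonf = correct_pvalues(stat, "bonferroni", 0.05)
        assert bonf.n_tests == 2
        assert bonf.n_significant == 1  # 0.01 <= 0.05/2 but 0.04 > 0.025

    def test_empty(self):
        stat = stat_from_pvalues([np.nan, np.nan])
        res = correct_pvalues(stat, "bh_fdr", 0.05)
        assert res.n_tests == 0 and res.n_significant == 0

    @given(
        st.lists(
            st.floats(min_value=0, max_value=1, width=32), min_size=1, max_size=100
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_bonferroni_subset_of_bh_and_statsmodels_oracle(self, pvals):
        stat = stat_from_pvalues(pvals)
        bonf = correct_pvalues(stat, "bonferroni", 0.05)
        bh = correct_pvalues(stat, "bh_fdr", 0.05)
        assert np.all(bonf.significant <= bh.significant)
        p = np.asarray(pvals, dtype=float)
        sm_bonf = p <= 0.05 / len(p)
        sm_bh = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        np.testing.assert_array_equal(bonf.significant.ravel().astype(bool), sm_bonf)
        np.testing.assert_array_equal(bh.significant.ravel().astype(bool), sm_bh)

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            correct_pvalues(stat_from_pvalues([0.5]), "holm", 0.05)


class TestExtrapolation:
    def _stat(self, unit_space, seed=3):
        cohort = random_cohort(unit_space, n=40, seed=seed)
        prev = lesion_count_map(cohort)
        amask = (prev.counts > 3).astype(np.uint8)
        return fit_voxelwise(cohort, None, ModelSpec.preset("M1"), amask)

    def test_identity(self, unit_space):
        stat = self._stat(unit_space)
        assert extrapolate_sample_size(stat, stat.n_used, stat.n_used) is stat

    def test_t_scaling(self, unit_space):
        stat = self._stat(unit_space)
        out = extrapolate_sample_size(stat, 98, 392)
        with np.errstate(invalid="ignore"):
            ratio = out.tstat / stat.tstat
        finite = np.isfinite(ratio)
        np.testing.assert_allclose(ratio[finite], 2.0, atol=1e-12)
        assert out.df == 392 - stat.n_params

    def test_p_monotone(self, unit_space):
        stat = self._stat(unit_space)
        out = extrapolate_sample_size(stat, stat.n_used, 4 * stat.n_used)
        finite = np.isfinite(stat.pvalue)
        assert np.all(out.pvalue[finite] <= stat.pvalue[finite] + 1e-15)

    def test_bad_sizes(self, unit_space):
        stat = self._stat(unit_space)
        with pytest.raises(ValueError):
            extrapolate_sample_size(stat, 100, 50)


class TestOrdinal:
    def test_categorize_edss(self):
        cats = categorize_edss(np.array([3.5, 4.0, 5.5, 6.0]))
        np.testing.assert_array_equal(cats, [0, 1, 1, 2])

    def test_categorize_preserves_missing(self):
        cats = categorize_edss(np.array([np.nan, 2.0]))
        assert math.isnan(cats[0]) and cats[1] == 0

    def test_matches_statsmodels_oracle(self):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        rng = np.random.default_rng(12)
        n = 300
        x = (rng.random(n) < 0.5).astype(float)
        z = rng.normal(size=n)
        latent = 1.2 * x + 0.5 * z + rng.logistic(size=n)
        ycat = np.digitize(latent, [0.5, 2.0])
        X = np.column_stack([x, z])
        beta, se, ok, _ = fit_proportional_odds(ycat, X)
        assert ok
        sm_fit = OrderedModel(ycat, X, distr="logit").fit(method="bfgs", disp=0)
        np.testing.assert_allclose(beta, sm_fit.params[:2], atol=5e-4)
        np.testing.assert_allclose(se, sm_fit.bse[:2], atol=5e-4)

    def test_separation_flagged(self, unit_space):
        # category is a deterministic step function of the lesion indicator
        n = 20
        masks = np.zeros((n, 8, 8, 8), np.uint8)
        masks[: n // 2, 3, 3, 3] = 1
        edss = np.where(masks[:, 3, 3, 3] == 1, 6.5, 2.0)
        cohort = make_cohort(unit_space, masks, edss=edss)
        amask = np.zeros((8, 8, 8), np.uint8)
        amask[3, 3, 3] = 1
        spec = ModelSpec.preset("M1", outcome_mode="ordinal")
        stat = fit_ordinal_voxelwise(cohort, None, spec, amask)
        assert math.isnan(stat.pvalue[3, 3, 3])
        assert stat.n_flagged == 1
        assert "separation" in stat.flag_reasons

    def test_too_few_categories(self, unit_space):
        n = 10
        masks = np.zeros((n, 8, 8, 8), np.uint8)
        masks[:5, 1, 1, 1] = 1
        cohort = make_cohort(unit_space, masks, edss=[2.0] * n)
        amask = np.ones((8, 8, 8), np.uint8)
        spec = ModelSpec.preset("M1", outcome_mode="ordinal")
        with pytest.raises(DegenerateDesignError):
            fit_ordinal_voxelwise(cohort, None, spec, amask)

    def test_requires_ordinal_mode(self, unit_space):
        cohort = random_cohort(unit_space, n=20, seed=1)
        with pytest.raises(ValueError):
            fit_ordinal_voxelwise(
                cohort, None, ModelSpec.preset("M1"), np.ones((8, 8, 8), np.uint8)
            )


class TestCohortRegression:
    def test_noiseless(self):
        x = np.arange(10, dtype=float)
        slope, se, p = cohort_regression(2 * x + 1, x)
        assert slope == pytest.approx(2.0)
        assert p < 1e-12

    def test_constant_x(self):
        with pytest.raises(DegenerateDesignError):
            cohort_regression(np.arange(5, dtype=float), np.ones(5))

    def test_too_few_pairs(self):
        with pytest.raises(DegenerateDesignError):
            cohort_regression(np.array([1.0, 2.0]), np.array([0.0, 1.0]))

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(30)
        n = 98
        x = rng.normal(size=n)
        y = 0.3 * x + rng.normal(0, 2, size=n)
        slope, se, p = cohort_regression(y, x)
        X = np.column_stack([np.ones(n), x])
        beta, ose, ot, op, _ = ols_oracle(y, X)
        assert slope == pytest.approx(beta[1], abs=1e-10)
        assert se == pytest.approx(ose[1], abs=1e-10)
        assert p == pytest.approx(op[1], abs=1e-10)

    def test_missing_pairs_dropped(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, np.nan])
        y = np.array([1.0, 3.0, 5.0, np.nan, 9.0])
        slope, _, _ = cohort_regression(y, x)
        assert slope == pytest.approx(2.0)


class TestModelSpec:
    def test_presets(self):
        assert ModelSpec.preset("M1").covariates == ("lesion",)
        assert ModelSpec.preset("M5").covariates == (
            "lesion", "tlv", "ldi", "age", "sex", "duration",
        )

    def test_lesion_required(self):
        with pytest.raises(ValueError):
            ModelSpec(name="X", covariates=("tlv",))

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            ModelSpec.preset("M9")
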