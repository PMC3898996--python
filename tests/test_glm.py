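"""Design construction, OLS correctness, contrasts, partial R^2, FWE,
and global-trend fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vbmglobals.glm import (
    DesignMatrix,
    MassUnivariateOLS,
    age_decline_contrast,
    build_design,
    contrast_t,
    fit_global_trend,
    fit_ols,
    fwe_correct,
    global_trend_table,
    lgm_map,
    partial_r2,
)


def _pinv_oracle(X, Y):
    return np.linalg.pinv(X) @ Y


class TestBuildDesign:
    def test_default_columns(self, cohort420):
        d = build_design(cohort420)
        assert d.names == [
            "age_lin_M",
            "age_quad_M",
            "age_lin_F",
            "age_quad_F",
            "const_M",
            "const_F",
            "tiv",
        ]
        assert d.matrix.shape == (420, 7)

    def test_tgm_column_is_centered(self, cohort420):
        d = build_design(cohort420, include_tgm=True)
        assert d.p == 8
        assert abs(d.column("tgm").mean()) < 1e-9

    def test_every_covariate_has_zero_grand_mean(self, cohort60):
        d = build_design(cohort60, include_tgm=True)
        for name in d.names:
            if not name.startswith("const_"):
                assert abs(d.column(name).mean()) < 1e-9, name

    def test_single_sex_cohort_drops_columns(self, cohort60):
        males = cohort60[cohort60.sex == "M"].reset_index(drop=True)
        with pytest.warns(UserWarning, match="single-sex"):
            d = build_design(males)
        assert d.names == ["age_lin_M", "age_quad_M", "const_M", "tiv"]

    def test_collinear_columns_are_named(self, cohort60):
        c = cohort60.copy()
        c["tgm"] = c["tiv"] + 1.0  # perfectly collinear with TIV
        with pytest.raises(ValueError, match="collinear|rank"):
            build_design(c, include_tgm=True)

    def test_constant_tgm_dropped_with_warning(self, cohort60):
        c = cohort60.copy()
        c["tgm"] = 3.0
        with pytest.warns(UserWarning, match="TGM is constant"):
            d = build_design(c, include_tgm=True)
        assert "tgm" not in d.names

    def test_centering_projects_new_subjects_onto_same_basis(self, cohort60):
        d = build_design(cohort60, include_tgm=True)
        half = cohort60.iloc[::2].reset_index(drop=True)
        d2 = build_design(half, include_tgm=True, centering=d.centering)
        assert d2.names == d.names
        # columns of the projected design use the original means
        np.testing.assert_allclose(d2.matrix[:, -1], half["tgm"] - d.centering["tgm_mean"])


class TestFitOLS:
    def test_exact_linear_fit(self):
        x = np.arange(10.0)
        X = np.column_stack([x, np.ones(10)])
        dm = DesignMatrix(X, ["x", "const"], {}, {})
        fit = fit_ols(2.0 * x + 3.0, dm)
        np.testing.assert_allclose(fit.beta[:, 0], [2.0, 3.0], atol=1e-12)
        assert fit.resid_var[0] == pytest.approx(0.0, abs=1e-20)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_pseudoinverse_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 21))
        p = int(rng.integers(1, 6))
        X = rng.normal(size=(n, p))
        Y = rng.normal(size=(n, 3))
        dm = DesignMatrix(X, [f"x{i}" for i in range(p)], {}, {})
        fit = fit_ols(Y, dm)
        assert np.max(np.abs(fit.beta - _pinv_oracle(X, Y))) < 1e-10

    def test_nan_units_are_listed(self, cohort60):
        d = build_design(cohort60)
        Y = np.zeros((len(cohort60), 3))
        Y[0, 1] = np.nan
        with pytest.raises(ValueError, match=r"\[1\]"):
            fit_ols(Y, d)

    def test_lgm_identity(self, cohort60, rng):
        """Sex-weighted constant equals the per-unit mean of the data."""
        d = build_design(cohort60, include_tgm=True)
        Y = rng.normal(0.5, 0.1, size=(len(cohort60), 40))
        fit = fit_ols(Y, d)
        np.testing.assert_allclose(lgm_map(fit), Y.mean(axis=0), atol=1e-10)

    def test_orthogonal_column_leaves_betas_unchanged(self, rng):
        n = 40
        X = np.column_stack([rng.normal(size=n), np.ones(n)])
        extra = rng.normal(size=n)
        extra -= X @ np.linalg.lstsq(X, extra, rcond=None)[0]  # orthogonalize
        Y = rng.normal(size=(n, 5))
        d1 = DesignMatrix(X, ["x", "const"], {}, {})
        d2 = DesignMatrix(np.column_stack([X, extra]), ["x", "const", "z"], {}, {})
        f1, f2 = fit_ols(Y, d1), fit_ols(Y, d2)
        np.testing.assert_allclose(f1.beta, f2.beta[:2], atol=1e-10)


class TestEstimator:
    def test_sklearn_protocol(self, rng):
        from sklearn.base import clone

        est = MassUnivariateOLS()
        assert est.get_params() == {}
        X = rng.normal(size=(30, 3))
        Y = rng.normal(size=(30, 4))
        est.fit(X, Y)
        assert est.coef_.shape == (3, 4)
        np.testing.assert_allclose(est.predict(X), X @ est.coef_)
        clone(est)  # must be clonable for model selection


class TestContrasts:
    def test_zero_effect_gives_half_one_tailed_p(self, rng):
        X = np.column_stack([np.ones(20)])
        dm = DesignMatrix(X, ["const"], {}, {})
        Y = rng.normal(size=(20, 1))
        fit = fit_ols(Y - Y.mean(), dm)
        # exact zero effect via a zero-variance unit
        fit0 = fit_ols(np.zeros((20, 1)), dm)
        con = contrast_t(fit0, [1.0], tail="lower")
        assert con.t[0] == 0.0
        assert con.p[0] == pytest.approx(0.5)

    def test_lower_and_upper_tails_sum_to_one(self, cohort60, rng):
        d = build_design(cohort60)
        Y = rng.normal(size=(len(cohort60), 8))
        fit = fit_ols(Y, d)
        w = np.zeros(d.p)
        w[0] = 1.0
        lo = contrast_t(fit, w, tail="lower").p
        hi = contrast_t(fit, w, tail="upper").p
        np.testing.assert_allclose(lo + hi, 1.0, atol=1e-12)

    def test_invalid_tail(self, cohort60, rng):
        d = build_design(cohort60)
        fit = fit_ols(rng.normal(size=(len(cohort60), 2)), d)
        with pytest.raises(ValueError, match="tail"):
            contrast_t(fit, np.zeros(d.p), tail="both")

    def test_null_decline_p_is_uniform(self, cohort60, rng):
        """Under no age effect, one-tailed p-values are Uniform(0,1)."""
        d = build_design(cohort60)
        Y = rng.normal(0.0, 1.0, size=(len(cohort60), 1000))
        p = age_decline_contrast(fit_ols(Y, d)).p
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestPartialR2:
    def test_identical_models_give_zero(self, cohort60, rng):
        d = build_design(cohort60)
        Y = rng.normal(size=(len(cohort60), 4))
        fit = fit_ols(Y, d)
        np.testing.assert_allclose(partial_r2(fit, fit), 0.0, atol=1e-12)

    def test_noiseless_signal_gives_one(self):
        x = np.linspace(-1, 1, 30)
        full = DesignMatrix(np.column_stack([x, np.ones(30)]), ["x", "const"], {}, {})
        red = DesignMatrix(np.ones((30, 1)), ["const"], {}, {})
        y = 2.0 * x
        r2 = partial_r2(fit_ols(y, full), fit_ols(y, red))
        assert r2[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_explicit_rss_oracle(self, rng):
        n = 25
        X = np.column_stack([rng.normal(size=n), rng.normal(size=n), np.ones(n)])
        Y = rng.normal(size=(n, 6))
        full = DesignMatrix(X, ["a", "b", "const"], {}, {})
        red = DesignMatrix(X[:, 1:], ["b", "const"], {}, {})
        rss = []
        for Xk in (X, X[:, 1:]):
            B = np.linalg.pinv(Xk) @ Y
            rss.append(((Y - Xk @ B) ** 2).sum(axis=0))
        expected = (rss[1] - rss[0]) / rss[1]
        got = partial_r2(fit_ols(Y, full), fit_ols(Y, red))
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_non_nested_rejected(self, rng):
        n = 20
        a = DesignMatrix(rng.normal(size=(n, 2)), ["a", "b"], {}, {})
        b = DesignMatrix(rng.normal(size=(n, 2)), ["c", "d"], {}, {})
        Y = rng.normal(size=(n, 1))
        with pytest.raises(ValueError, match="nested"):
            partial_r2(fit_ols(Y, a), fit_ols(Y, b))


class TestFWE:
    def test_bonferroni_scales_and_caps(self, cohort60, rng):
        d = build_design(cohort60)
        fit = fit_ols(rng.normal(size=(len(cohort60), 100)), d)
        con = age_decline_contrast(fit)
        corr = fwe_correct(con, "bonferroni")
        np.testing.assert_allclose(corr.p_fwe, np.minimum(1.0, 100 * con.p))
        assert np.all(corr.p_fwe >= con.p)

    def test_single_unit_bonferroni_is_identity(self, cohort60, rng):
        d = build_design(cohort60)
        fit = fit_ols(rng.normal(size=(len(cohort60), 1)), d)
        con = age_decline_contrast(fit)
        corr = fwe_correct(con, "bonferroni")
        np.testing.assert_allclose(corr.p_fwe, con.p)

    def test_permutation_p_on_lattice_and_deterministic(self, cohort60, rng):
        d = build_design(cohort60)
        Y = rng.normal(size=(len(cohort60), 30))
        fit = fit_ols(Y, d)
        con = age_decline_contrast(fit)
        c1 = fwe_correct(con, "permutation_maxT", fit=fit, Y=Y, n_perm=199, seed=42)
        c2 = fwe_correct(con, "permutation_maxT", fit=fit, Y=Y, n_perm=199, seed=42)
        np.testing.assert_array_equal(c1.p_fwe, c2.p_fwe)
        lattice = np.arange(1, 201) / 200.0
        assert np.all(np.isin(np.round(c1.p_fwe * 200), np.round(lattice * 200)))
        assert c1.p_fwe.min() >= 1.0 / 200.0

    def test_permutation_requires_seed(self, cohort60, rng):
        d = build_design(cohort60)
        Y = rng.normal(size=(len(cohort60), 3))
        fit = fit_ols(Y, d)
        con = age_decline_contrast(fit)
        with pytest.raises(ValueError, match="seed"):
            fwe_correct(con, "permutation_maxT", fit=fit, Y=Y)


class TestGlobalTrend:
    def test_noiseless_quadratic_recovery(self, cohort60):
        age = cohort60["age"].to_numpy()
        d = age - age.mean()
        v = 1000.0 - 2.0 * d - 0.05 * (d**2 - (d**2).mean())
        ft = fit_global_trend(v, cohort60)
        assert ft.beta_linear == pytest.approx(-2.0, abs=1e-9)
        assert ft.beta_quadratic == pytest.approx(-0.05, abs=1e-9)
        assert ft.r2_age == pytest.approx(1.0, abs=1e-9)

    def test_percent_change_closed_form(self, cohort60):
        age = cohort60["age"].to_numpy()
        v = 100.0 - 0.1 * (age - age.mean())
        ft = fit_global_trend(v, cohort60)
        lo, hi = age.min(), age.max()
        f = lambda a: 100.0 - 0.1 * (a - age.mean())
        assert ft.percent_change == pytest.approx(100 * (f(hi) - f(lo)) / f(lo), rel=1e-6)
        assert ft.percent_change < 0

    def test_cannot_covary_tiv_out_of_tiv(self, cohort60):
        with pytest.raises(ValueError, match="TIV"):
            fit_global_trend(cohort60["tiv"].to_numpy(), cohort60, covary_tiv=True)

    def test_trend_table_shape(self, cohort60):
        tab = global_trend_table(cohort60)
        # TIV raw only; TGM/TWM/TCSF raw + adjusted
        assert len(tab) == 7
        assert set(tab["measure"]) == {"tiv", "tgm", "twm", "tcsf"}
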