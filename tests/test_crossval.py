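"""Split-half cross-validation: splitting, scoring, oracle equivalence,
overfitting direction, and the two generative regimes."""

import numpy as np
import pandas as pd
import pytest

from vbmglobals.crossval import (
    CVConfig,
    cv_iteration,
    full_data_r2,
    run_crossval,
    split_half,
    summarize_cv,
)
from vbmglobals.glm import build_design
from vbmglobals.synthetic import (
    default_region_specs,
    generate_proportional_roi_dataset,
    generate_roi_dataset,
)


class TestSplitHalf:
    def test_even_split_covers_cohort(self, cohort420):
        tr, te = split_half(cohort420, seed=1, iteration=0)
        assert len(tr) == len(te) == 210
        assert len(np.intersect1d(tr, te)) == 0
        assert len(np.union1d(tr, te)) == 420

    def test_deterministic_given_seed_and_iteration(self, cohort420):
        a = split_half(cohort420, seed=1, iteration=5)
        b = split_half(cohort420, seed=1, iteration=5)
        np.testing.assert_array_equal(a[0], b[0])
        c = split_half(cohort420, seed=1, iteration=6)
        assert not np.array_equal(a[0], c[0])

    def test_stratified_split_balances_cells(self, cohort420):
        tr, te = split_half(
            cohort420, seed=2, iteration=0, stratify="by_sex_and_decade"
        )
        age = cohort420["age"].to_numpy()
        sex = cohort420["sex"].to_numpy()
        decade = np.floor((age - age.min()) / 10.0).astype(int)
        for s in ("M", "F"):
            for d in range(6):
                cell = np.where((sex == s) & (decade == d))[0]
                n_tr = len(np.intersect1d(cell, tr))
                assert abs(n_tr - len(cell) / 2) <= 0.5

    def test_too_small_cohort_rejected(self, cohort420):
        with pytest.raises(ValueError, match="4"):
            split_half(cohort420.iloc[:3], seed=0, iteration=0)


def _mini_cohort(n=24, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "age": np.linspace(20, 75, n),
            "sex": ["M", "M", "F", "F"] * (n // 4),
            "tiv": rng.normal(1500, 100, n),
            "tgm": rng.uniform(600, 700, n),
        }
    )


class TestCVIteration:
    def test_noiseless_true_model_scores_one(self, cohort60):
        """When the training fit recovers the exact generative model, the
        held-out half is predicted perfectly."""
        c = cohort60.copy()
        c["tgm"] = 650.0  # constant TGM: scaling is a no-op
        delta = (c["age"] - c["age"].mean()).to_numpy()
        tivc = (c["tiv"] - c["tiv"].mean()).to_numpy()
        Y = pd.DataFrame(
            {1: 0.6 - 0.003 * delta - 1e-5 * delta**2 + 2e-5 * tivc},
            index=c["subject_id"],
        )
        tr, te = split_half(c, seed=3, iteration=0)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # constant TGM drop
            r2_tr, r2_te = cv_iteration(Y, c, tr, te, "global_scaling")
        assert r2_tr[0] == pytest.approx(1.0, abs=1e-9)
        assert r2_te[0] == pytest.approx(1.0, abs=1e-9)

    def test_zero_age_betas_score_zero(self, cohort60, rng):
        """If the training half estimates no age effect at all, test R^2 is
        exactly zero by the definition of TSS."""
        c = cohort60.copy()
        tr, te = split_half(c, seed=4, iteration=0)
        d_tr = build_design(c.iloc[tr].reset_index(drop=True), include_tgm=True)
        y = rng.normal(size=len(c))
        # orthogonalize the training rows against the training design
        ytr = y[tr]
        ytr = ytr - d_tr.matrix @ np.linalg.lstsq(d_tr.matrix, ytr, rcond=None)[0]
        y[tr] = ytr
        Y = pd.DataFrame({1: y}, index=c["subject_id"])
        r2_tr, r2_te = cv_iteration(Y, c, tr, te, "local_covariation")
        assert r2_tr[0] == pytest.approx(0.0, abs=1e-10)
        assert r2_te[0] == pytest.approx(0.0, abs=1e-10)

    def test_matches_hand_rolled_oracle(self):
        """An independent step-by-step implementation of the train/test
        equations gives the same R^2 on a tiny instance."""
        c = _mini_cohort()
        rng = np.random.default_rng(9)
        y = 0.6 - 0.002 * (c["age"] - 47.5) + rng.normal(0, 0.01, len(c))
        Y = pd.DataFrame({1: y.to_numpy()}, index=c["subject_id"])
        tr = np.arange(0, len(c), 2)
        te = np.arange(1, len(c), 2)

        def design(rows, centering=None, with_age=True, with_tgm=False):
            a = c["age"].to_numpy()[rows]
            s = c["sex"].to_numpy()[rows]
            tiv = c["tiv"].to_numpy()[rows]
            if centering is None:
                amean = a.mean()
                tivm = tiv.mean()
                offs = {}
            else:
                amean, tivm, offs = centering
            cols, names = [], []
            new_offs = {}
            for sx in ("M", "F"):
                ind = (s == sx).astype(float)
                d = (a - amean) * ind
                q = (a - amean) ** 2 * ind
                for nm, col in ((f"lin_{sx}", d), (f"quad_{sx}", q)):
                    off = offs.get(nm, col[ind > 0].mean())
                    new_offs[nm] = off
                    if with_age:
                        cols.append((col - off) * ind)
                        names.append(nm)
            for sx in ("M", "F"):
                cols.append((s == sx).astype(float))
                names.append(f"c_{sx}")
            cols.append(tiv - tivm)
            names.append("tiv")
            if with_tgm:
                tg = c["tgm"].to_numpy()[rows]
                cols.append(tg - tg.mean())
                names.append("tgm")
            return np.column_stack(cols), names, (amean, tivm, new_offs)

        # oracle for local_covariation
        Xtr, names, ctr_info = design(tr, with_tgm=True)
        beta = np.linalg.lstsq(Xtr, Y.to_numpy()[tr, 0], rcond=None)[0]
        age_idx = [i for i, n in enumerate(names) if n.startswith(("lin", "quad"))]
        # train partial R2 of the age terms
        Xred = Xtr[:, [i for i in range(len(names)) if i not in age_idx]]
        bred = np.linalg.lstsq(Xred, Y.to_numpy()[tr, 0], rcond=None)[0]
        rss_f = ((Y.to_numpy()[tr, 0] - Xtr @ beta) ** 2).sum()
        rss_r = ((Y.to_numpy()[tr, 0] - Xred @ bred) ** 2).sum()
        r2_train_oracle = (rss_r - rss_f) / rss_r
        # test: re-estimate nuisance + TGM on the test half, subtract
        Znames_cols, _, _ = design(te, with_age=False, with_tgm=True)
        Z = Znames_cols
        gz = np.linalg.lstsq(Z, Y.to_numpy()[te, 0], rcond=None)[0]
        y_adj = Y.to_numpy()[te, 0] - Z @ gz
        Xte, _, _ = design(te, centering=ctr_info)
        pred = Xte[:, age_idx] @ beta[age_idx]
        pred = pred - Z @ np.linalg.lstsq(Z, pred, rcond=None)[0]
        r2_test_oracle = 1.0 - ((y_adj - pred) ** 2).sum() / (y_adj**2).sum()

        r2_tr, r2_te = cv_iteration(Y, c, tr, te, "local_covariation")
        assert r2_tr[0] == pytest.approx(r2_train_oracle, abs=1e-10)
        assert r2_te[0] == pytest.approx(r2_test_oracle, abs=1e-10)

    def test_unknown_method_rejected(self, cohort60):
        Y = pd.DataFrame({1: np.ones(len(cohort60))}, index=cohort60["subject_id"])
        with pytest.raises(ValueError, match="method"):
            cv_iteration(Y, cohort60, np.arange(30), np.arange(30, 60), "ridge")


class TestFullDataR2:
    def test_proportional_data_leave_no_age_variance_after_scaling(
        self, cohort420, atlas116
    ):
        regions = default_region_specs(atlas116, seed=51)
        Y, cohort, _ = generate_proportional_roi_dataset(
            cohort420, regions, seed=52
        )
        r2 = full_data_r2(Y, cohort)
        assert r2["r2_gs"].median() < 0.02

    def test_uncoupled_regions_give_equal_r2_across_methods(self, cohort420):
        """With no global coupling and near-constant TGM, both adjustments
        recover the same age fraction as a direct fit of the raw data."""
        from vbmglobals.synthetic import RegionSpec
        from vbmglobals.glm import fit_ols, partial_r2

        regions = [
            RegionSpec(i, "L", mean_gm=0.6, linear_slope=-0.004, global_coef=0.0)
            for i in range(1, 6)
        ]
        Y, cohort, _ = generate_roi_dataset(cohort420, regions, seed=53)
        rng = np.random.default_rng(54)
        cohort = cohort.copy()
        cohort["tgm"] = 650.0 * (1.0 + rng.normal(0, 1e-3, len(cohort)))
        r2 = full_data_r2(Y, cohort)
        # oracle: age partial R2 of the raw, unadjusted fit
        d = build_design(cohort)
        fit = fit_ols(Y.to_numpy(), d)
        lin = [n for n in d.names if n.startswith("age_")]
        red = d.subset([n for n in d.names if n not in lin])
        oracle = partial_r2(fit, fit_ols(Y.to_numpy(), red))
        np.testing.assert_allclose(r2["r2_gs"], oracle, atol=0.02)
        np.testing.assert_allclose(r2["r2_lc"], oracle, atol=0.02)


class TestRegimes:
    @pytest.fixture(scope="class")
    def additive_cv(self, cohort420, atlas116):
        regions = default_region_specs(atlas116, seed=61, coupling="heterogeneous")
        Y, cohort, _ = generate_roi_dataset(cohort420, regions, seed=62)
        result = run_crossval(Y, cohort, CVConfig(n_iterations=200, seed=63))
        return result

    def test_training_beats_test_on_average(self, additive_cv):
        """Overfitting direction: mean train R^2 >= mean test R^2 for both
        methods across iterations."""
        r2 = additive_cv.r2
        for j in range(2):
            assert np.nanmean(r2[:, :, j, 0]) >= np.nanmean(r2[:, :, j, 1])

    def test_local_covariation_generalizes_better_on_additive_data(
        self, additive_cv
    ):
        summ = summarize_cv(additive_cv)
        assert summ.wins["test"]["local_covariation"] > summ.wins["test"]["global_scaling"]

    def test_lc_advantage_is_specific_to_the_additive_regime(
        self, additive_cv, cohort420, atlas116
    ):
        """Local Covariation's generalization advantage is substantive on
        additive data and collapses to a near-tie on proportional data,
        where both adjustments are correctly specified (the proportional
        model is nested in the affine one)."""
        regions = default_region_specs(atlas116, seed=71)
        Y, cohort, _ = generate_proportional_roi_dataset(cohort420, regions, seed=72)
        result = run_crossval(Y, cohort, CVConfig(n_iterations=200, seed=73))
        med_prop = summarize_cv(result).roi_medians
        med_add = summarize_cv(additive_cv).roi_medians
        diff_add = (med_add["lc_test"] - med_add["gs_test"]).mean()
        diff_prop = (med_prop["lc_test"] - med_prop["gs_test"]).mean()
        assert diff_add > 0.05
        assert abs(diff_prop) < 0.005

    def test_method_label_swap_swaps_win_counts(self, additive_cv):
        import copy

        swapped = copy.deepcopy(additive_cv)
        swapped.r2 = additive_cv.r2[:, :, ::-1, :]
        a = summarize_cv(additive_cv).wins
        b = summarize_cv(swapped).wins
        assert a["test"]["local_covariation"] == b["test"]["global_scaling"]
        assert a["test"]["global_scaling"] == b["test"]["local_covariation"]
        assert a["train"]["local_covariation"] == b["train"]["global_scaling"]

    def test_single_iteration_summary_equals_iteration(self, cohort420, atlas116):
        regions = default_region_specs(atlas116, seed=81)[:10]
        Y, cohort, _ = generate_roi_dataset(cohort420, regions, seed=82)
        result = run_crossval(Y, cohort, CVConfig(n_iterations=1, seed=83))
        summ = summarize_cv(result)
        np.testing.assert_allclose(
            summ.roi_medians["gs_test"].to_numpy(), result.r2[0, :, 0, 1]
        )
        np.testing.assert_allclose(
            summ.iteration_means["lc_train"].iloc[0],
            np.nanmean(result.r2[0, :, 1, 0]),
        )


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs", [{"n_iterations": 0}, {"stratify": "by_site"}, {"test_centering": "mid"}]
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(ValueError):
            CVConfig(**kwargs).validate()
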