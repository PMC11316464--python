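import numpy as np
import pandas as pd
import pytest
from scipy import linalg

import foramenflow as ff
from foramenflow import pgls as P


@pytest.fixture(scope="module")
def common_fit(study_tree, study_table):
    tree, _ = study_tree
    return ff.pgls_fit(tree, study_table, "log_qdot", "log_bm", group="group")


@pytest.fixture(scope="module")
def interaction_fit(study_tree, study_table):
    tree, _ = study_tree
    return ff.pgls_fit(
        tree, study_table, "log_qdot", "log_bm", group="group", interaction=True
    )


class TestGLSCore:
    def test_identity_correlation_equals_ols(self, study_tree, study_table):
        tree, _ = study_tree
        fit = ff.pgls_fit(
            tree, study_table, "log_qdot", "log_bm", correlation="identity"
        )
        X = np.column_stack(
            [np.ones(88), study_table.loc[fit.taxa, "log_bm"].to_numpy()]
        )
        y = study_table.loc[fit.taxa, "log_qdot"].to_numpy()
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.coef.to_numpy(), beta, atol=1e-8)

    def test_two_points_exact_interpolation(self):
        tree = ff.read_tree("(A:1,B:1);")
        tab = pd.DataFrame(
            {"log_bm": [1.0, 2.0], "log_qdot": [0.0, 1.0]}, index=["A", "B"]
        )
        fit = ff.pgls_fit(tree, tab, "log_qdot", "log_bm", correlation="identity")
        assert np.allclose(fit.residuals, 0.0, atol=1e-10)

    def test_brute_force_normal_equations_oracle(self):
        cfg = ff.SimulationConfig(n_extant=10, n_fossil=2, tree_height=60.0)
        tree, meta = ff.simulate_tree(cfg, 51)
        tab = ff.simulate_allometry(tree, cfg, 52, fossil_tips=meta["fossil_tips"])
        alpha = 0.03
        fit = ff.pgls_fit(
            tree, tab, "log_qdot", "log_bm", group="group", alpha=alpha
        )
        # independent route: explicit inverse + normal equations
        V = np.exp(-alpha * tree.patristic())
        np.fill_diagonal(V, 1.0)
        order = [tree.tip_labels.index(t) for t in fit.taxa]
        V = V[np.ix_(order, order)]
        g = tab.loc[fit.taxa, "group"]
        groups = sorted(g.unique())
        X = np.column_stack(
            [(g == gr).to_numpy(float) for gr in groups]
            + [tab.loc[fit.taxa, "log_bm"].to_numpy()]
        )
        y = tab.loc[fit.taxa, "log_qdot"].to_numpy()
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        assert np.allclose(fit.coef.to_numpy(), beta, atol=1e-8)

    def test_taxa_missing_from_tree_listed(self, study_tree, study_table):
        tree, _ = study_tree
        tab = study_table.copy()
        tab = tab.rename(index={tab.index[0]: "Imaginary_taxon"})
        with pytest.raises(ValueError, match="Imaginary_taxon"):
            ff.pgls_fit(tree, tab, "log_qdot", "log_bm")

    def test_rank_deficient_design_rejected(self, study_tree, study_table):
        # a constant covariate is aliased with the (single-group) intercept
        tree, _ = study_tree
        tab = study_table.copy()
        tab["group"] = "one"
        tab["log_bm"] = 3.0
        with pytest.raises(ValueError, match="rank-deficient"):
            ff.pgls_fit(tree, tab, "log_qdot", "log_bm", group="group", alpha=0.02)

    def test_profiled_alpha_is_profile_optimum(self, study_tree, study_table):
        tree, _ = study_tree
        fit = ff.pgls_fit(tree, study_table, "log_qdot", "log_bm", group="group")
        grid = [
            ff.pgls_fit(
                tree, study_table, "log_qdot", "log_bm", group="group", alpha=a
            ).lnL
            for a in np.logspace(-4, 0, 9)
        ]
        assert fit.lnL >= max(grid) - 1e-6

    def test_bic_definition(self, common_fit):
        assert common_fit.bic == pytest.approx(
            common_fit.k * np.log(common_fit.n) - 2 * common_fit.lnL
        )


class TestModelComparison:
    def test_identical_fits_have_zero_deltas(self, interaction_fit):
        rec = ff.compare_models(interaction_fit, interaction_fit)
        assert rec["delta_aic"] == pytest.approx(0.0)
        assert rec["delta_bic"] == pytest.approx(0.0)

    def test_common_slope_data_rarely_triggers_interaction(self):
        from foramenflow.validation import interaction_power_experiment

        res = interaction_power_experiment(n_reps=50, seed=61, delta_slope=0.0)
        assert res["detected"] <= 5  # non-significant in >= 90% of replicates

    def test_true_slope_difference_detected(self):
        from foramenflow.validation import interaction_power_experiment

        res = interaction_power_experiment(n_reps=50, seed=62, delta_slope=0.3)
        assert res["detected"] >= 40  # >= 80% power

    def test_different_data_rejected(self, study_tree, study_table, interaction_fit):
        tree, _ = study_tree
        small = study_table.iloc[:40]
        fit_small = ff.pgls_fit(tree, small, "log_qdot", "log_bm", group="group")
        with pytest.raises(ValueError):
            ff.compare_models(fit_small, interaction_fit)


class TestWhitenedNormality:
    def test_identity_correlation_whitening_is_identity(self, study_tree, study_table):
        tree, _ = study_tree
        fit = ff.pgls_fit(
            tree, study_table, "log_qdot", "log_bm", correlation="identity"
        )
        L = linalg.cholesky(fit.V, lower=True)
        u = linalg.solve_triangular(L, fit.residuals, lower=True)
        assert np.allclose(u, fit.residuals)

    def test_statistic_matches_statsmodels(self, rng):
        from statsmodels.stats.diagnostic import lilliefors

        x = rng.standard_normal(88)
        stat_sm, _ = lilliefors(x, dist="norm")
        assert P.lilliefors_statistic(x) == pytest.approx(stat_sm, abs=1e-10)

    def test_mc_pvalue_calibrated_under_null(self, rng):
        # iid normal samples should be rejected at ~ the nominal 5% rate
        rejections = 0
        for _ in range(200):
            stat = P.lilliefors_statistic(rng.standard_normal(88))
            if P.lilliefors_mc_pvalue(stat, 88) < 0.05:
                rejections += 1
        assert 4 <= rejections <= 20  # 2%..10% of 200

    def test_heavy_tails_rejected(self, rng):
        rejections = 0
        for _ in range(100):
            stat = P.lilliefors_statistic(rng.standard_t(df=2, size=88))
            if P.lilliefors_mc_pvalue(stat, 88) < 0.05:
                rejections += 1
        assert rejections > 50

    def test_whitened_gls_residuals_pass_under_correct_model(
        self, study_tree, common_fit
    ):
        res = ff.whitened_residual_normality(common_fit, seed=0)
        assert res.n == 88
        assert 0.0 <= res.p_value <= 1.0

    def test_mc_null_deterministic(self):
        p1 = P.lilliefors_mc_pvalue(0.08, 88)
        p2 = P.lilliefors_mc_pvalue(0.08, 88)
        assert p1 == p2


class TestPairwiseAncova:
    def test_bonferroni_arithmetic_and_ratio(self, common_fit):
        contrasts = ff.pairwise_ancova(common_fit)
        assert len(contrasts) == 6  # all pairs of 4 groups
        for c in contrasts:
            assert c.p_bonferroni == pytest.approx(min(1.0, 6 * c.p_raw))
            assert c.flow_ratio == pytest.approx(10.0**c.delta_intercept)
            assert c.z == pytest.approx(c.delta_intercept / c.se)

    def test_bonferroni_multiplication_and_cap(self):
        # p_raw 0.01 with m=6 -> 0.06; p_raw 0.3 -> capped at 1
        assert min(1.0, 6 * 0.01) == pytest.approx(0.06)
        assert min(1.0, 6 * 0.3) == 1.0

    def test_equal_intercepts_rarely_rejected(self):
        from foramenflow.validation import ancova_type_i_experiment

        res = ancova_type_i_experiment(n_reps=30, seed=63)
        assert res["rejections"] <= 6

    def test_recentering_covariate_leaves_z_invariant(self, study_tree, study_table):
        tree, _ = study_tree
        shifted = study_table.copy()
        shifted["log_bm"] = shifted["log_bm"] - shifted["log_bm"].mean()
        alpha = 0.02
        f1 = ff.pgls_fit(tree, study_table, "log_qdot", "log_bm", group="group", alpha=alpha)
        f2 = ff.pgls_fit(tree, shifted, "log_qdot", "log_bm", group="group", alpha=alpha)
        z1 = [c.z for c in ff.pairwise_ancova(f1)]
        z2 = [c.z for c in ff.pairwise_ancova(f2)]
        assert np.allclose(z1, z2, atol=1e-8)

    def test_t_reference_is_more_conservative(self, common_fit):
        z_contrasts = ff.pairwise_ancova(common_fit)
        t_contrasts = ff.pairwise_ancova(common_fit, reference="t")
        for cz, ct in zip(z_contrasts, t_contrasts):
            assert ct.p_raw >= cz.p_raw
            assert ct.z == pytest.approx(cz.z)

    def test_single_group_rejected(self, study_tree, study_table):
        tree, _ = study_tree
        tab = study_table.copy()
        tab["group"] = "everything"
        fit = ff.pgls_fit(tree, tab, "log_qdot", "log_bm", group="group")
        with pytest.raises(ValueError):
            ff.pairwise_ancova(fit)


class TestFlowRatio:
    def test_printed_intercept_arithmetic(self):
        assert ff.flow_ratio(-5.31, -5.77) == pytest.approx(2.884, abs=0.005)
        assert ff.flow_ratio(-5.35, -5.77) == pytest.approx(2.63, abs=0.005)

    def test_reciprocal_product_is_one(self):
        assert ff.flow_ratio(-5.31, -5.77) * ff.flow_ratio(-5.77, -5.31) == pytest.approx(1.0)

    def test_equal_intercepts_give_unity(self):
        assert ff.flow_ratio(-5.0, -5.0) == 1.0


class TestOLSReference:
    def test_collinear_points_recovered_exactly(self):
        tab = pd.DataFrame(
            {"log_bm": [1.0, 2.0, 3.0], "log_qdot": [0.78 - 5.63, 1.56 - 5.63, 2.34 - 5.63]}
        )
        slope, intercept = ff.ols_reference(tab)
        assert slope == pytest.approx(0.78, abs=1e-10)
        assert intercept == pytest.approx(-5.63, abs=1e-10)

    def test_equals_identity_pgls(self, study_tree, study_table):
        tree, _ = study_tree
        fit = ff.pgls_fit(
            tree, study_table, "log_qdot", "log_bm", correlation="identity"
        )
        slope, intercept = ff.ols_reference(study_table)
        assert fit.coef["log_bm"] == pytest.approx(slope, abs=1e-8)
        assert fit.coef["intercept"] == pytest.approx(intercept, abs=1e-8)
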