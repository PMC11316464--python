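import numpy as np
import pandas as pd
import pytest
from scipy import linalg
from scipy.integrate import quad
from scipy.linalg import expm
from scipy.stats import multivariate_normal

import foramenflow as ff
from foramenflow import mvou as M

A2 = np.array([[0.9, 0.3], [0.3, 0.5]])
S2 = np.array([[1.0, 0.4], [0.4, 0.7]])
TH2 = np.array([0.2, -0.5])


def kernel_oracle(tree, A, Sigma):
    """Independent route to the joint OU tip covariance: expm + quadrature."""
    p = A.shape[0]
    T = tree.tip_depths
    S = tree.shared_times()
    n = tree.n_tips
    C = np.zeros((p * n, p * n))
    for i in range(n):
        for j in range(n):
            s = S[i, j]
            V = np.zeros((p, p))
            for a in range(p):
                for b in range(p):
                    V[a, b] = quad(
                        lambda w: (expm(-A * w) @ Sigma @ expm(-A.T * w))[a, b],
                        0.0,
                        s,
                        epsabs=1e-12,
                        epsrel=1e-12,
                    )[0]
            blk = expm(-A * (T[i] - s)) @ V @ expm(-A.T * (T[j] - s))
            for a in range(p):
                for b in range(p):
                    C[a * n + i, b * n + j] = blk[a, b]
    return C


class TestKernel:
    def test_matches_quadrature_oracle(self, four_tip_tree):
        C = M.mvou_covariance(
            four_tip_tree.tip_depths, four_tip_tree.shared_times(), A2, S2
        )
        assert np.allclose(C, kernel_oracle(four_tip_tree, A2, S2), atol=1e-8)

    def test_univariate_reduction_to_ou_structure(self, four_tip_tree):
        from foramenflow.evomodels import _ou_structure

        alpha, sig2 = 0.7, 1.3
        C = M.mvou_covariance(
            four_tip_tree.tip_depths,
            four_tip_tree.shared_times(),
            np.array([[alpha]]),
            np.array([[sig2]]),
        )
        expected = sig2 * _ou_structure(
            four_tip_tree.patristic(), four_tip_tree.shared_times(), alpha
        )
        assert np.allclose(C, expected, atol=1e-10)

    def test_stationary_root_saturates_variance(self, four_tip_tree):
        # with a stationary root every diagonal block sits at the
        # infinite-time (stationary) variance regardless of node depth
        C = M.mvou_covariance(
            four_tip_tree.tip_depths, four_tip_tree.shared_times(), A2, S2,
            root="stationary",
        )
        Cfix = M.mvou_covariance(
            four_tip_tree.tip_depths, four_tip_tree.shared_times(), A2, S2
        )
        lam, Q = np.linalg.eigh(A2)
        St = Q.T @ S2 @ Q
        Vinf = Q @ (St / (lam[:, None] + lam[None, :])) @ Q.T
        n = four_tip_tree.n_tips
        for i in range(n):
            assert C[i, i] == pytest.approx(Vinf[0, 0], rel=1e-10)
        assert np.all(np.diag(Cfix)[:n] < np.diag(C)[:n])

    def test_tiny_pull_approaches_bm(self, four_tip_tree):
        A = 1e-10 * np.eye(2)
        C = M.mvou_covariance(
            four_tip_tree.tip_depths, four_tip_tree.shared_times(), A, S2
        )
        assert np.allclose(
            C, M.mvbm_covariance(four_tip_tree.shared_times(), S2), rtol=1e-6
        )


class TestLoglik:
    def traits(self, tree, values):
        return pd.DataFrame(values, index=tree.tip_labels)

    def test_p1_equals_direct_mvn(self, four_tip_tree):
        x = self.traits(four_tip_tree, {"x": [0.3, -0.2, 1.1, 0.5]})
        alpha, sig2, z0 = 0.7, 1.3, 0.2
        lnl = M.mvou_loglik(
            four_tip_tree, x, np.array([[alpha]]), np.array([[sig2]]), np.array([z0])
        )
        from foramenflow.evomodels import _ou_structure

        C = sig2 * _ou_structure(
            four_tip_tree.patristic(), four_tip_tree.shared_times(), alpha
        )
        oracle = multivariate_normal(mean=np.full(4, z0), cov=C).logpdf(
            x["x"].to_numpy()
        )
        assert lnl == pytest.approx(oracle, abs=1e-6)

    def test_diagonal_model_factorizes(self, four_tip_tree):
        A = np.diag([0.5, 1.2])
        Sg = np.diag([0.8, 0.3])
        th = np.array([0.1, -0.4])
        y = self.traits(
            four_tip_tree, {"a": [0.3, -0.2, 1.1, 0.5], "b": [0.0, 0.2, -0.3, 0.9]}
        )
        joint = M.mvou_loglik(four_tip_tree, y, A, Sg, th)
        parts = M.mvou_loglik(
            four_tip_tree, y[["a"]], A[:1, :1], Sg[:1, :1], th[:1]
        ) + M.mvou_loglik(four_tip_tree, y[["b"]], A[1:, 1:], Sg[1:, 1:], th[1:])
        assert joint == pytest.approx(parts, abs=1e-6)

    def test_complete_data_equals_full_mvn(self, four_tip_tree):
        y = self.traits(
            four_tip_tree, {"a": [0.3, -0.2, 1.1, 0.5], "b": [0.0, 0.2, -0.3, 0.9]}
        )
        lnl = M.mvou_loglik(four_tip_tree, y, A2, S2, TH2)
        C = M.mvou_covariance(
            four_tip_tree.tip_depths, four_tip_tree.shared_times(), A2, S2
        )
        flat = y.to_numpy().T.reshape(-1)
        mean = np.repeat(TH2, 4)
        oracle = multivariate_normal(mean=mean, cov=C, allow_singular=True).logpdf(flat)
        assert lnl == pytest.approx(oracle, abs=1e-6)

    def test_non_spd_parameters_rejected(self, four_tip_tree):
        y = self.traits(
            four_tip_tree, {"a": [0.3, -0.2, 1.1, 0.5], "b": [0.0, 0.2, -0.3, 0.9]}
        )
        with pytest.raises(ValueError, match="positive definite"):
            M.mvou_loglik(four_tip_tree, y, -np.eye(2), S2, TH2)
        with pytest.raises(ValueError, match="symmetric"):
            M.mvou_loglik(four_tip_tree, y, np.array([[1.0, 0.9], [0.1, 1.0]]), S2, TH2)


class TestConditionalEstimates:
    @pytest.fixture
    def toy(self):
        cfg = ff.SimulationConfig(n_extant=5, n_fossil=2, tree_height=10.0)
        tree, _ = ff.simulate_tree(cfg, 71)
        rng = np.random.default_rng(72)
        traits = ff.simulate_mvou_traits(
            tree, A2 * 0.1, S2 * 0.05, TH2, rng, trait_names=("u", "v")
        )
        masked = traits.copy()
        masked.iloc[0, 0] = np.nan
        masked.iloc[3, 1] = np.nan
        masked.iloc[5, 0] = np.nan
        fit = M.MvOUFit(
            "mvOU", ["u", "v"], A2 * 0.1, S2 * 0.05, TH2, 0.0, 13, True, 11
        )
        return tree, traits, masked, fit

    def test_observed_entries_returned_with_zero_sd(self, toy):
        tree, traits, masked, fit = toy
        est = M.estimate_missing(fit, tree, masked)
        obs = est[est["observed"]]
        for _, row in obs.iterrows():
            assert row["sd"] == 0.0
            assert row["mean"] == pytest.approx(
                masked.loc[row["node"], row["trait"]], abs=1e-12
            )

    def test_matches_brute_force_conditional_mvn(self, toy):
        tree, traits, masked, fit = toy
        est = M.estimate_missing(fit, tree, masked)
        # brute force: explicit inverse on the full stacked covariance
        n, p = 7, 2
        C = M.mvou_covariance(tree.tip_depths, tree.shared_times(), fit.A, fit.Sigma)
        flat = masked.to_numpy().T.reshape(-1)
        obs = np.isfinite(flat)
        mean = np.repeat(fit.theta, n)
        Coo_inv = np.linalg.inv(C[np.ix_(obs, obs)])
        mu = mean[~obs] + C[np.ix_(~obs, obs)] @ Coo_inv @ (flat[obs] - mean[obs])
        Sig = C[np.ix_(~obs, ~obs)] - C[np.ix_(~obs, obs)] @ Coo_inv @ C[
            np.ix_(obs, ~obs)
        ]
        miss = est[~est["observed"]]
        assert np.allclose(miss["mean"].to_numpy(), mu, atol=1e-8)
        assert np.allclose(miss["sd"].to_numpy(), np.sqrt(np.diag(Sig)), atol=1e-8)

    def test_trait_column_reordering_invariance(self, toy):
        tree, traits, masked, fit = toy
        est1 = M.estimate_missing(fit, tree, masked)
        fit_swapped = M.MvOUFit(
            "mvOU",
            ["v", "u"],
            fit.A[::-1, ::-1].copy(),
            fit.Sigma[::-1, ::-1].copy(),
            fit.theta[::-1].copy(),
            0.0,
            13,
            True,
            11,
        )
        est2 = M.estimate_missing(fit_swapped, tree, masked[["v", "u"]])
        key = ["node", "trait"]
        merged = est1.merge(est2, on=key, suffixes=("_1", "_2"))
        assert np.allclose(merged["mean_1"], merged["mean_2"], atol=1e-10)
        assert np.allclose(merged["sd_1"], merged["sd_2"], atol=1e-10)

    def test_all_missing_trait_rejected(self, toy):
        tree, traits, masked, fit = toy
        masked = masked.copy()
        masked["u"] = np.nan
        with pytest.raises(ValueError, match="fewer than two"):
            M.estimate_missing(fit, tree, masked)


class TestAncestralStates:
    def test_two_tip_bm_limit_root_is_midpoint(self):
        tree = ff.read_tree("(A:1,B:1);")
        traits = pd.DataFrame({"x": [0.0, 2.0]}, index=["A", "B"])
        fit = ff.mvou_fit(tree, traits, mode="diagonal")
        anc = ff.ancestral_states(fit, tree, traits)
        root = anc[anc["node_index"] == 0]
        assert root["mean"].iloc[0] == pytest.approx(1.0, abs=1e-6)
        assert root["sd"].iloc[0] == pytest.approx(0.0, abs=1e-8)

    def test_strong_pull_shrinks_nodes_toward_optimum(self, four_tip_tree):
        traits = pd.DataFrame(
            {"x": [1.5, 2.1, -0.4, 0.8]}, index=four_tip_tree.tip_labels
        )
        theta = np.array([0.5])

        def node_spread(alpha):
            fit = M.MvOUFit(
                "mvOU", ["x"], np.array([[alpha]]), np.array([[1.0]]), theta,
                0.0, 3, True, 4,
            )
            anc = M.ancestral_states(fit, four_tip_tree, traits)
            return np.abs(anc["mean"].to_numpy() - theta[0]).max()

        assert node_spread(5.0) < node_spread(0.1)

    def test_matches_brute_force_on_toy(self):
        cfg = ff.SimulationConfig(n_extant=4, n_fossil=1, tree_height=8.0)
        tree, _ = ff.simulate_tree(cfg, 73)
        traits = ff.simulate_mvou_traits(
            tree, A2 * 0.2, S2 * 0.1, TH2, np.random.default_rng(74),
            trait_names=("u", "v"),
        )
        fit = M.MvOUFit("mvOU", ["u", "v"], A2 * 0.2, S2 * 0.1, TH2, 0.0, 13, True, 10)
        anc = M.ancestral_states(fit, tree, traits)
        # brute force over the joint (tips + internals) Gaussian
        tip_idx = tree.tip_indices
        internal = [i for i in range(tree.n_nodes) if i not in set(tip_idx.tolist())]
        nodes = np.concatenate([tip_idx, internal])
        C = M.mvou_covariance(tree.depths[nodes], tree.shared_times(nodes), fit.A, fit.Sigma)
        m = nodes.size
        n = tree.n_tips
        obs = np.zeros(2 * m, dtype=bool)
        x = np.zeros(2 * m)
        for k in range(2):
            obs[k * m : k * m + n] = True
            x[k * m : k * m + n] = traits.iloc[:, k].to_numpy()
        mean = np.repeat(fit.theta, m)
        Coo_inv = np.linalg.inv(C[np.ix_(obs, obs)])
        mu = mean[~obs] + C[np.ix_(~obs, obs)] @ Coo_inv @ (x[obs] - mean[obs])
        got = anc.sort_values(["trait", "node_index"])["mean"].to_numpy()
        want = np.concatenate(
            [mu[: len(internal)], mu[len(internal) :]]
        )  # traits are already in (u, v) = sorted order
        assert np.allclose(got, want, atol=1e-6)


class TestFitting:
    def test_single_trait_fit_matches_univariate_ou(self):
        cfg = ff.SimulationConfig(n_extant=40, n_fossil=0, tree_height=5.0)
        tree, _ = ff.simulate_tree(cfg, 75)
        rng = np.random.default_rng(76)
        traits = ff.simulate_mvou_traits(
            tree, np.array([[0.8]]), np.array([[1.0]]), np.array([0.0]), rng,
            trait_names=("x",),
        )
        fit_mv = ff.mvou_fit(tree, traits, mode="diagonal")
        fit_uni = ff.fit_ou(tree, traits["x"])
        assert fit_mv.lnL == pytest.approx(fit_uni.lnL, abs=1e-2)
        assert fit_mv.A[0, 0] == pytest.approx(fit_uni.parameters["alpha"], rel=0.1)

    @pytest.mark.parametrize("truth", ["mvBM", "mvOU"])
    def test_model_selection_recovers_generating_process(self, truth):
        cfg = ff.SimulationConfig(n_extant=32, n_fossil=0, tree_height=100.0)
        tree, _ = ff.simulate_tree(cfg, 77)
        tree.shared_times()
        rng = np.random.default_rng(78)
        wins = 0
        n_reps = 12
        for _ in range(n_reps):
            if truth == "mvBM":
                Sg = np.array([[0.02, 0.008], [0.008, 0.015]])
                C = M.mvbm_covariance(tree.shared_times(), Sg)
                L = linalg.cholesky(C + 1e-10 * np.eye(64), lower=True)
                flat = L @ rng.standard_normal(64)
                traits = pd.DataFrame(
                    flat.reshape(2, 32).T, index=tree.tip_labels, columns=["a", "b"]
                )
            else:
                traits = ff.simulate_mvou_traits(
                    tree, np.diag([0.1, 0.08]), np.array([[0.4, 0.1], [0.1, 0.3]]),
                    np.zeros(2), rng, trait_names=("a", "b"),
                )
            fit_ou_mv = ff.mvou_fit(tree, traits, mode="diagonal")
            fit_bm_mv = ff.mvbm_fit(tree, traits)
            best = "mvOU" if fit_ou_mv.aic < fit_bm_mv.aic else "mvBM"
            wins += best == truth
        assert wins >= int(0.8 * n_reps)

    def test_study_design_imputation_recovers_truth(self, study_tree, study_config):
        tree, fossil = study_tree
        traits = ff.simulate_mvou_traits(
            tree, study_config.mvou_A, study_config.mvou_Sigma,
            study_config.mvou_theta, np.random.default_rng(79),
        )
        masked = traits.copy()
        masked.loc[fossil, "log_mmr"] = np.nan
        fit = ff.mvou_fit(tree, masked, mode="diagonal")
        est = ff.estimate_missing(fit, tree, masked)
        miss = est[(est["trait"] == "log_mmr") & (~est["observed"])]
        truth = traits.loc[miss["node"], "log_mmr"]
        assert ff.prediction_r2(miss["mean"], truth) >= 0.8


class TestScalarHelpers:
    def test_prediction_r2_limits(self, rng):
        x = rng.standard_normal(50)
        assert ff.prediction_r2(x, x) == pytest.approx(1.0)
        y = rng.standard_normal(50)
        assert ff.prediction_r2(x, y) < 0.15

    def test_prediction_r2_rejects_degenerate(self):
        with pytest.raises(ValueError):
            ff.prediction_r2([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])

    @pytest.mark.parametrize(
        "mmr,bm,expected",
        [(7.0, 1.0, 7.0), (1000.0, 1000.0, 1000.0 / 1000.0**0.67)],
    )
    def test_mass_independent_mmr(self, mmr, bm, expected):
        assert ff.mass_independent_mmr(mmr, bm) == pytest.approx(expected, rel=1e-12)

    def test_mass_independent_mmr_doubling_rule(self):
        a = ff.mass_independent_mmr(500.0, 200.0)
        b = ff.mass_independent_mmr(500.0, 400.0)
        assert a / b == pytest.approx(2.0**0.67, rel=1e-12)

    def test_mass_independent_mmr_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ff.mass_independent_mmr(-1.0, 10.0)
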