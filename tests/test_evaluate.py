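"""Evaluation battery: tests, AUC, distances, FDR, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mvharmonize import PanelData
from mvharmonize.evaluate import (
    benjamini_hochberg,
    boxm_test,
    correlation_distances,
    eb_prior_checks,
    manova_batch,
    matrix_distances,
    mcmc_diagnostics,
    rf_batch_auc,
    signal_preservation,
    univariate_batch_tests,
)
from tests.conftest import make_panel


class TestBoxM:
    def test_identical_groups_give_zero_statistic(self, rng):
        g = rng.standard_normal((30, 3))
        chi2, df, p = boxm_test([g.copy(), g.copy()])
        assert chi2 == pytest.approx(0.0, abs=1e-8)
        assert p == pytest.approx(1.0)

    def test_detects_scaled_covariance(self, rng):
        """Identity vs 2*identity covariance (M=2, n=200 per group) is
        detected at p < 0.01."""
        a = rng.standard_normal((200, 2))
        b = np.sqrt(2.0) * rng.standard_normal((200, 2))
        _, _, p = boxm_test([a, b])
        assert p < 0.01

    def test_matches_pingouin_reference(self, rng):
        """Cross-check statistic and p-value against the independent
        pingouin implementation."""
        pingouin = pytest.importorskip("pingouin")
        groups = [rng.standard_normal((40, 3)) * (1 + 0.3 * i) for i in range(3)]
        chi2, df, p = boxm_test(groups)
        frames = []
        for i, g in enumerate(groups):
            df_ = pd.DataFrame(g, columns=["a", "b", "c"])
            df_["grp"] = i
            frames.append(df_)
        ref = pingouin.box_m(pd.concat(frames), dvs=["a", "b", "c"], group="grp")
        assert chi2 == pytest.approx(float(ref["Chi2"].iloc[0]), rel=1e-6)
        assert p == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-6)

    def test_affine_invariance(self, rng):
        """A common invertible linear map applied to every group leaves the
        statistic unchanged."""
        groups = [rng.standard_normal((50, 3)) * (1 + 0.5 * i) for i in range(2)]
        A = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        chi2_a, _, _ = boxm_test(groups)
        chi2_b, _, _ = boxm_test([g @ A.T for g in groups])
        assert chi2_a == pytest.approx(chi2_b, rel=1e-8)

    def test_null_calibration(self, rng):
        """Equal covariances: rejection rate near the nominal level."""
        rejections = 0
        trials = 300
        for _ in range(trials):
            groups = [rng.standard_normal((100, 2)) for _ in range(2)]
            _, _, p = boxm_test(groups)
            rejections += p < 0.05
        assert abs(rejections / trials - 0.05) < 0.03


class TestManova:
    def test_matches_statsmodels_reference(self, rng):
        from statsmodels.multivariate.manova import MANOVA

        n = 90
        panel = make_panel(n=n, p=2, M=3, I=3, seed=3, batch_shift=[0.0, 0.4, -0.4])
        res = manova_batch(panel, formula="age + sex")
        # reference on the same residuals for feature 0
        from mvharmonize import fit_fixed_effects, remove_fixed_effects
        model = fit_fixed_effects(panel, "age + sex")
        Z = remove_fixed_effects(panel, model)
        df = pd.DataFrame(Z[:, 0, :], columns=["y1", "y2", "y3"])
        df["batch"] = panel.batch
        ref = MANOVA.from_formula("y1 + y2 + y3 ~ C(batch)", data=df).mv_test()
        tbl = ref.results["C(batch)"]["stat"]
        p_ref = float(tbl.loc["Pillai's trace", "Pr > F"])
        assert res["pval"].iloc[0] == pytest.approx(p_ref, rel=1e-6)

    def test_detects_location_shift(self):
        panel = make_panel(n=150, p=3, M=3, I=2, seed=5, batch_shift=[1.0, -1.0])
        res = manova_batch(panel, formula="age + sex")
        assert (res["pval_bonf"] < 0.05).all()


class TestUnivariateTests:
    def test_null_calibration_with_permuted_labels(self, rng):
        """Permuted batch labels: per-test rejection near the nominal rate
        (before correction) over many slices."""
        panel = make_panel(n=120, p=25, M=4, I=2, seed=7)
        perm = rng.permutation(panel.batch)
        panel = PanelData(values=panel.values, batch=perm,
                          covariates=panel.covariates,
                          feature_ids=panel.feature_ids,
                          metric_ids=panel.metric_ids)
        df = univariate_batch_tests(panel, "age + sex")
        for t in ("anova", "kruskal", "levene"):
            rate = (df[t] < 0.05).mean()
            assert rate <= 0.05 + 0.05

    def test_huge_shift_detected(self):
        panel = make_panel(n=80, p=2, M=2, I=2, seed=8, batch_shift=[2.5, -2.5])
        df = univariate_batch_tests(panel, "age + sex")
        assert (df["anova"] < 1e-6).all()

    def test_bonferroni_is_multiplication(self):
        panel = make_panel(n=40, p=1, M=2, I=2, seed=9)
        df = univariate_batch_tests(panel, "age + sex")
        np.testing.assert_allclose(df["anova_bonf"],
                                   np.minimum(df["anova"] * 2, 1.0))


class TestRandomForestAUC:
    def test_chance_level_on_permuted_labels(self, rng):
        panel = make_panel(n=200, p=8, M=1, I=2, seed=10)
        panel = PanelData(values=panel.values,
                          batch=rng.permutation(panel.batch),
                          covariates=panel.covariates,
                          feature_ids=panel.feature_ids,
                          metric_ids=panel.metric_ids)
        auc = rf_batch_auc(panel, panel.metric_ids[0], seed=1)
        assert 0.35 <= auc <= 0.65

    def test_separable_batches_detected(self):
        rng = np.random.default_rng(2)
        n = 200
        vals = rng.standard_normal((n, 5, 1))
        batch = np.where(vals[:, 0, 0] > 0, "a", "b")
        panel = PanelData(values=vals, batch=batch,
                          covariates=pd.DataFrame(index=range(n)),
                          feature_ids=[f"f{i}" for i in range(5)],
                          metric_ids=["m"])
        auc = rf_batch_auc(panel, "m", seed=3)
        assert auc > 0.95


class TestDistances:
    def test_zero_on_identical_matrices(self, rng):
        C = np.corrcoef(rng.standard_normal((30, 4)), rowvar=False)
        d = matrix_distances(C, C.copy())
        assert all(v == 0.0 for v in d.values())

    def test_hand_computed_frobenius(self):
        """3x3 identity vs identity with one off-diagonal pair +/-0.5:
        Frobenius = sqrt(2 * 0.25) = 0.7071."""
        C = np.eye(3)
        C2 = np.eye(3)
        C2[0, 1] = C2[1, 0] = 0.5
        d = matrix_distances(C, C2)
        assert d["frobenius"] == pytest.approx(np.sqrt(0.5), rel=1e-10)
        assert d["mse"] == pytest.approx(2 * 0.25 / 9, rel=1e-10)
        assert d["spectral"] == pytest.approx(0.5, rel=1e-10)

    def test_permutation_invariance(self, rng):
        A_ = rng.standard_normal((40, 5))
        B_ = rng.standard_normal((40, 5))
        C1 = np.corrcoef(A_, rowvar=False)
        C2 = np.corrcoef(B_, rowvar=False)
        perm = rng.permutation(5)
        d1 = matrix_distances(C1, C2)
        d2 = matrix_distances(C1[np.ix_(perm, perm)], C2[np.ix_(perm, perm)])
        for k in d1:
            assert d1[k] == pytest.approx(d2[k], rel=1e-9)

    def test_panel_level_distances_nonnegative_and_zero_vs_self(self):
        panel = make_panel(n=90, p=5, M=2, I=2, seed=11)
        d = correlation_distances(panel, "age + sex", scope="within_metric",
                                  reference="vs_gold", gold=panel)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in d.values())
        d2 = correlation_distances(panel, "age + sex", scope="cross_metric")
        assert all(v >= 0 for v in d2.values())


class TestSignalPreservation:
    def test_bh_step_up_by_hand(self):
        """p = (0.01, 0.02, 0.5) at q = 0.05: first two rejected."""
        rej = benjamini_hochberg(np.array([0.01, 0.02, 0.5]), q=0.05)
        assert rej.tolist() == [True, True, False]

    def test_strong_effects_all_detected(self):
        from mvharmonize import SimulationConfig, gen_baseline
        cfg = SimulationConfig(n=400, p=10, M=3, beta_diag_weak=2.0,
                               beta_diag_strong=2.0, biomarker_fraction=1.0)
        gold, truth = gen_baseline(cfg, 3)
        out = signal_preservation(gold, "diagnosis", "age + sex + diagnosis",
                                  truth=truth)
        assert out["tp"] == 10 * 3
        assert out["fdr"] == 0.0

    def test_null_covariate_fdr_behaviour(self):
        from mvharmonize import SimulationConfig, gen_baseline
        cfg = SimulationConfig(n=300, p=15, M=3, beta_diag_weak=0.0,
                               beta_diag_strong=0.0)
        gold, truth = gen_baseline(cfg, 4)
        truth = dict(truth, beta_diag=np.zeros((15, 3)))
        out = signal_preservation(gold, "diagnosis", "age + sex + diagnosis",
                                  truth=truth)
        # BH under the global null controls false discoveries strictly
        assert out["n_significant"] <= 2


class TestPriorChecks:
    def test_self_consistent_data_overlap(self):
        """Data generated exactly from the EB model shows high overlap
        between empirical and prior-predictive covariance distances."""
        from scipy.stats import invwishart
        rng = np.random.default_rng(5)
        n, p, M, nu = 1000, 80, 3, 10
        Psi = 3.0 * np.eye(M)
        Z = np.zeros((n, p, M))
        for v in range(p):
            S = invwishart.rvs(df=nu, scale=Psi, random_state=rng)
            Z[:, v, :] = rng.multivariate_normal(rng.normal(0, 0.3, M), S, size=n)
        batch = np.array(["a"] * n)
        from mvharmonize import eb_posteriors, mom_hyperparameters
        priors = mom_hyperparameters(Z, batch)
        post = eb_posteriors(Z, batch, priors)
        checks = eb_prior_checks(post, priors, Z, batch, seed=1)
        assert checks["a"]["cov_overlap"] > 0.8

    def test_degenerate_prior_flagged(self, rng):
        from mvharmonize import BatchPriors, BatchPosteriors
        M = 2
        priors = BatchPriors(batches=["a"], gamma_bar={"a": np.zeros(M)},
                             T={"a": np.zeros((M, M))},
                             Psi={"a": np.eye(M)}, nu={"a": M + 4.0})
        post = BatchPosteriors(batches=["a"], gamma_star={}, sigma_star={})
        Z = rng.standard_normal((10, 3, M))
        out = eb_prior_checks(post, priors, Z, np.array(["a"] * 10))
        assert out["a"]["degenerate_T"]


class TestMCMCDiagnostics:
    def test_constant_chains_flagged(self):
        chains = np.ones((4, 100, 2))
        out = mcmc_diagnostics(chains)
        assert out["constant"] and out["passed"]

    def test_independent_chains_pass(self, rng):
        chains = rng.standard_normal((4, 2000, 3))
        out = mcmc_diagnostics(chains)
        assert out["passed"]
        assert np.all(out["ess"] > 1000)

    def test_shifted_chain_fails(self, rng):
        chains = rng.standard_normal((4, 500, 2))
        chains[0] += 2.0
        out = mcmc_diagnostics(chains)
        assert not out["passed"]
        assert np.max(out["rhat"]) > 1.01
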