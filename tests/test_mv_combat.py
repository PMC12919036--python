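"""MV-ComBat: MoM hyperparameters, EB posteriors, whitening, pipeline."""

import numpy as np
import pytest
from scipy.stats import invwishart

from mvharmonize import (
    BatchPriors,
    adjust_residuals,
    eb_posteriors,
    mom_hyperparameters,
    mv_combat,
)
from mvharmonize.evaluate import boxm_feature_fraction
from tests.conftest import make_panel


def _single_batch(Z):
    return np.array(["a"] * Z.shape[0])


class TestMomHyperparameters:
    def test_degenerate_identical_feature_means(self, rng):
        """All features sharing the same batch mean c give prior mean c and
        a zero prior covariance T."""
        n, p, M = 30, 5, 2
        c = np.array([0.7, -0.2])
        noise = rng.standard_normal((n, p, M))
        noise -= noise.mean(axis=0)  # exact per-(v,m) zero means
        Z = noise + c
        priors = mom_hyperparameters(Z, _single_batch(Z))
        np.testing.assert_allclose(priors.gamma_bar["a"], c, atol=1e-12)
        np.testing.assert_allclose(priors.T["a"], 0.0, atol=1e-12)

    def test_iw_parameter_recovery(self):
        """Sigma_iv ~ IW(Psi, nu=12) with M=4, p=200, n=500: the implied
        prior mean Psi_hat/(nu_hat-M-1) recovers Psi/(nu-M-1) to < 10%
        relative Frobenius error."""
        rng = np.random.default_rng(42)
        n, p, M, nu = 500, 200, 4, 12
        Psi = 8.0 * np.eye(M)
        true_mean = Psi / (nu - M - 1)
        Z = np.zeros((n, p, M))
        for v in range(p):
            S = invwishart.rvs(df=nu, scale=Psi, random_state=rng)
            Z[:, v, :] = rng.multivariate_normal(np.zeros(M), S, size=n)
        priors = mom_hyperparameters(Z, _single_batch(Z))
        est_mean = priors.Psi["a"] / (priors.nu["a"] - M - 1)
        rel = np.linalg.norm(est_mean - true_mean, "fro") / np.linalg.norm(true_mean, "fro")
        assert rel < 0.1

    def test_scalar_case_matches_inverse_gamma_mom(self):
        """With M=1 the dof formula reduces to scalar inverse-gamma moment
        matching: nu = 4 + 2*mean^2/var of the per-feature variances."""
        rng = np.random.default_rng(3)
        n, p = 200, 50
        scales = rng.uniform(0.5, 2.0, size=p)
        Z = rng.standard_normal((n, p, 1)) * np.sqrt(scales)[None, :, None]
        priors = mom_hyperparameters(Z, _single_batch(Z))
        S = Z[:, :, 0].var(axis=0, ddof=1)
        expected = max(1 + 3 + 2.0 * S.mean() ** 2 / S.var(ddof=1), 1 + 4)
        assert priors.nu["a"] == pytest.approx(expected, rel=1e-10)

    def test_too_small_batch_rejected(self, rng):
        Z = rng.standard_normal((6, 4, 6))
        with pytest.raises(ValueError, match="M\\+2"):
            mom_hyperparameters(Z, _single_batch(Z))


def _priors_for(Z, batch, t_scale=1.0):
    base = mom_hyperparameters(Z, batch)
    for b in base.batches:
        base.T[b] = t_scale * np.eye(Z.shape[2])
    return base


class TestEBPosteriors:
    def setup_method(self):
        rng = np.random.default_rng(17)
        self.Z = rng.standard_normal((60, 8, 3)) + rng.normal(0, 0.5, size=(8, 3))
        self.batch = _single_batch(self.Z)

    def test_no_shrinkage_limit(self):
        """T -> infinity: gamma* equals the per-feature batch mean."""
        priors = _priors_for(self.Z, self.batch, t_scale=1e8)
        post = eb_posteriors(self.Z, self.batch, priors)
        zbar = self.Z.mean(axis=0)
        np.testing.assert_allclose(post.gamma_star["a"], zbar, rtol=1e-4, atol=1e-4)

    def test_full_shrinkage_limit(self):
        """T -> 0: gamma* collapses to the prior mean."""
        priors = _priors_for(self.Z, self.batch, t_scale=1e-8)
        post = eb_posteriors(self.Z, self.batch, priors)
        expected = np.tile(priors.gamma_bar["a"], (8, 1))
        np.testing.assert_allclose(post.gamma_star["a"], expected, atol=1e-4)

    def test_fixed_point_equations_satisfied(self):
        """Substituting (gamma*, Sigma*) back into the two conditional
        posterior-mean equations reproduces them to < 1e-8."""
        priors = mom_hyperparameters(self.Z, self.batch)
        post = eb_posteriors(self.Z, self.batch, priors, tol=1e-12)
        b = "a"
        ni, p, M = self.Z.shape
        T_inv = np.linalg.inv(priors.T[b] + 1e-12 * np.eye(M))
        for v in range(p):
            g, S = post.gamma_star[b][v], post.sigma_star[b][v]
            Sinv = np.linalg.inv(S)
            zbar = self.Z[:, v, :].mean(axis=0)
            g_rhs = np.linalg.solve(ni * Sinv + T_inv,
                                    ni * Sinv @ zbar + T_inv @ priors.gamma_bar[b])
            dev = self.Z[:, v, :] - g
            S_rhs = (dev.T @ dev + priors.Psi[b]) / (ni + priors.nu[b] - M - 1)
            assert np.max(np.abs(g - g_rhs)) < 1e-8
            assert np.max(np.abs(S - S_rhs)) < 1e-8

    def test_univariate_reduction_is_convex_combination(self):
        """For M=1 the posterior mean lies between the batch mean and the
        prior mean with the familiar n/(n + sigma2/tau2) weight."""
        rng = np.random.default_rng(9)
        Z = rng.standard_normal((40, 6, 1)) + 0.5
        batch = _single_batch(Z)
        priors = _priors_for(Z, batch, t_scale=0.3)
        post = eb_posteriors(Z, batch, priors, tol=1e-12)
        n = Z.shape[0]
        for v in range(6):
            zbar = Z[:, v, 0].mean()
            gbar = priors.gamma_bar["a"][0]
            s2 = post.sigma_star["a"][v][0, 0]
            w = n / (n + s2 / 0.3)
            expected = w * zbar + (1 - w) * gbar
            assert post.gamma_star["a"][v][0] == pytest.approx(expected, rel=1e-6)
            lo, hi = sorted([zbar, gbar])
            assert lo - 1e-9 <= post.gamma_star["a"][v][0] <= hi + 1e-9


class TestAdjustResiduals:
    def test_identity_whitening(self, rng):
        Z = rng.standard_normal((20, 3, 2))
        batch = _single_batch(Z)
        from mvharmonize import BatchPosteriors
        post = BatchPosteriors(
            batches=["a"],
            gamma_star={"a": np.zeros((3, 2))},
            sigma_star={"a": np.tile(np.eye(2), (3, 1, 1))},
        )
        np.testing.assert_array_equal(adjust_residuals(Z, batch, post), Z)

    def test_scalar_scaling(self, rng):
        Z = rng.standard_normal((15, 2, 2))
        batch = _single_batch(Z)
        from mvharmonize import BatchPosteriors
        g = rng.standard_normal((2, 2))
        post = BatchPosteriors(
            batches=["a"],
            gamma_star={"a": g},
            sigma_star={"a": np.tile(4.0 * np.eye(2), (2, 1, 1))},
        )
        out = adjust_residuals(Z, batch, post)
        np.testing.assert_allclose(out, (Z - g) / 2.0, atol=1e-12)

    def test_sample_moment_whitening_gives_identity_covariance(self, rng):
        """Whitening with the sample moments produces exactly identity
        per-batch covariance."""
        n, p, M = 50, 4, 3
        Z = rng.standard_normal((n, p, M)) @ np.diag([1.0, 2.0, 0.5])
        batch = _single_batch(Z)
        from mvharmonize import BatchPosteriors
        gamma = Z.mean(axis=0)
        sigma = np.zeros((p, M, M))
        for v in range(p):
            sigma[v] = np.cov(Z[:, v, :], rowvar=False, ddof=1)
        post = BatchPosteriors(batches=["a"], gamma_star={"a": gamma},
                               sigma_star={"a": sigma})
        out = adjust_residuals(Z, batch, post)
        for v in range(p):
            C = np.cov(out[:, v, :], rowvar=False, ddof=1)
            np.testing.assert_allclose(C, np.eye(M), atol=1e-8)


class TestPipeline:
    def test_single_batch_identity(self):
        panel = make_panel(n=30, p=4, M=3, I=1, seed=5)
        with pytest.warns(UserWarning, match="single batch"):
            out, _ = mv_combat(panel, formula="age + sex")
        np.testing.assert_allclose(out.values, panel.values, atol=1e-8)

    def test_removes_covariance_batch_effects(self):
        """Simulated batch-specific cross-metric covariance: Box's M finds
        many affected features before harmonization and none after."""
        from mvharmonize import SimulationConfig, simulate_dataset
        cfg = SimulationConfig(n=240, p=25, M=4, seed=77)
        sim = simulate_dataset(cfg)
        frac_before = boxm_feature_fraction(sim.observed, "age + sex + diagnosis")
        out, _ = mv_combat(sim.observed, formula="age + sex + diagnosis")
        frac_after = boxm_feature_fraction(out, "age + sex + diagnosis")
        assert frac_before > 0.2
        assert frac_after <= 0.05

    def test_sigma_recovery_improves_with_sample_size(self):
        """Mean Frobenius error of Sigma* against the generating covariance
        decreases monotonically in n."""
        from mvharmonize import SimulationConfig, simulate_dataset
        from mvharmonize.fixed_effects import fit_fixed_effects, remove_fixed_effects
        from mvharmonize.panel import apply_standardization, fit_standardization
        errors = []
        for n in (50, 150, 500):
            errs = []
            for seed in (1, 2, 3):
                cfg = SimulationConfig(n=n, p=12, M=3, seed=seed)
                sim = simulate_dataset(cfg)
                out, post = mv_combat(sim.observed, formula="age + sex + diagnosis")
                model = fit_fixed_effects(sim.observed, "age + sex + diagnosis")
                Z = remove_fixed_effects(sim.observed, model)
                std = fit_standardization(Z)
                scale = std.scale  # Sigma* lives on the standardized scale
                err = 0.0
                for b in post.batches:
                    truth_cov = sim.truth["sigma"][b]
                    for v in range(cfg.p):
                        D = np.diag(1.0 / scale[v])
                        # true residual covariance = baseline + batch noise
                        truth_std = D @ (np.eye(cfg.M) + truth_cov[v]) @ D
                        err += np.linalg.norm(post.sigma_star[b][v] - truth_std, "fro")
                errs.append(err / (len(post.batches) * cfg.p))
            errors.append(np.mean(errs))
        assert errors[0] > errors[1] > errors[2]

    def test_eb_pipeline_is_deterministic(self):
        panel = make_panel(n=60, p=4, M=2, I=2, seed=10, batch_shift=[0.4, -0.4])
        out1, _ = mv_combat(panel, formula="age + sex")
        out2, _ = mv_combat(panel, formula="age + sex")
        np.testing.assert_array_equal(out1.values, out2.values)

    def test_small_batch_rejected(self):
        panel = make_panel(n=12, p=3, M=6, I=2, seed=2)
        with pytest.raises(ValueError, match="M\\+2"):
            mv_combat(panel, formula="age + sex")
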