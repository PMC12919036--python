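"""Multivariate ComBat: joint batch-effect harmonization across metrics.

For each feature v the M metric residuals of a subject are stacked into a
vector modelled as

    Z_ijv ~ N(gamma_iv, Sigma_iv)        (i = batch, j = subject)

with conjugate priors gamma_iv ~ N(gamma_i, T_i) and
Sigma_iv ~ InverseWishart(Psi_i, nu_i) shared across features within a
batch. Posterior means (gamma*, Sigma*) are computed either in closed form
by a joint fixed-point iteration of the two conditional posterior means
(empirical Bayes, method-of-moments hyperparameters) or by MCMC with an
LKJ correlation prior and half-t scale priors. Adjustment whitens each
residual vector by the symmetric inverse square root of Sigma*:

    Z*_ijv = Sigma*_iv^{-1/2} (Z_ijv - gamma*_iv)

so residuals land on a common location and covariance scale across
batches, after which fixed effects are restored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._linalg import RIDGE, ridge_psd, sym_inv_sqrt, sym_sqrt
from .fixed_effects import FixedEffectsModel, fit_fixed_effects, remove_fixed_effects
from .panel import (
    PanelData,
    apply_standardization,
    fit_standardization,
    invert_standardization,
)

__all__ = [
    "BatchPriors",
    "BatchPosteriors",
    "MCMCConfig",
    "mom_hyperparameters",
    "eb_posteriors",
    "mcmc_posteriors",
    "adjust_residuals",
    "mv_combat",
]


@dataclass
class BatchPriors:
    """Per-batch prior hyperparameters for the MV batch-effect model.

    ``gamma_bar[i]`` is the length-M normal prior mean, ``T[i]`` the M x M
    prior covariance of location effects across features; ``Psi[i]`` and
    ``nu[i]`` parameterize the inverse-Wishart prior on Sigma_iv, with
    prior mean Psi / (nu - M - 1).
    """

    batches: list
    gamma_bar: dict  # batch -> (M,)
    T: dict          # batch -> (M, M) PSD
    Psi: dict        # batch -> (M, M) PD
    nu: dict         # batch -> float > M + 3


@dataclass
class BatchPosteriors:
    """Posterior batch-effect estimates per (batch, feature)."""

    batches: list
    gamma_star: dict  # batch -> (p, M)
    sigma_star: dict  # batch -> (p, M, M) PD
    z_bar: dict = field(default_factory=dict)  # batch -> (p, M) sample means
    iterations: dict = field(default_factory=dict)
    converged: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)  # MCMC: rhat/ess summaries


def _batch_moments(Z: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature sample mean (p, M) and covariance (p, M, M) of one batch."""
    Zb = Z[mask]  # (n_i, p, M)
    zbar = Zb.mean(axis=0)
    D = Zb - zbar
    ni = Zb.shape[0]
    S = np.einsum("jpm,jpk->pmk", D, D) / max(ni - 1, 1)
    return zbar, S


def mom_hyperparameters(Z: np.ndarray, batch: np.ndarray) -> BatchPriors:
    """Method-of-moments prior hyperparameters from standardized residuals.

    Per batch: the normal prior's mean/covariance are the across-feature
    mean and covariance of the per-feature batch means; the IW degrees of
    freedom are solved from the across-feature dispersion of the diagonal
    second moments, Var_v(S_iv[mm]) = 2 * mean_v(S_iv[mm])^2 / (nu - M - 3)
    averaged over metrics and floored at M + 4, and the IW scale is set so
    the prior mean equals the average empirical covariance.
    """
    Z = np.asarray(Z, dtype=float)
    n, p, M = Z.shape
    if p < 2:
        raise ValueError("MoM hyperparameters need at least 2 features")
    batches = sorted(np.unique(batch).tolist())
    priors = BatchPriors(batches=batches, gamma_bar={}, T={}, Psi={}, nu={})
    for b in batches:
        mask = np.asarray(batch == b)
        ni = int(mask.sum())
        if ni < M + 2:
            raise ValueError(
                f"batch {b!r} has {ni} subjects; n_i >= M+2 = {M + 2} required"
            )
        zbar, S = _batch_moments(Z, mask)
        priors.gamma_bar[b] = zbar.mean(axis=0)
        priors.T[b] = np.cov(zbar, rowvar=False, ddof=1).reshape(M, M)
        S_mean = S.mean(axis=0)
        diag = S[:, np.arange(M), np.arange(M)]  # (p, M)
        var_diag = diag.var(axis=0, ddof=1)
        mean_diag = diag.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            nu_m = M + 3 + 2.0 * mean_diag ** 2 / var_diag
        nu_m = nu_m[np.isfinite(nu_m)]
        nu = float(np.mean(nu_m)) if nu_m.size else float(M + 4)
        nu = max(nu, M + 4.0)
        priors.nu[b] = nu
        priors.Psi[b] = ridge_psd((nu - M - 1.0) * S_mean, 0.0) + RIDGE * np.eye(M)
    return priors


def eb_posteriors(
    Z: np.ndarray,
    batch: np.ndarray,
    priors: BatchPriors,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> BatchPosteriors:
    """Closed-form EB posteriors by joint fixed-point iteration.

    The two conditional posterior means are mutually dependent:

        gamma* = (n Sigma*^-1 + T^-1)^-1 (n Sigma*^-1 zbar + T^-1 gamma_bar)
        Sigma* = (sum_j (Z_j - gamma*)(Z_j - gamma*)^T + Psi) / (n + nu - M - 1)

    They are alternated per (batch, feature) from (zbar, S + ridge) until
    the maximum elementwise change drops below ``tol``.
    """
    Z = np.asarray(Z, dtype=float)
    n, p, M = Z.shape
    batches = priors.batches
    post = BatchPosteriors(batches=batches, gamma_star={}, sigma_star={})
    for b in batches:
        mask = np.asarray(batch == b)
        Zb = Z[mask]
        ni = Zb.shape[0]
        if ni < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 subjects")
        zbar, S = _batch_moments(Z, mask)
        T = priors.T[b]
        try:
            T_inv = np.linalg.inv(ridge_psd(T, 0.0) + 1e-12 * np.eye(M))
        except np.linalg.LinAlgError:
            warnings.warn(f"singular prior covariance T for batch {b!r}; using pseudo-inverse")
            T_inv = np.linalg.pinv(T)
        gbar = priors.gamma_bar[b]
        Psi, nu = priors.Psi[b], priors.nu[b]
        denom = ni + nu - M - 1.0

        g_star = zbar.copy()                      # (p, M)
        s_star = S + RIDGE * np.eye(M)            # (p, M, M)
        it_count = np.zeros(p, dtype=int)
        conv = np.zeros(p, dtype=bool)
        for v in range(p):
            g, Sg = g_star[v], s_star[v]
            for it in range(max_iter):
                Sinv = np.linalg.inv(ridge_psd(Sg, 0.0) + 1e-12 * np.eye(M))
                A = ni * Sinv + T_inv
                rhs = ni * Sinv @ zbar[v] + T_inv @ gbar
                g_new = np.linalg.solve(A, rhs)
                d = zbar[v] - g_new
                scatter = (ni - 1) * S[v] + ni * np.outer(d, d)
                S_new = (scatter + Psi) / denom
                change = max(np.max(np.abs(g_new - g)), np.max(np.abs(S_new - Sg)))
                g, Sg = g_new, S_new
                if change < tol:
                    conv[v] = True
                    it_count[v] = it + 1
                    break
            else:
                it_count[v] = max_iter
                warnings.warn(
                    f"EB fixed point did not converge for batch {b!r}, feature {v}"
                )
            g_star[v], s_star[v] = g, ridge_psd(Sg, 0.0) + 1e-12 * np.eye(M)
        post.gamma_star[b] = g_star
        post.sigma_star[b] = s_star
        post.z_bar[b] = zbar
        post.iterations[b] = it_count
        post.converged[b] = conv
    return post


# ---------------------------------------------------------------------------
# MCMC estimation (ensemble sampler, LKJ + half-t priors)
# ---------------------------------------------------------------------------


@dataclass
class MCMCConfig:
    """Sampler settings for :func:`mcmc_posteriors`."""

    draws: int = 3000
    warmup: int = 1000
    walkers: int | None = None  # default: 2 * n_params rounded up to even
    chains: int = 4             # walker groups treated as chains for Rhat
    lkj_eta: float = 2.0
    halft_df: float = 3.0
    seed: int = 0
    rhat_limit: float = 1.01


def _vine_to_corr(partials: np.ndarray, M: int) -> np.ndarray:
    """C-vine partial correlations (upper-tri order) -> correlation matrix."""
    P = np.zeros((M, M))
    k = 0
    for i in range(M - 1):
        for j in range(i + 1, M):
            P[i, j] = partials[k]
            k += 1
    R = np.eye(M)
    for i in range(M - 1):
        for j in range(i + 1, M):
            r = P[i, j]
            for l in range(i - 1, -1, -1):
                r = r * np.sqrt((1 - P[l, i] ** 2) * (1 - P[l, j] ** 2)) + P[l, i] * P[l, j]
            R[i, j] = R[j, i] = r
    return R


def _lkj_beta_shapes(M: int, eta: float) -> np.ndarray:
    """Beta(b, b) shapes per C-vine partial correlation giving LKJ(eta)."""
    shapes = []
    for i in range(M - 1):
        b = eta + (M - 1 - (i + 1)) / 2.0
        shapes.extend([b] * (M - 1 - i))
    return np.array(shapes)


def _halft_logpdf(x: np.ndarray, df: float, scale: float) -> np.ndarray:
    return -0.5 * (df + 1.0) * np.log1p((x / scale) ** 2 / df)


def mcmc_posteriors(
    Z: np.ndarray,
    batch: np.ndarray,
    config: MCMCConfig | None = None,
) -> BatchPosteriors:
    """Fully Bayesian batch-effect posteriors via ensemble MCMC.

    Per (batch, feature) the model is Z_j ~ N(gamma, D R D) with
    D = diag(sigma), sigma_m ~ half-t(df, scale = pooled SD),
    R ~ LKJ(eta) through independent Beta partial correlations on the
    C-vine, and gamma ~ N(mu_i, tau_i^2 I) with plug-in hyperparameters
    from the across-feature moments of the batch means. Sampling uses an
    affine-invariant ensemble sampler; walker groups serve as chains for
    split-Rhat/ESS diagnostics, and the run is flagged failed when any
    Rhat >= ``rhat_limit``.
    """
    import arviz as az
    import emcee
    from scipy.stats import beta as beta_dist

    cfg = config or MCMCConfig()
    Z = np.asarray(Z, dtype=float)
    n, p, M = Z.shape
    n_corr = M * (M - 1) // 2
    dim = 2 * M + n_corr
    nwalkers = cfg.walkers or max(2 * dim + 2, 2 * cfg.chains)
    nwalkers += nwalkers % 2
    beta_shapes = _lkj_beta_shapes(M, cfg.lkj_eta)
    batches = sorted(np.unique(batch).tolist())
    post = BatchPosteriors(batches=batches, gamma_star={}, sigma_star={})
    rng = np.random.default_rng(cfg.seed)

    for b in batches:
        mask = np.asarray(batch == b)
        Zb = Z[mask]
        ni = Zb.shape[0]
        zbar, S = _batch_moments(Z, mask)
        # plug-in partial-pooling hyperparameters for gamma; with a single
        # feature there is no across-feature spread, so fall back to a
        # weakly informative prior scale
        mu_i = zbar.mean(axis=0)
        if p >= 2:
            tau2 = float(np.mean(zbar.var(axis=0, ddof=1)))
        else:
            tau2 = np.nan
        if not np.isfinite(tau2) or tau2 <= 0:
            tau2 = 100.0
        tau2 = max(tau2, 1e-6)
        pooled_sd = float(np.sqrt(np.mean(Zb.var(axis=0, ddof=1)))) if ni >= 2 else 1.0
        if not np.isfinite(pooled_sd) or pooled_sd <= 0:
            pooled_sd = 1.0

        g_star = np.zeros((p, M))
        s_star = np.zeros((p, M, M))
        rhat_max = np.zeros(p)
        ess_min = np.zeros(p)

        for v in range(p):
            Zv = Zb[:, v, :]
            zm = Zv.mean(axis=0) if ni else np.zeros(M)
            Sc = (Zv - zm).T @ (Zv - zm) if ni else np.zeros((M, M))

            def log_post(theta: np.ndarray) -> float:
                gamma = theta[:M]
                log_sig = theta[M:2 * M]
                u = theta[2 * M:]
                if np.any(np.abs(log_sig) > 15) or np.any(np.abs(u) > 15):
                    return -np.inf
                sig = np.exp(log_sig)
                r = np.tanh(u)
                R = _vine_to_corr(r, M)
                try:
                    L = np.linalg.cholesky(R + 1e-10 * np.eye(M))
                except np.linalg.LinAlgError:
                    return -np.inf
                lp = 0.0
                # LKJ via independent scaled Betas + tanh jacobian
                lp += float(np.sum(beta_dist.logpdf((r + 1) / 2, beta_shapes, beta_shapes)))
                lp += float(np.sum(np.log1p(-r ** 2)))  # d tanh
                lp += float(np.sum(_halft_logpdf(sig, cfg.halft_df, pooled_sd)))
                lp += float(np.sum(log_sig))  # Jacobian of exp
                lp += -0.5 * float(np.sum((gamma - mu_i) ** 2)) / tau2
                if ni:
                    # N(gamma, D R D) likelihood from sufficient statistics
                    logdet = 2.0 * float(np.sum(np.log(np.diag(L)))) + 2.0 * float(np.sum(log_sig))
                    Dinv = 1.0 / sig
                    W = (np.eye(M) * Dinv)
                    Sigma_inv = W @ np.linalg.inv(R + 1e-10 * np.eye(M)) @ W
                    d = zm - gamma
                    quad = float(np.trace(Sigma_inv @ Sc)) + ni * float(d @ Sigma_inv @ d)
                    lp += -0.5 * ni * logdet - 0.5 * quad
                if not np.isfinite(lp):
                    return -np.inf
                return lp

            start = np.concatenate([
                zm,
                0.5 * np.log(np.maximum(np.diag(S[v]), 1e-4)),
                np.zeros(n_corr),
            ])
            p0 = start + 0.05 * rng.standard_normal((nwalkers, dim))
            # differential-evolution moves mix far better than the default
            # stretch move in these moderately correlated posteriors
            moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
            sampler = emcee.EnsembleSampler(nwalkers, dim, log_post, moves=moves)
            state = sampler.run_mcmc(p0, cfg.warmup, progress=False,
                                     skip_initial_state_check=True)
            sampler.reset()
            sampler.run_mcmc(state, cfg.draws, progress=False,
                             skip_initial_state_check=True)
            chain = sampler.get_chain()  # (draws, walkers, dim)
            flat = chain.reshape(-1, dim)

            gammas = flat[:, :M]
            sigs = np.exp(flat[:, M:2 * M])
            Sig_draws = np.zeros((flat.shape[0], M, M))
            for t in range(flat.shape[0]):
                R = _vine_to_corr(np.tanh(flat[t, 2 * M:]), M)
                Sig_draws[t] = (sigs[t][:, None] * R) * sigs[t][None, :]
            g_star[v] = gammas.mean(axis=0)
            s_star[v] = ridge_psd(Sig_draws.mean(axis=0), 1e-10)

            # diagnostics: evenly spaced walkers serve as chains
            idx = np.linspace(0, nwalkers - 1, cfg.chains).astype(int)
            arr = chain[:, idx, :].transpose(1, 0, 2)  # (chain, draw, dim)
            idata = az.convert_to_dataset(arr)
            rh = az.rhat(idata)["x"].values
            es = az.ess(idata)["x"].values
            rhat_max[v] = float(np.nanmax(rh))
            ess_min[v] = float(np.nanmin(es))

        post.gamma_star[b] = g_star
        post.sigma_star[b] = s_star
        post.z_bar[b] = zbar
        post.diagnostics[b] = {
            "rhat_max": rhat_max,
            "ess_min": ess_min,
            "passed": bool(np.all(rhat_max < cfg.rhat_limit)),
        }
        if not post.diagnostics[b]["passed"]:
            warnings.warn(
                f"MCMC convergence check failed for batch {b!r}: "
                f"max Rhat = {rhat_max.max():.3f} >= {cfg.rhat_limit}"
            )
    return post


# ---------------------------------------------------------------------------
# Adjustment and full pipeline
# ---------------------------------------------------------------------------


def adjust_residuals(
    Z: np.ndarray, batch: np.ndarray, posteriors: BatchPosteriors
) -> np.ndarray:
    """Whiten residuals: ``Z* = Sigma*^{-1/2} (Z - gamma*)`` per (batch, feature).

    Uses the symmetric (spectral) inverse square root with eigenvalues
    floored at 1e-10, so the transform is basis-independent and symmetric
    under metric reordering.
    """
    Z = np.asarray(Z, dtype=float)
    out = Z.copy()
    p = Z.shape[1]
    for b in posteriors.batches:
        mask = np.asarray(batch == b)
        g = posteriors.gamma_star[b]
        s = posteriors.sigma_star[b]
        for v in range(p):
            W = sym_inv_sqrt(s[v])
            out[mask, v, :] = (Z[mask, v, :] - g[v]) @ W.T
    return out


def mv_combat(
    data: PanelData,
    formula: str | None = None,
    estimator: str = "eb",
    model: FixedEffectsModel | None = None,
    fe_kind: str = "linear",
    recolor: str = "none",
    tol: float = 1e-6,
    max_iter: int = 100,
    mcmc_config: MCMCConfig | None = None,
) -> tuple[PanelData, BatchPosteriors]:
    """End-to-end MV-ComBat harmonization.

    Pipeline: fit fixed effects -> remove -> standardize (pooled SD) ->
    estimate batch posteriors (``estimator='eb'`` or ``'mcmc'``) ->
    whiten -> invert standardization -> restore fixed effects. With
    ``recolor='pooled'`` the whitened residuals are re-multiplied by the
    square root of the pooled across-batch residual covariance before
    de-standardizing, giving a pooled rather than identity residual target
    on the standardized scale.

    A single-batch panel is returned unchanged (with a warning): there is
    nothing to harmonize.
    """
    if estimator not in {"eb", "mcmc"}:
        raise ValueError(f"unknown estimator {estimator!r}")
    if recolor not in {"none", "pooled"}:
        raise ValueError(f"unknown recolor mode {recolor!r}")
    if len(data.batches) < 2:
        warnings.warn("single batch: returning input unchanged")
        M = data.n_metrics
        b = data.batches[0] if data.batches else None
        post = BatchPosteriors(
            batches=data.batches,
            gamma_star={b: np.zeros((data.n_features, M))} if b is not None else {},
            sigma_star={b: np.tile(np.eye(M), (data.n_features, 1, 1))} if b is not None else {},
        )
        return data.with_values(data.values), post
    M = data.n_metrics
    for b, ni in data.batch_sizes().items():
        if ni < M + 2:
            raise ValueError(
                f"batch {b!r} has {ni} subjects; n_i >= M+2 = {M + 2} required "
                "for multivariate covariance estimation"
            )

    if model is None:
        model = fit_fixed_effects(data, formula, kind=fe_kind)
    Z = remove_fixed_effects(data, model)
    std = fit_standardization(Z, mode="pooled_sd")
    Zs = apply_standardization(Z, std)

    if estimator == "eb":
        priors = mom_hyperparameters(Zs, data.batch)
        post = eb_posteriors(Zs, data.batch, priors, tol=tol, max_iter=max_iter)
    else:
        post = mcmc_posteriors(Zs, data.batch, config=mcmc_config)

    Zadj = adjust_residuals(Zs, data.batch, post)
    if recolor == "pooled":
        p = Zs.shape[1]
        for v in range(p):
            pooled = np.cov(Zs[:, v, :], rowvar=False, ddof=1)
            C = sym_sqrt(ridge_psd(pooled))
            Zadj[:, v, :] = Zadj[:, v, :] @ C.T
    Zstar = invert_standardization(Zadj, std)
    harmonized = data.with_values(model.fitted(data.covariates) + Zstar)
    return harmonized, post
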