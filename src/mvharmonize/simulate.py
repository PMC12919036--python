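"""Synthetic multi-metric panel generation with ground-truth bookkeeping.

Three batch-effect scenarios are supported on top of a common baseline of
covariate-driven biological signal plus unit Gaussian noise:

* ``concordant`` — location shifts gamma_iv ~ N(gamma_i, T_i) and
  covariances Sigma_iv drawn from an inverse-Wishart, matching the EB
  model assumed by MV-ComBat;
* ``misspecified`` — Sigma_iv drawn from a weighted mixture of covariance
  families (IW, LKJ, FA, AR, CS), stressing the exchangeable IW prior;
* ``latent`` — batch effects injected through a batch-specific affine
  rotation, shift and noise of the shared latent scores, producing
  correlated low-rank distortions across features and metrics.

Every generator records the exact injected batch term, so
``observed - gold`` reproduces it bit-for-bit and harmonizers can be
scored against the batch-free gold standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from ._linalg import is_pd
from .panel import PanelData

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "gen_baseline",
    "draw_batch_covariance",
    "draw_lkj_correlation",
    "gen_feature_batch_effects",
    "gen_latent_batch_effects",
    "simulate_dataset",
]

#: mixture weights over (IW, LKJ, FA, AR, CS) in the misspecified scenario
MIXTURE_FAMILIES = ("IW", "LKJ", "FA", "AR", "CS")
MIXTURE_WEIGHTS = (0.20, 0.30, 0.20, 0.20, 0.10)


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic panel generators.

    The defaults encode the *regular* (mild batch effects) condition:
    per-batch metric offsets gamma_i ~ N(0, gamma_scale^2), feature-level
    location spread T_i = t_scale * I, and batch covariances with
    inverse-Wishart prior mean ``iw_mean_scale * I`` at ``nu = M + nu_extra``
    degrees of freedom. The stress condition triples the location offsets
    and doubles the covariance scale (``stress_gamma_mult`` /
    ``stress_cov_mult``).
    """

    I: int = 3
    p: int = 70
    M: int = 6
    n: int = 500
    scenario: str = "concordant"   # concordant | misspecified | latent
    condition: str = "regular"     # regular | stress
    # covariate effects
    beta_age: float = 0.05
    beta_sex: float = 0.5
    beta_diag_weak: float = 0.2
    beta_diag_strong: float = 0.6
    biomarker_fraction: float = 0.6
    # feature-wise batch-effect magnitudes (regular condition)
    gamma_scale: float = 1.0
    t_scale: float = 0.4
    nu_extra: float = 3.0
    iw_mean_scale: float = 0.5
    # fraction of features whose noise covariance differs across batches;
    # the rest share one draw across batches (scanner-insensitive features)
    cov_effect_fraction: float = 0.73
    # among affected features, the fraction whose batch effect alters the
    # cross-metric correlation as well; the rest differ in marginal scales
    # only (removable by per-metric harmonization)
    corr_effect_fraction: float = 0.66
    stress_gamma_mult: float = 3.0
    stress_cov_mult: float = 2.0
    mixture_weights: tuple = MIXTURE_WEIGHTS
    # latent-scenario magnitudes
    angle_scale: float = 0.5
    mu_scale: float = 1.0
    latent_noise_scale: float = 0.5
    latent_var_fraction: float = 0.95
    replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if self.scenario not in {"concordant", "misspecified", "latent"}:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.condition not in {"regular", "stress"}:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.nu() <= self.M + 1:
            raise ValueError("IW degrees of freedom must exceed M + 1")

    def nu(self) -> float:
        return self.M + self.nu_extra

    def effective_gamma_scale(self) -> float:
        mult = self.stress_gamma_mult if self.condition == "stress" else 1.0
        return self.gamma_scale * mult

    def effective_cov_scale(self) -> float:
        mult = self.stress_cov_mult if self.condition == "stress" else 1.0
        return self.iw_mean_scale * mult

    def batch_sizes(self) -> list[int]:
        base = self.n // self.I
        sizes = [base] * self.I
        sizes[-1] += self.n - base * self.I
        return sizes


@dataclass
class SimulatedDataset:
    """Paired gold-standard and unharmonized panels plus generator truth."""

    gold: PanelData
    observed: PanelData
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Baseline (batch-free) data
# ---------------------------------------------------------------------------


def gen_baseline(config: SimulationConfig, rng: np.random.Generator | int = 0):
    """Generate the batch-free gold standard panel and its truth record.

    Age ~ N(50, 10^2), Sex ~ Bernoulli(0.5), Diagnosis ~ Bernoulli(0.3);
    a random biomarker subset of size round(0.6 p) carries diagnosis
    effects — weak on the first two metrics, strong on the remaining ones.
    Baseline noise is i.i.d. N(0, 1).
    """
    rng = np.random.default_rng(rng)
    n, p, M = config.n, config.p, config.M
    age = rng.normal(50.0, 10.0, size=n)
    sex = rng.binomial(1, 0.5, size=n).astype(float)
    diag = rng.binomial(1, 0.3, size=n).astype(float)
    n_bio = int(round(config.biomarker_fraction * p))
    biomarkers = np.sort(rng.choice(p, size=n_bio, replace=False))

    beta_age = np.full((p, M), config.beta_age)
    beta_sex = np.full((p, M), config.beta_sex)
    beta_diag = np.zeros((p, M))
    n_weak = min(2, M)
    beta_diag[biomarkers, :n_weak] = config.beta_diag_weak
    beta_diag[biomarkers, n_weak:] = config.beta_diag_strong

    noise = rng.standard_normal((n, p, M))
    values = (
        noise
        + age[:, None, None] * beta_age
        + sex[:, None, None] * beta_sex
        + diag[:, None, None] * beta_diag
    )
    covariates = pd.DataFrame({"age": age, "sex": sex, "diagnosis": diag})
    batch_labels = np.concatenate(
        [np.full(sz, f"site{i + 1}") for i, sz in enumerate(config.batch_sizes())]
    )
    gold = PanelData(
        values=values,
        batch=batch_labels,
        covariates=covariates,
        feature_ids=[f"roi{v + 1:03d}" for v in range(p)],
        metric_ids=[f"m{m + 1}" for m in range(M)],
    )
    truth = {
        "biomarkers": biomarkers,
        "beta_age": beta_age,
        "beta_sex": beta_sex,
        "beta_diag": beta_diag,
        "noise": noise,
    }
    return gold, truth


# ---------------------------------------------------------------------------
# Covariance families
# ---------------------------------------------------------------------------


def draw_lkj_correlation(M: int, eta: float, rng: np.random.Generator) -> np.ndarray:
    """Draw a correlation matrix from LKJ(eta) via the C-vine construction.

    Partial correlations on the vine are independent scaled
    Beta(b_i, b_i) variables with b_i = eta + (M - 1 - i) / 2 (row i,
    1-based), which induces the LKJ density on the resulting matrix.
    """
    P = np.zeros((M, M))
    for i in range(M - 1):
        b = eta + (M - 1 - (i + 1)) / 2.0
        P[i, i + 1:] = 2.0 * rng.beta(b, b, size=M - 1 - i) - 1.0
    R = np.eye(M)
    for i in range(M - 1):
        for j in range(i + 1, M):
            r = P[i, j]
            for l in range(i - 1, -1, -1):
                r = r * np.sqrt((1 - P[l, i] ** 2) * (1 - P[l, j] ** 2)) + P[l, i] * P[l, j]
            R[i, j] = R[j, i] = r
    return R


def draw_batch_covariance(
    family: str, M: int, params: dict, rng: np.random.Generator
) -> np.ndarray:
    """Draw one M x M positive-definite covariance from the named family.

    Families: ``IW`` (Psi, nu), ``LKJ`` (eta, sd), ``FA`` (q factors,
    scale), ``AR`` (sigma2, rho with |rho| < 1) and ``CS`` (sigma2, rho).
    """
    if family == "IW":
        Sigma = invwishart.rvs(df=params["nu"], scale=params["Psi"], random_state=rng)
        Sigma = np.atleast_2d(Sigma)
    elif family == "LKJ":
        R = draw_lkj_correlation(M, params.get("eta", 2.0), rng)
        sd = np.asarray(params["sd"], dtype=float) * np.ones(M)
        Sigma = (sd[:, None] * R) * sd[None, :]
    elif family == "FA":
        q = int(params.get("q", 2))
        if q >= M:
            raise ValueError("FA requires fewer factors than metrics")
        scale = float(params["scale"])
        lam = rng.standard_normal((M, q)) * np.sqrt(scale / 2.0)
        d = rng.uniform(0.2, 1.0, size=M) * scale / 2.0
        Sigma = lam @ lam.T + np.diag(d)
    elif family in {"AR", "CS"}:
        rho = float(params["rho"])
        if not -1.0 < rho < 1.0:
            raise ValueError("AR/CS correlation must satisfy |rho| < 1")
        s2 = float(params["sigma2"])
        if family == "AR":
            idx = np.arange(M)
            Sigma = s2 * rho ** np.abs(idx[:, None] - idx[None, :])
        else:
            Sigma = s2 * ((1 - rho) * np.eye(M) + rho * np.ones((M, M)))
    else:
        raise ValueError(f"unknown covariance family {family!r}")
    if not is_pd(Sigma):
        raise ValueError(f"drawn {family} covariance is not positive definite")
    return Sigma


def _draw_sigma(config: SimulationConfig, rng: np.random.Generator) -> tuple[str, np.ndarray]:
    """One batch-feature covariance draw under the configured scenario."""
    M = config.M
    scale = config.effective_cov_scale()
    nu = config.nu()
    if config.scenario != "misspecified":
        fam = "IW"
    else:
        fam = MIXTURE_FAMILIES[rng.choice(len(MIXTURE_FAMILIES), p=np.asarray(config.mixture_weights))]
    if fam == "IW":
        Sigma = draw_batch_covariance(
            "IW", M, {"nu": nu, "Psi": (nu - M - 1.0) * scale * np.eye(M)}, rng
        )
    elif fam == "LKJ":
        Sigma = draw_batch_covariance("LKJ", M, {"eta": 2.0, "sd": np.sqrt(scale)}, rng)
    elif fam == "FA":
        Sigma = draw_batch_covariance("FA", M, {"q": 2, "scale": scale}, rng)
    else:  # AR / CS
        rho = rng.uniform(0.2, 0.8) if fam == "AR" else rng.uniform(0.1, 0.6)
        Sigma = draw_batch_covariance(fam, M, {"sigma2": scale, "rho": rho}, rng)
    return fam, Sigma


# ---------------------------------------------------------------------------
# Feature-wise batch effects
# ---------------------------------------------------------------------------


def gen_feature_batch_effects(
    config: SimulationConfig,
    gold: PanelData,
    truth: dict,
    rng: np.random.Generator | int = 0,
) -> SimulatedDataset:
    """Inject per-(batch, feature) location and covariance batch effects.

    gamma_iv ~ N(gamma_i, T_i) with gamma_i ~ N(0, gamma_scale^2) per
    metric and T_i = t_scale * I; Sigma_iv drawn from the configured
    scenario's covariance law; each subject of batch i then receives
    ``gamma_iv + N(0, Sigma_iv)`` noise on top of the gold values.
    """
    rng = np.random.default_rng(rng)
    n, p, M = gold.values.shape
    masks = gold.batch_indices()
    g_scale = config.effective_gamma_scale()

    # features whose covariance differs across batches; the rest get one
    # shared covariance draw (location shifts still apply everywhere)
    n_cov = int(round(config.cov_effect_fraction * p))
    cov_affected = np.zeros(p, dtype=bool)
    cov_affected[rng.choice(p, size=n_cov, replace=False)] = True
    affected_idx = np.flatnonzero(cov_affected)
    n_corr = int(round(config.corr_effect_fraction * len(affected_idx)))
    corr_affected = np.zeros(p, dtype=bool)
    if len(affected_idx):
        corr_affected[rng.choice(affected_idx, size=n_corr, replace=False)] = True
    # shared structure for features without (full) covariance batch effects
    shared = {v: _draw_sigma(config, rng) for v in np.flatnonzero(~corr_affected)}

    def _corr_of(S: np.ndarray) -> np.ndarray:
        sd = np.sqrt(np.diag(S))
        return S / np.outer(sd, sd)

    gamma = {}
    sigma = {}
    families = {}
    injected = np.zeros_like(gold.values)
    for b, mask in masks.items():
        gamma_i = rng.normal(0.0, g_scale, size=M)
        gam_iv = gamma_i + rng.normal(0.0, np.sqrt(config.t_scale), size=(p, M))
        sig_iv = np.zeros((p, M, M))
        fams = []
        ni = int(mask.sum())
        eps = np.zeros((ni, p, M))
        for v in range(p):
            if corr_affected[v]:
                fam, S = _draw_sigma(config, rng)
            elif cov_affected[v]:
                # scale-only batch effect: batch-specific marginal SDs on a
                # correlation structure shared across batches
                fam, S_draw = _draw_sigma(config, rng)
                sd = np.sqrt(np.diag(S_draw))
                S = np.outer(sd, sd) * _corr_of(shared[v][1])
            else:
                fam, S = shared[v]
            sig_iv[v] = S
            fams.append(fam)
            L = np.linalg.cholesky(S + 1e-12 * np.eye(M))
            eps[:, v, :] = rng.standard_normal((ni, M)) @ L.T
        injected[mask] = gam_iv + eps
        gamma[b] = gam_iv
        sigma[b] = sig_iv
        families[b] = fams

    observed = gold.with_values(gold.values + injected)
    out_truth = dict(truth)
    out_truth.update(
        gamma=gamma, sigma=sigma, families=families, cov_affected=cov_affected,
        corr_affected=corr_affected,
        # recorded as the realized difference so the bookkeeping is bit-exact
        injected=observed.values - gold.values,
        scenario=config.scenario, condition=config.condition,
    )
    return SimulatedDataset(gold=gold, observed=observed, truth=out_truth)


# ---------------------------------------------------------------------------
# Latent-space batch effects
# ---------------------------------------------------------------------------


def _random_rotation(r: int, angle_scale: float, rng: np.random.Generator) -> np.ndarray:
    """Orthogonal matrix blending identity with a random rotation.

    ``(1 - a) I + a Q`` (Q from QR of a Gaussian matrix) projected back to
    the orthogonal group via polar decomposition; ``a = 0`` is exactly the
    identity.
    """
    if angle_scale == 0:
        return np.eye(r)
    Q, Rm = np.linalg.qr(rng.standard_normal((r, r)))
    Q = Q * np.sign(np.diag(Rm))
    B = (1.0 - angle_scale) * np.eye(r) + angle_scale * Q
    U, _, Vt = np.linalg.svd(B)
    return U @ Vt


def gen_latent_batch_effects(
    config: SimulationConfig,
    gold: PanelData,
    truth: dict,
    rng: np.random.Generator | int = 0,
) -> SimulatedDataset:
    """Inject batch effects through the shared latent score space.

    The gold noise tensor (baseline residuals with covariate effects
    removed) is decomposed per metric by PCA; a shared orthonormal score
    matrix G is estimated as in MV-CovBat. Each batch's rows of G are then
    rotated (identity blended with a random rotation by ``angle_scale``),
    shifted by a batch-specific mean and perturbed with Gaussian noise;
    the difference is propagated back through A^(m) and L^(m) and added to
    the gold data, yielding correlated low-rank batch distortions.
    """
    from .mv_covbat import metric_pca, shared_subspace

    rng = np.random.default_rng(rng)
    n, p, M = gold.values.shape
    noise = truth["noise"]  # (n, p, M) baseline residuals

    F_list, L_list = [], []
    for mi in range(M):
        Rm = noise[:, :, mi]
        Rc = Rm - Rm.mean(axis=0)
        F, L, _ = metric_pca(Rc, var_fraction=config.latent_var_fraction)
        F_list.append(F)
        L_list.append(L)
    G, A_list, _ = shared_subspace(F_list, var_fraction_shared=config.latent_var_fraction)
    r_s = G.shape[1]
    col_sd = 1.0 / np.sqrt(n)  # orthonormal columns have ~1/sqrt(n) entries

    masks = gold.batch_indices()
    injected = np.zeros_like(gold.values)
    rotations, shifts = {}, {}
    for b, mask in masks.items():
        R_i = _random_rotation(r_s, config.angle_scale, rng)
        mu_i = rng.normal(0.0, config.mu_scale * col_sd, size=r_s)
        ni = int(mask.sum())
        E = rng.normal(0.0, config.latent_noise_scale * col_sd, size=(ni, r_s))
        G_new = G[mask] @ R_i + mu_i + E
        dG = G_new - G[mask]
        for mi in range(M):
            injected[mask, :, mi] += dG @ A_list[mi] @ L_list[mi].T
        rotations[b] = R_i
        shifts[b] = mu_i

    observed = gold.with_values(gold.values + injected)
    out_truth = dict(truth)
    out_truth.update(
        injected=observed.values - gold.values, rotations=rotations, shifts=shifts,
        scenario="latent", condition=config.condition, G=G,
    )
    return SimulatedDataset(gold=gold, observed=observed, truth=out_truth)


def simulate_dataset(config: SimulationConfig, seed: int | None = None) -> SimulatedDataset:
    """Generate one full (gold, observed) pair under the configured scenario."""
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence([int(seed) % (2 ** 31), 17])
    rng_base, rng_batch = [np.random.default_rng(s) for s in ss.spawn(2)]
    gold, truth = gen_baseline(config, rng_base)
    if config.scenario == "latent":
        return gen_latent_batch_effects(config, gold, truth, rng_batch)
    return gen_feature_batch_effects(config, gold, truth, rng_batch)
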