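"""Harmonization evaluation battery.

Covers three complementary views of residual batch structure: univariate
and multivariate location/scale tests (ANOVA, Kruskal-Wallis, Levene,
Bartlett, Fligner-Killeen, MANOVA, Box's M), machine-learning batch
detection (stratified cross-validated random forests scored by macro
AUC), correlation-structure distances (Frobenius, elementwise MSE,
eigenvalue error, spectral norm), covariate signal preservation with
Benjamini-Hochberg FDR control, and checks of the EB prior assumptions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._linalg import ridge_psd
from .fixed_effects import FixedEffectsModel, fit_fixed_effects, remove_fixed_effects
from .mv_combat import BatchPosteriors, BatchPriors
from .panel import PanelData

__all__ = [
    "EvalReport",
    "univariate_batch_tests",
    "boxm_test",
    "boxm_feature_fraction",
    "manova_batch",
    "rf_batch_auc",
    "correlation_distances",
    "signal_preservation",
    "eb_prior_checks",
    "mcmc_diagnostics",
    "benjamini_hochberg",
]

UNIVARIATE_TESTS = ("anova", "kruskal", "levene", "bartlett", "fligner")
DISTANCE_NAMES = ("frobenius", "mse", "eigenvalue", "spectral")


@dataclass
class EvalReport:
    """Container aggregating the evaluation outputs of one dataset."""

    univariate: pd.DataFrame | None = None       # per-slice Bonferroni p-values
    boxm: pd.DataFrame | None = None             # per-feature Box's M
    manova: pd.DataFrame | None = None           # per-feature Pillai p-values
    auc: dict = field(default_factory=dict)      # metric -> macro AUC
    distances: dict = field(default_factory=dict)
    signal: dict = field(default_factory=dict)
    prior_checks: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


def _residuals(data: PanelData, formula: str | None,
               model: FixedEffectsModel | None) -> np.ndarray:
    if model is None:
        model = fit_fixed_effects(data, formula)
    return remove_fixed_effects(data, model)


# ---------------------------------------------------------------------------
# Univariate tests
# ---------------------------------------------------------------------------


def univariate_batch_tests(
    data: PanelData,
    formula: str | None = None,
    model: FixedEffectsModel | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-slice location/scale batch tests with Bonferroni correction.

    ANOVA and Kruskal-Wallis test mean differences; Levene, Bartlett and
    Fligner-Killeen test scale differences. Residuals (after fixed-effect
    removal) are tested; p-values are Bonferroni-corrected within each
    test family over all ``p * M`` slices. Zero-variance slices yield NA.
    """
    Z = _residuals(data, formula, model)
    n, p, M = Z.shape
    masks = list(data.batch_indices().values())
    if len(masks) < 2:
        raise ValueError("batch tests need at least 2 batches")
    rows = []
    for v in range(p):
        for m in range(M):
            groups = [Z[mask, v, m] for mask in masks]
            rec = {"feature": data.feature_ids[v], "metric": data.metric_ids[m]}
            if any(np.allclose(g, g[0]) for g in groups):
                warnings.warn(f"zero-variance slice ({v},{m}); p-values set to NA")
                for t in UNIVARIATE_TESTS:
                    rec[t] = np.nan
            else:
                rec["anova"] = stats.f_oneway(*groups).pvalue
                rec["kruskal"] = stats.kruskal(*groups).pvalue
                rec["levene"] = stats.levene(*groups).pvalue
                rec["bartlett"] = stats.bartlett(*groups).pvalue
                rec["fligner"] = stats.fligner(*groups).pvalue
            rows.append(rec)
    df = pd.DataFrame(rows)
    n_tests = p * M
    for t in UNIVARIATE_TESTS:
        df[t + "_bonf"] = np.minimum(df[t] * n_tests, 1.0)
        df[t + "_significant"] = df[t + "_bonf"] < alpha
    return df


# ---------------------------------------------------------------------------
# Multivariate tests
# ---------------------------------------------------------------------------


def boxm_test(groups: list[np.ndarray]) -> tuple[float, int, float]:
    """Box's M test of covariance homogeneity across groups.

    ``groups`` is a list of (n_i, d) arrays. Returns (chi2 statistic,
    degrees of freedom, p-value) using the standard chi-square
    approximation; singular group covariances are ridged with a warning.
    """
    I = len(groups)
    if I < 2:
        raise ValueError("Box's M needs at least 2 groups")
    d = groups[0].shape[1]
    ns = np.array([g.shape[0] for g in groups])
    if np.any(ns < 2):
        raise ValueError("each group needs at least 2 observations")
    N = int(ns.sum())
    covs = []
    for g in groups:
        S = np.cov(g, rowvar=False, ddof=1).reshape(d, d)
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            warnings.warn("singular group covariance in Box's M; adding ridge")
            S = ridge_psd(S, 1e-8)
        covs.append(S)
    S_pool = sum((ni - 1) * S for ni, S in zip(ns, covs)) / (N - I)
    sign, logdet_pool = np.linalg.slogdet(S_pool)
    if sign <= 0:
        S_pool = ridge_psd(S_pool, 1e-8)
        _, logdet_pool = np.linalg.slogdet(S_pool)
    Mstat = (N - I) * logdet_pool - sum(
        (ni - 1) * np.linalg.slogdet(S)[1] for ni, S in zip(ns, covs)
    )
    c1 = (np.sum(1.0 / (ns - 1)) - 1.0 / (N - I)) * (
        (2 * d * d + 3 * d - 1) / (6.0 * (d + 1) * (I - 1))
    )
    chi2 = float(Mstat * (1.0 - c1))
    df = int((I - 1) * d * (d + 1) / 2)
    pval = float(stats.chi2.sf(chi2, df))
    return chi2, df, pval


def _per_feature_residual_groups(data: PanelData, Z: np.ndarray):
    masks = data.batch_indices()
    for v in range(data.n_features):
        yield v, [Z[mask, v, :] for mask in masks.values()]


def boxm_by_feature(
    data: PanelData,
    formula: str | None = None,
    model: FixedEffectsModel | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Box's M across batches for every feature's M-metric residual block."""
    Z = _residuals(data, formula, model)
    rows = []
    for v, groups in _per_feature_residual_groups(data, Z):
        chi2, df, pval = boxm_test(groups)
        rows.append({"feature": data.feature_ids[v], "chi2": chi2, "df": df, "pval": pval})
    out = pd.DataFrame(rows)
    out["pval_bonf"] = np.minimum(out["pval"] * len(out), 1.0)
    out["significant"] = out["pval_bonf"] < alpha
    return out


def boxm_feature_fraction(
    data: PanelData,
    formula: str | None = None,
    model: FixedEffectsModel | None = None,
    alpha: float = 0.05,
) -> float:
    """Fraction of features with Bonferroni-significant Box's M."""
    return float(boxm_by_feature(data, formula, model, alpha)["significant"].mean())


def manova_batch(
    data: PanelData,
    formula: str | None = None,
    model: FixedEffectsModel | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature MANOVA (Pillai's trace) of batch on the metric vector.

    Uses the standard F approximation of Pillai's trace computed from the
    between/within SSCP matrices; Bonferroni correction across features.
    """
    Z = _residuals(data, formula, model)
    d = data.n_metrics
    I = len(data.batches)
    rows = []
    for v, groups in _per_feature_residual_groups(data, Z):
        allz = np.vstack(groups)
        grand = allz.mean(axis=0)
        H = np.zeros((d, d))
        E = np.zeros((d, d))
        for g in groups:
            mu = g.mean(axis=0)
            H += g.shape[0] * np.outer(mu - grand, mu - grand)
            C = g - mu
            E += C.T @ C
        N = allz.shape[0]
        evals = np.linalg.eigvals(np.linalg.solve(E + H + 1e-12 * np.eye(d), H))
        V = float(np.real(np.sum(evals)))
        s = min(d, I - 1)
        m_ = (abs(d - I + 1) - 1) / 2.0
        n_ = (N - I - d - 1) / 2.0
        df1 = s * (2 * m_ + s + 1)
        df2 = s * (2 * n_ + s + 1)
        F = (df2 / df1) * V / max(s - V, 1e-12)
        pval = float(stats.f.sf(F, df1, df2))
        rows.append({"feature": data.feature_ids[v], "pillai": V, "F": F, "pval": pval})
    out = pd.DataFrame(rows)
    out["pval_bonf"] = np.minimum(out["pval"] * len(out), 1.0)
    out["significant"] = out["pval_bonf"] < alpha
    return out


# ---------------------------------------------------------------------------
# Random-forest batch detection
# ---------------------------------------------------------------------------


def rf_batch_auc(
    data: PanelData,
    metric: str,
    n_estimators: int = 100,
    n_splits: int = 10,
    seed: int = 0,
) -> float:
    """Macro one-vs-rest AUC of a stratified K-fold random-forest batch classifier.

    Features are the ``p`` values of one metric; the forest (100 trees,
    library defaults otherwise) predicts the batch label. Per-fold macro
    AUC is averaged over folds. Values near 0.5 indicate no detectable
    batch signal; near 1.0, strong residual batch effects.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold

    mi = data.metric_ids.index(metric)
    X = data.values[:, :, mi]
    y = np.asarray(data.batch).astype(str)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("batch prediction needs at least 2 batches")
    for c in classes:
        if np.sum(y == c) < n_splits:
            raise ValueError(f"batch {c!r} has fewer subjects than folds")
    seed = int(seed) % (2 ** 31)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    aucs = []
    for k, (tr, te) in enumerate(skf.split(X, y)):
        clf = RandomForestClassifier(n_estimators=n_estimators,
                                     random_state=(seed * 1000 + k) % (2 ** 31))
        clf.fit(X[tr], y[tr])
        proba = clf.predict_proba(X[te])
        if len(classes) == 2:
            auc = roc_auc_score(y[te], proba[:, 1])
        else:
            auc = roc_auc_score(y[te], proba, multi_class="ovr", average="macro",
                                labels=clf.classes_)
        aucs.append(auc)
    return float(np.mean(aucs))


def rf_batch_auc_all_metrics(data: PanelData, seed: int = 0, **kw) -> dict:
    """Macro AUC per metric (seed derived per metric for reproducibility)."""
    return {
        m: rf_batch_auc(data, m, seed=(seed + 7919 * mi) % (2 ** 31), **kw)
        for mi, m in enumerate(data.metric_ids)
    }


# ---------------------------------------------------------------------------
# Correlation-structure distances
# ---------------------------------------------------------------------------


def matrix_distances(C: np.ndarray, C2: np.ndarray) -> dict:
    """Four distances between symmetric matrices C and C2.

    Frobenius norm, elementwise MSE, mean absolute difference of
    descending-sorted eigenvalues, and spectral norm of the difference.
    """
    D = np.asarray(C, dtype=float) - np.asarray(C2, dtype=float)
    ev1 = np.sort(np.linalg.eigvalsh(0.5 * (C + C.T)))[::-1]
    ev2 = np.sort(np.linalg.eigvalsh(0.5 * (C2 + C2.T)))[::-1]
    return {
        "frobenius": float(np.linalg.norm(D, "fro")),
        "mse": float(np.mean(D ** 2)),
        "eigenvalue": float(np.mean(np.abs(ev1 - ev2))),
        "spectral": float(np.linalg.norm(D, 2)),
    }


def _corr(X: np.ndarray) -> np.ndarray:
    C = np.corrcoef(X, rowvar=False)
    return np.nan_to_num(C, nan=0.0)


def correlation_distances(
    data: PanelData,
    formula: str | None = None,
    model: FixedEffectsModel | None = None,
    scope: str = "within_metric",
    reference: str = "across_batches",
    gold: PanelData | None = None,
    cross_blocks_only: bool = True,
) -> dict:
    """Distances between correlation matrices, across batches or vs gold.

    ``scope='within_metric'`` uses each metric's p x p feature correlation
    (averaged over metrics); ``'cross_metric'`` uses the pooled
    (p*M) x (p*M) correlation restricted to between-metric blocks.
    ``reference='across_batches'`` averages all pairwise batch distances;
    ``'vs_gold'`` compares pooled correlations with the gold panel's.
    """
    if scope not in {"within_metric", "cross_metric"}:
        raise ValueError(f"unknown scope {scope!r}")
    if reference not in {"across_batches", "vs_gold"}:
        raise ValueError(f"unknown reference {reference!r}")
    Z = _residuals(data, formula, model)
    n, p, M = Z.shape

    def corr_of(X: np.ndarray) -> list[np.ndarray]:
        if scope == "within_metric":
            return [_corr(X[:, :, mi]) for mi in range(M)]
        C = _corr(X.reshape(X.shape[0], p * M))
        if cross_blocks_only:
            mask = np.zeros((p * M, p * M), dtype=bool)
            metr = np.tile(np.arange(M), p)
            mask[metr[:, None] != metr[None, :]] = True
            C = C * mask
        return [C]

    if reference == "vs_gold":
        if gold is None:
            raise ValueError("reference='vs_gold' requires the gold panel")
        Zg = _residuals(gold, formula, model)
        pairs = list(zip(corr_of(Z), corr_of(Zg)))
    else:
        masks = list(data.batch_indices().values())
        if any(int(m.sum()) < 3 for m in masks):
            raise ValueError("each batch needs at least 3 subjects for correlations")
        per_batch = [corr_of(Z[mask]) for mask in masks]
        pairs = [
            (per_batch[i][k], per_batch[j][k])
            for i in range(len(masks))
            for j in range(i + 1, len(masks))
            for k in range(len(per_batch[0]))
        ]
    acc = {k: [] for k in DISTANCE_NAMES}
    for C1, C2 in pairs:
        d = matrix_distances(C1, C2)
        for k in DISTANCE_NAMES:
            acc[k].append(d[k])
    return {k: float(np.mean(vs)) for k, vs in acc.items()}


# ---------------------------------------------------------------------------
# Signal preservation
# ---------------------------------------------------------------------------


def benjamini_hochberg(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Boolean rejection mask of the BH step-up procedure at level q."""
    from statsmodels.stats.multitest import multipletests

    reject, *_ = multipletests(np.asarray(pvals, dtype=float), alpha=q, method="fdr_bh")
    return reject


def covariate_pvalues(data: PanelData, covariate: str,
                      formula: str | None = None) -> np.ndarray:
    """Per-slice t-test p-values of one covariate's linear coefficient.

    Fits the (intercept + covariates) linear model to every slice at once
    and returns the two-sided p-value matrix with shape (p, M).
    """
    from .fixed_effects import parse_formula

    linear, smooth = parse_formula(formula)
    if smooth:
        raise ValueError("signal preservation supports linear formulas only")
    if not linear:
        linear = [c for c in data.covariates.columns]
    if covariate not in linear:
        raise ValueError(f"covariate {covariate!r} not in the model")
    n, p, M = data.values.shape
    X = np.column_stack([np.ones(n)] + [data.covariates[c].to_numpy(dtype=float)
                                        for c in linear])
    k = X.shape[1]
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ data.values.reshape(n, p * M)
    resid = data.values.reshape(n, p * M) - X @ beta
    dof = n - k
    s2 = np.sum(resid ** 2, axis=0) / dof
    j = 1 + linear.index(covariate)
    se = np.sqrt(XtX_inv[j, j] * s2)
    tstat = beta[j] / np.maximum(se, 1e-300)
    pv = 2.0 * stats.t.sf(np.abs(tstat), dof)
    return pv.reshape(p, M)


def signal_preservation(
    data: PanelData,
    covariate: str = "diagnosis",
    formula: str | None = None,
    truth: dict | None = None,
    q: float = 0.05,
) -> dict:
    """Significant-slice counts and, with known truth, TP and empirical FDR.

    BH is applied over all p * M slices. With a truth record (from the
    simulators), a slice is a true effect when its generating coefficient
    for ``covariate`` is nonzero; empirical FDR = FP / max(1, discoveries).
    """
    pv = covariate_pvalues(data, covariate, formula)
    flat = pv.reshape(-1)
    reject = benjamini_hochberg(flat, q=q)
    out = {"n_significant": int(reject.sum()), "n_tests": flat.size}
    if truth is not None:
        key = {"age": "beta_age", "sex": "beta_sex", "diagnosis": "beta_diag"}[covariate]
        true_mask = (np.abs(truth[key]) > 0).reshape(-1)
        tp = int(np.sum(reject & true_mask))
        fp = int(np.sum(reject & ~true_mask))
        out.update(
            tp=tp, fp=fp,
            fdr=float(fp / max(1, reject.sum())),
            sensitivity=float(tp / max(1, true_mask.sum())),
        )
    return out


# ---------------------------------------------------------------------------
# EB prior checks & MCMC diagnostics
# ---------------------------------------------------------------------------


def _hist_overlap(a: np.ndarray, b: np.ndarray, bins: int = 30) -> float:
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi <= lo:
        return 1.0
    ha, _ = np.histogram(a, bins=bins, range=(lo, hi), density=True)
    hb, _ = np.histogram(b, bins=bins, range=(lo, hi), density=True)
    w = (hi - lo) / bins
    return float(np.sum(np.minimum(ha, hb)) * w)


def eb_prior_checks(
    posteriors: BatchPosteriors,
    priors: BatchPriors,
    Z: np.ndarray,
    batch: np.ndarray,
    n_draws: int = 500,
    seed: int = 0,
) -> dict:
    """Agreement between empirical batch-effect distributions and EB priors.

    Location: standardized discrepancies of the per-feature batch means
    against N(gamma_i, T_i). Covariance: Frobenius distances of empirical
    per-feature covariances to the IW prior mean, compared with the same
    distances for draws from the IW prior; the histogram overlap
    coefficient summarizes agreement (1 = perfect).
    """
    from scipy.stats import invwishart

    rng = np.random.default_rng(seed)
    Z = np.asarray(Z, dtype=float)
    out = {}
    for b in priors.batches:
        mask = np.asarray(batch == b)
        Zb = Z[mask]
        zbar = Zb.mean(axis=0)
        T = priors.T[b]
        tdiag = np.sqrt(np.maximum(np.diag(T), 1e-12))
        if np.any(np.diag(T) < 1e-10):
            out[b] = {"degenerate_T": True}
            continue
        std_disc = (zbar - priors.gamma_bar[b]) / tdiag
        Psi, nu = priors.Psi[b], priors.nu[b]
        prior_mean = Psi / (nu - Z.shape[2] - 1.0)
        D = Zb - zbar
        ni = Zb.shape[0]
        S = np.einsum("jpm,jpk->pmk", D, D) / max(ni - 1, 1)
        emp_d = np.array([np.linalg.norm(S[v] - prior_mean, "fro")
                          for v in range(S.shape[0])])
        draws = invwishart.rvs(df=nu, scale=Psi, size=n_draws, random_state=rng)
        drw_d = np.array([np.linalg.norm(np.atleast_2d(d) - prior_mean, "fro")
                          for d in draws])
        out[b] = {
            "degenerate_T": False,
            "location_std_mean": float(np.mean(std_disc)),
            "location_std_sd": float(np.std(std_disc)),
            "cov_overlap": _hist_overlap(emp_d, drw_d),
        }
    return out


def mcmc_diagnostics(chains: np.ndarray, rhat_limit: float = 1.01) -> dict:
    """Rank-normalized split-Rhat and ESS for a (chain, draw, param) array."""
    import arviz as az

    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 3 or chains.shape[0] < 2:
        raise ValueError("chains must be (n_chains >= 2, n_draws, n_params)")
    if np.allclose(chains.std(axis=(0, 1)), 0.0):
        return {"rhat": np.ones(chains.shape[2]), "ess": np.full(chains.shape[2], np.nan),
                "passed": True, "constant": True}
    ds = az.convert_to_dataset(chains)
    rhat = az.rhat(ds)["x"].values
    ess = az.ess(ds)["x"].values
    return {
        "rhat": rhat,
        "ess": ess,
        "passed": bool(np.all(rhat < rhat_limit)),
        "constant": False,
    }
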