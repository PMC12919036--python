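"""Univariate ComBat and CovBat harmonization.

ComBat models each (feature, metric) slice as intercept + covariate effects
plus a batch-specific location shift ``gamma`` and scale factor ``delta``.
After standardizing residuals, batch-wise estimates of (gamma, delta^2) are
shrunk toward across-feature priors (normal for gamma, inverse-gamma for
delta^2) whose hyperparameters come from method-of-moments estimation, and
the residuals are adjusted to ``(z - gamma*)/delta*``.

CovBat adds a second stage: eigendecomposition of the pooled post-ComBat
residual covariance within each metric, ComBat applied to the leading
principal-component scores, and reconstruction — harmonizing batch effects
in the cross-feature covariance that feature-wise ComBat cannot see.

These serve both as baselines and as the inner harmonizer that MV-CovBat
applies to its shared latent scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._linalg import fix_signs
from .fixed_effects import FixedEffectsModel, fit_fixed_effects, remove_fixed_effects
from .panel import (
    PanelData,
    apply_standardization,
    fit_standardization,
    invert_standardization,
)

__all__ = ["UVBatchEffects", "UVCovBatDecomposition", "combat_adjust_matrix",
           "combat_columns", "uv_combat", "uv_covbat"]


@dataclass
class UVBatchEffects:
    """Estimated per-(batch, slice) location/scale effects and EB priors."""

    batches: list
    gamma_star: dict  # batch -> (n_slices,) additive effect
    delta_star: dict  # batch -> (n_slices,) multiplicative effect (>0)
    gamma_bar: dict = field(default_factory=dict)  # normal prior mean
    tau2: dict = field(default_factory=dict)       # normal prior variance
    lam: dict = field(default_factory=dict)        # IG shape
    theta: dict = field(default_factory=dict)      # IG scale


def _ig_mom(d2: np.ndarray) -> tuple[float, float]:
    """Inverse-gamma (shape, scale) matched to the moments of ``d2``."""
    m = float(np.mean(d2))
    s2 = float(np.var(d2, ddof=1)) if d2.size > 1 else 0.0
    if s2 <= 0:
        # degenerate dispersion: an effectively flat prior
        return 2.0 + 1e8, m * (1.0 + 1e8)
    lam = (2.0 * s2 + m * m) / s2
    theta = (m * s2 + m ** 3) / s2
    return lam, theta


def _eb_iterate(
    z: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    g_bar: float,
    t2: float,
    lam: float,
    theta: float,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Alternate the conditional posterior means for one batch.

    ``z`` is (n_i, n_slices); returns (gamma_star, delta_star) per slice.
    """
    n = z.shape[0]
    g_old = gamma_hat.copy()
    d_old = delta_hat.copy()
    for _ in range(max_iter):
        g_new = (n * t2 * gamma_hat + d_old * g_bar) / (n * t2 + d_old)
        ss = np.sum((z - g_new) ** 2, axis=0)
        d_new = (theta + 0.5 * ss) / (n / 2.0 + lam - 1.0)
        change = max(np.max(np.abs(g_new - g_old)), np.max(np.abs(d_new - d_old)))
        g_old, d_old = g_new, d_new
        if change < tol:
            break
    return g_old, d_old


def combat_adjust_matrix(
    Z: np.ndarray,
    batch: np.ndarray,
    eb: bool = True,
    pool_groups: np.ndarray | None = None,
) -> tuple[np.ndarray, UVBatchEffects]:
    """Core ComBat adjustment on an already-standardized (n, q) matrix.

    Each column is one slice. EB pooling (MoM priors) runs within
    ``pool_groups`` (default: all columns form one pooling family). With a
    single batch the input is returned unchanged (gamma*=0, delta*=1).
    """
    Z = np.asarray(Z, dtype=float)
    n, q = Z.shape
    batches = sorted(np.unique(batch).tolist())
    eff = UVBatchEffects(batches=batches, gamma_star={}, delta_star={})
    if len(batches) < 2:
        for b in batches:
            eff.gamma_star[b] = np.zeros(q)
            eff.delta_star[b] = np.ones(q)
        return Z.copy(), eff

    groups = np.zeros(q, dtype=int) if pool_groups is None else np.asarray(pool_groups)
    out = Z.copy()
    for b in batches:
        mask = batch == b
        zb = Z[mask]
        ni = zb.shape[0]
        if ni < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 subjects")
        gamma_hat = zb.mean(axis=0)
        delta_hat = zb.var(axis=0, ddof=1)
        delta_hat = np.maximum(delta_hat, 1e-12)
        if not eb:
            g_star, d_star = gamma_hat, delta_hat
        else:
            g_star = np.empty(q)
            d_star = np.empty(q)
            for g in np.unique(groups):
                sel = groups == g
                if np.sum(sel) < 2:
                    # nothing to pool across: fall back to direct estimates
                    g_star[sel], d_star[sel] = gamma_hat[sel], delta_hat[sel]
                    continue
                gb = float(np.mean(gamma_hat[sel]))
                t2 = float(np.var(gamma_hat[sel], ddof=1))
                t2 = max(t2, 1e-12)
                lam, theta = _ig_mom(delta_hat[sel])
                gs, ds = _eb_iterate(zb[:, sel], gamma_hat[sel], delta_hat[sel],
                                     gb, t2, lam, theta)
                g_star[sel], d_star[sel] = gs, ds
        d_star = np.maximum(d_star, 1e-12)
        out[mask] = (zb - g_star) / np.sqrt(d_star)
        eff.gamma_star[b] = g_star
        eff.delta_star[b] = d_star
    return out, eff


def combat_columns(
    Y: np.ndarray, batch: np.ndarray, eb: bool = True
) -> tuple[np.ndarray, UVBatchEffects]:
    """ComBat on arbitrary-scale columns: standardize, adjust, restore scale.

    Used for PC / latent-score harmonization where each column carries its
    own (eigenvalue) scale that must survive the adjustment.
    """
    Y = np.asarray(Y, dtype=float)
    center = Y.mean(axis=0)
    scale = Y.std(axis=0, ddof=1)
    scale = np.where(scale > 0, scale, 1.0)
    adj, eff = combat_adjust_matrix((Y - center) / scale, batch, eb=eb)
    return adj * scale + center, eff


def uv_combat(
    data: PanelData,
    model: FixedEffectsModel | None = None,
    formula: str | None = None,
    eb: bool = True,
) -> tuple[PanelData, UVBatchEffects]:
    """Univariate ComBat on every (feature, metric) slice.

    EB priors pool across features *within each metric* (each metric is
    harmonized independently, as in single-metric practice). Returns the
    harmonized panel and the estimated batch effects.
    """
    if len(data.batches) < 2:
        return data.with_values(data.values), UVBatchEffects(
            batches=data.batches,
            gamma_star={b: np.zeros(data.n_features * data.n_metrics) for b in data.batches},
            delta_star={b: np.ones(data.n_features * data.n_metrics) for b in data.batches},
        )
    data.check_harmonizable()
    if model is None:
        model = fit_fixed_effects(data, formula)
    Z = remove_fixed_effects(data, model)
    std = fit_standardization(Z, mode="pooled_sd")
    Zs = apply_standardization(Z, std)

    n, p, M = Zs.shape
    flat = Zs.reshape(n, p * M)
    # column j = (feature v, metric m) with m fastest; pool per metric
    pool = np.tile(np.arange(M), p)
    adj, eff = combat_adjust_matrix(flat, data.batch, eb=eb, pool_groups=pool)
    Zstar = invert_standardization(adj.reshape(n, p, M), std)
    harmonized = data.with_values(model.fitted(data.covariates) + Zstar)
    return harmonized, eff


@dataclass
class UVCovBatDecomposition:
    """Per-metric PCA state from CovBat's covariance-harmonization stage."""

    eigenvectors: dict   # metric -> (p, p) orthonormal columns
    scores: dict         # metric -> (n, p) PC scores
    n_retained: dict     # metric -> K
    score_effects: dict  # metric -> UVBatchEffects on the K score columns


def uv_covbat(
    data: PanelData,
    model: FixedEffectsModel | None = None,
    formula: str | None = None,
    var_fraction: float = 0.95,
    eb: bool = True,
) -> tuple[PanelData, UVCovBatDecomposition]:
    """Univariate CovBat: ComBat, then PC-score harmonization per metric.

    Stage 1 applies :func:`uv_combat`. Stage 2, independently per metric,
    eigendecomposes the pooled covariance of the Stage-1 residuals across
    the ``p`` features, harmonizes the leading score columns (smallest K
    reaching ``var_fraction`` of total variance) with intercept-only
    ComBat, and reconstructs.
    """
    if not (0 < var_fraction <= 1):
        raise ValueError("var_fraction must lie in (0, 1]")
    if model is None:
        model = fit_fixed_effects(data, formula)
    stage1, _ = uv_combat(data, model=model, eb=eb)
    if len(data.batches) < 2:
        return stage1, UVCovBatDecomposition({}, {}, {}, {})

    fitted = model.fitted(data.covariates)
    resid = stage1.values - fitted  # (n, p, M)
    out = stage1.values.copy()
    decomp = UVCovBatDecomposition({}, {}, {}, {})
    for mi, m in enumerate(data.metric_ids):
        E = resid[:, :, mi]
        mu = E.mean(axis=0)
        Ec = E - mu
        cov = np.cov(Ec, rowvar=False, ddof=1)
        w, V = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, V = np.maximum(w[order], 0.0), fix_signs(V[:, order])
        total = float(np.sum(w))
        frac = np.cumsum(w) / max(total, 1e-300)
        K = int(np.searchsorted(frac, var_fraction - 1e-12) + 1)
        K = min(K, V.shape[1])
        scores = Ec @ V
        adj, seff = combat_columns(scores[:, :K], data.batch, eb=eb)
        scores_h = scores.copy()
        scores_h[:, :K] = adj
        out[:, :, mi] = fitted[:, :, mi] + mu + scores_h @ V.T
        decomp.eigenvectors[m] = V
        decomp.scores[m] = scores
        decomp.n_retained[m] = K
        decomp.score_effects[m] = seff
    return data.with_values(out), decomp
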