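"""MV-CovBat: shared-latent-subspace harmonization on top of MV-ComBat.

Stage 1 runs MV-ComBat to remove feature-wise batch effects in the mean
and cross-metric covariance. Stage 2 targets batch effects that persist in
the cross-*feature* covariance: the per-metric residual matrices R^(m) are
decomposed by PCA (R = F L^T, singular-value-scaled scores), a shared
orthonormal score matrix G is estimated by minimizing

    sum_m || F^(m) - G A^(m) ||_F^2    s.t.  G^T G = I,

whose solution (Rayleigh-Ritz) is the top eigenvectors of
S = sum_m F^(m) F^(m)^T, with A^(m) = G^T F^(m). Univariate ComBat applied
to the columns of G removes batch effects in the shared scores, which are
propagated back through A^(m) and L^(m) to the metric spaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._linalg import fix_signs
from .fixed_effects import FixedEffectsModel, fit_fixed_effects
from .mv_combat import BatchPosteriors, MCMCConfig, mv_combat
from .panel import PanelData
from .univariate import UVBatchEffects, combat_columns

__all__ = [
    "LatentModel",
    "metric_pca",
    "shared_subspace",
    "harmonize_shared_scores",
    "reconstruct",
    "mv_covbat",
]


@dataclass
class LatentModel:
    """Stage-2 latent state: per-metric PCA plus the shared subspace."""

    loadings: dict        # metric -> (p, r_m) orthonormal columns
    scores: dict          # metric -> (n, r_m) singular-value-scaled scores
    remainders: dict      # metric -> (n, p) discarded-component residual
    col_means: dict       # metric -> (p,) column means removed before PCA
    G: np.ndarray         # (n, r_s), orthonormal columns
    A: dict               # metric -> (r_s, r_m)
    H: dict               # metric -> (n, r_m) idiosyncratic component
    eigenvalues: np.ndarray  # eigenvalues of S = sum_m F F^T (descending)

    @property
    def r_s(self) -> int:
        return self.G.shape[1]


def metric_pca(R: np.ndarray, var_fraction: float = 0.95):
    """SVD-based PCA of a column-centered residual matrix.

    Returns singular-value-scaled scores ``F = U D`` (restricted to the
    smallest component count reaching ``var_fraction`` of total variance),
    orthonormal loadings ``L``, and the retained count ``r_m``. The sign of
    each component is fixed so its largest-magnitude loading is positive.
    """
    if not (0 < var_fraction <= 1):
        raise ValueError("var_fraction must lie in (0, 1]")
    R = np.asarray(R, dtype=float)
    if R.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    col_mean = np.abs(R.mean(axis=0))
    scale = max(float(np.abs(R).max()), 1.0)
    if np.any(col_mean > 1e-6 * scale):
        raise ValueError("residual matrix must be column-centered before PCA")
    U, d, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    signs = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    U, V = U * signs, V * signs
    var = d ** 2
    total = float(var.sum())
    if total <= 0:
        return np.zeros((R.shape[0], 1)), V[:, :1], 1
    frac = np.cumsum(var) / total
    r_m = int(np.searchsorted(frac, var_fraction - 1e-12) + 1)
    r_m = min(r_m, len(d))
    F = U[:, :r_m] * d[:r_m]
    return F, V[:, :r_m], r_m


def shared_subspace(F_list: list[np.ndarray], r_s: int | None = None,
                    var_fraction_shared: float = 0.95):
    """Shared orthonormal scores across metric-specific PCA spaces.

    ``G`` holds the top eigenvectors of ``S = sum_m F^(m) F^(m)^T``; the
    dimension is either given (``r_s``) or chosen as the smallest count
    whose eigenvalues reach ``var_fraction_shared`` of ``trace(S)``.
    Returns ``(G, A_list, eigenvalues)``.
    """
    n = F_list[0].shape[0]
    for F in F_list:
        if F.shape[0] != n:
            raise ValueError("all score matrices must share the row count")
    S = np.zeros((n, n))
    for F in F_list:
        S += F @ F.T
    w, V = np.linalg.eigh(S)
    order = np.argsort(w)[::-1]
    w = np.maximum(w[order], 0.0)
    V = fix_signs(V[:, order])
    if np.any(np.isclose(np.diff(w), 0.0, atol=1e-12) & (w[:-1] > 1e-10)):
        warnings.warn("eigenvalue ties in shared-subspace problem; broken by index order")
    if r_s is None:
        total = float(w.sum())
        if total <= 0:
            r_s = 1
        else:
            frac = np.cumsum(w) / total
            r_s = int(np.searchsorted(frac, var_fraction_shared - 1e-12) + 1)
    if r_s > n:
        raise ValueError("r_s cannot exceed the number of subjects")
    G = V[:, :r_s]
    A_list = [G.T @ F for F in F_list]
    return G, A_list, w


def harmonize_shared_scores(
    G: np.ndarray, batch: np.ndarray, eb: bool = True
) -> tuple[np.ndarray, UVBatchEffects]:
    """Univariate ComBat on the shared score columns (intercept-only)."""
    if len(np.unique(batch)) < 2:
        q = G.shape[1]
        return G.copy(), UVBatchEffects(
            batches=sorted(np.unique(batch).tolist()),
            gamma_star={}, delta_star={},
        )
    return combat_columns(G, batch, eb=eb)


def reconstruct(latent: LatentModel, G_star: np.ndarray) -> dict:
    """Propagate harmonized shared scores back to metric residual matrices.

    ``F*^(m) = G* A^(m) + H^(m)``, then ``R*^(m) = F* L^T + remainder``
    with the discarded-component remainder re-added so skipping the score
    harmonization (``G* = G``) reproduces the input exactly.
    """
    out = {}
    for m, L in latent.loadings.items():
        F_star = G_star @ latent.A[m] + latent.H[m]
        out[m] = F_star @ L.T + latent.remainders[m] + latent.col_means[m]
    return out


def mv_covbat(
    data: PanelData,
    formula: str | None = None,
    model: FixedEffectsModel | None = None,
    fe_kind: str = "linear",
    estimator: str = "eb",
    var_fraction: float = 0.95,
    var_fraction_shared: float = 0.95,
    r_s: int | None = None,
    eb_scores: bool = True,
    mcmc_config: MCMCConfig | None = None,
) -> tuple[PanelData, BatchPosteriors, LatentModel | None]:
    """Two-stage MV-CovBat harmonization.

    Stage 1 is :func:`mv_combat`; Stage 2 decomposes the Stage-1 residuals
    per metric, estimates the shared subspace, harmonizes the shared
    scores with univariate ComBat and reconstructs. Fixed effects are
    restored at the end. Returns the harmonized panel, the Stage-1 batch
    posteriors and the latent model (``None`` for single-batch input).
    """
    if model is None:
        model = fit_fixed_effects(data, formula, kind=fe_kind)
    stage1, post = mv_combat(
        data, model=model, estimator=estimator, mcmc_config=mcmc_config
    )
    if len(data.batches) < 2:
        return stage1, post, None

    fitted = model.fitted(data.covariates)
    resid = stage1.values - fitted  # (n, p, M), de-standardized
    loadings, scores, remainders, col_means, H = {}, {}, {}, {}, {}
    F_list = []
    for mi, m in enumerate(data.metric_ids):
        Rm = resid[:, :, mi]
        mu = Rm.mean(axis=0)
        Rc = Rm - mu
        F, L, _ = metric_pca(Rc, var_fraction=var_fraction)
        loadings[m] = L
        scores[m] = F
        remainders[m] = Rc - F @ L.T
        col_means[m] = mu
        F_list.append(F)

    G, A_list, eigvals = shared_subspace(F_list, r_s=r_s,
                                         var_fraction_shared=var_fraction_shared)
    A = {m: A_list[mi] for mi, m in enumerate(data.metric_ids)}
    Hd = {m: scores[m] - G @ A[m] for m in data.metric_ids}
    latent = LatentModel(
        loadings=loadings, scores=scores, remainders=remainders,
        col_means=col_means, G=G, A=A, H=Hd, eigenvalues=eigvals,
    )
    G_star, _ = harmonize_shared_scores(G, data.batch, eb=eb_scores)
    R_star = reconstruct(latent, G_star)
    out = stage1.values.copy()
    for mi, m in enumerate(data.metric_ids):
        out[:, :, mi] = fitted[:, :, mi] + R_star[m]
    return data.with_values(out), post, latent
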