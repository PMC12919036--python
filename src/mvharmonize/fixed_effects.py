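"""Covariate ("biological") fixed-effect estimation, removal and restoration.

Each (feature, metric) slice is modelled independently as

    y = alpha + X beta + f(x_smooth) + residual

with either a plain least-squares fit (``kind='linear'``) or penalized
B-spline smooth terms for covariates flagged nonlinear (``kind='gam'``).
Harmonizers remove the fitted covariate contribution before batch-effect
estimation and add it back afterwards, so biological signal is preserved
by construction.

Formulas are simple ``+``-separated covariate lists; a ``_s`` suffix flags
a smooth term, e.g. ``"age_s + sex"`` fits a spline in ``age`` and a linear
term in ``sex``. The batch label is deliberately never part of the design —
it would absorb the very effect to be removed later.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import PanelData

__all__ = ["FixedEffectsModel", "parse_formula", "fit_fixed_effects",
           "remove_fixed_effects", "restore_fixed_effects"]


def parse_formula(formula: str | None) -> tuple[list[str], list[str]]:
    """Split a formula string into (linear covariates, smooth covariates)."""
    if not formula or not formula.strip():
        return [], []
    linear, smooth = [], []
    for term in formula.split("+"):
        term = term.strip()
        if not term:
            continue
        if term.endswith("_s"):
            smooth.append(term[:-2])
        else:
            linear.append(term)
    return linear, smooth


@dataclass
class FixedEffectsModel:
    """Fitted per-(feature, metric) covariate model.

    ``coef`` holds the intercept and linear coefficients with shape
    ``(1 + k_lin, p, M)``. For ``kind='gam'`` the smooth contribution is
    stored as per-slice spline coefficients over a fixed B-spline basis.
    """

    kind: str
    linear_covariates: list[str]
    smooth_covariates: list[str]
    coef: np.ndarray  # (1 + k_lin, p, M)
    feature_ids: list[str]
    metric_ids: list[str]
    # gam-only state
    spline_coef: np.ndarray | None = None  # (n_basis, p, M)
    spline_knots: dict = field(default_factory=dict)
    basis_df: int = 10

    def design(self, covariates: pd.DataFrame) -> np.ndarray:
        """Intercept + linear-covariate design matrix for new subjects."""
        missing = [c for c in self.linear_covariates + self.smooth_covariates
                   if c not in covariates.columns]
        if missing:
            raise ValueError(f"covariate columns absent at transform time: {missing}")
        n = len(covariates)
        cols = [np.ones(n)]
        cols += [covariates[c].to_numpy(dtype=float) for c in self.linear_covariates]
        return np.column_stack(cols)

    def smooth_basis(self, covariates: pd.DataFrame) -> np.ndarray | None:
        if not self.smooth_covariates:
            return None
        from scipy.interpolate import BSpline

        blocks = []
        for c in self.smooth_covariates:
            knots, degree = self.spline_knots[c]
            x = covariates[c].to_numpy(dtype=float)
            nb = len(knots) - degree - 1
            B = np.column_stack([
                BSpline.basis_element(knots[i:i + degree + 2], extrapolate=True)(x)
                for i in range(nb)
            ])
            # center each basis column (fitted on training data) so the
            # smooth carries no intercept
            B = B - self.spline_knots[c + "__means"]
            blocks.append(B)
        return np.hstack(blocks)

    def fitted(self, covariates: pd.DataFrame) -> np.ndarray:
        """Fitted values tensor ``(n, p, M)`` for given covariates."""
        X = self.design(covariates)
        p, M = self.coef.shape[1], self.coef.shape[2]
        fit = np.einsum("nk,kpm->npm", X, self.coef)
        if self.kind == "gam" and self.smooth_covariates:
            B = self.smooth_basis(covariates)
            fit = fit + np.einsum("nk,kpm->npm", B, self.spline_coef)
        return fit


def _spline_knots(x: np.ndarray, df: int, degree: int = 3) -> np.ndarray:
    """Interior knots at quantiles, boundary knots repeated degree+1 times."""
    n_interior = df - degree - 1
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(x, qs) if n_interior > 0 else np.array([])
    lo, hi = x.min(), x.max()
    span = max(hi - lo, 1e-8)
    lo, hi = lo - 1e-3 * span, hi + 1e-3 * span
    return np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])


def fit_fixed_effects(
    data: PanelData,
    formula: str | None = None,
    kind: str = "linear",
    basis_df: int = 10,
) -> FixedEffectsModel:
    """Fit the covariate model on every (feature, metric) slice.

    All slices share one design matrix, so the least-squares problem is
    solved for the full ``p*M`` response block at once. GAM smooths use a
    cubic B-spline basis (default dimension 10) with a second-difference
    ridge penalty selected by generalized cross-validation on the pooled
    response.
    """
    linear, smooth = parse_formula(formula)
    if kind == "linear" and smooth:
        raise ValueError("smooth terms require kind='gam'")
    for c in smooth:
        vals = np.unique(data.covariates[c].to_numpy(dtype=float))
        if len(vals) <= 2:
            raise ValueError(f"smooth term requested on binary covariate {c!r}")

    n, p, M = data.values.shape
    Y = data.values.reshape(n, p * M)

    model = FixedEffectsModel(
        kind=kind,
        linear_covariates=linear,
        smooth_covariates=smooth if kind == "gam" else [],
        coef=np.zeros((1 + len(linear), p, M)),
        feature_ids=list(data.feature_ids),
        metric_ids=list(data.metric_ids),
        basis_df=basis_df,
    )
    X = model.design(data.covariates)

    if kind == "linear" or not smooth:
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise ValueError("rank-deficient fixed-effects design matrix")
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        model.coef = beta.reshape(X.shape[1], p, M)
        return model

    # GAM: assemble [X | centered spline basis] and solve a penalized LS
    # problem with one GCV-chosen ridge weight on second differences.
    from scipy.interpolate import BSpline

    blocks, pen_blocks = [], []
    for c in smooth:
        x = data.covariates[c].to_numpy(dtype=float)
        knots = _spline_knots(x, basis_df)
        degree = 3
        nb = len(knots) - degree - 1
        B = np.column_stack([
            BSpline.basis_element(knots[i:i + degree + 2], extrapolate=True)(x)
            for i in range(nb)
        ])
        means = B.mean(axis=0)
        B = B - means
        model.spline_knots[c] = (knots, degree)
        model.spline_knots[c + "__means"] = means
        blocks.append(B)
        D = np.diff(np.eye(nb), n=2, axis=0)
        pen_blocks.append(D.T @ D)
    Bfull = np.hstack(blocks)
    kx = X.shape[1]
    ks = Bfull.shape[1]
    from scipy.linalg import block_diag

    P = block_diag(np.zeros((kx, kx)), block_diag(*pen_blocks))
    Dm = np.hstack([X, Bfull])
    DtD = Dm.T @ Dm
    DtY = Dm.T @ Y

    def gcv(lam: float) -> float:
        A = DtD + lam * P
        coef = np.linalg.solve(A, DtY)
        fitted = Dm @ coef
        rss = float(np.sum((Y - fitted) ** 2))
        edf = float(np.trace(np.linalg.solve(A, DtD)))
        return n * rss / max(n - edf, 1.0) ** 2

    lams = np.logspace(-4, 6, 21)
    lam = lams[int(np.argmin([gcv(l) for l in lams]))]
    coef = np.linalg.solve(DtD + lam * P, DtY)
    model.coef = coef[:kx].reshape(kx, p, M)
    model.spline_coef = coef[kx:].reshape(ks, p, M)
    return model


def remove_fixed_effects(data: PanelData, model: FixedEffectsModel) -> np.ndarray:
    """Residual tensor ``Z = Y - fitted`` capturing batch-related variation."""
    return data.values - model.fitted(data.covariates)


def restore_fixed_effects(
    Z: np.ndarray, model: FixedEffectsModel, covariates: pd.DataFrame
) -> np.ndarray:
    """Inverse of :func:`remove_fixed_effects`: ``Y = fitted + Z``."""
    return np.asarray(Z, dtype=float) + model.fitted(covariates)
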