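"""Multi-metric panel data container, tabular I/O and residual standardization.

A *panel* holds one numeric value per (subject, feature, metric) together
with a batch label per subject and a table of subject-level covariates.
Features are measurement units (e.g. cortical regions of interest) and
metrics are derived measurement types (e.g. thickness, surface area); the
same ``p`` features are observed under each of the ``M`` metrics.

The in-memory layout is a dense ``(n, p, M)`` tensor with lexicographically
sorted feature and metric identifiers, so every downstream module can rely
on a deterministic ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PanelData",
    "Standardization",
    "read_panel",
    "write_panel",
    "fit_standardization",
    "apply_standardization",
    "invert_standardization",
]


@dataclass
class PanelData:
    """Dense (subject, feature, metric) value tensor with batch and covariates.

    Parameters
    ----------
    values
        ``(n, p, M)`` float array; must be finite.
    batch
        Length-``n`` sequence of batch labels (site/scanner identifiers).
    covariates
        ``(n, k)`` DataFrame of numeric/binary subject-level covariates.
        May be empty (zero columns).
    feature_ids, metric_ids
        Ordered identifier lists of length ``p`` and ``M``.
    subject_ids
        Optional ordered subject identifiers (defaults to ``s000..``).
    """

    values: np.ndarray
    batch: np.ndarray
    covariates: pd.DataFrame
    feature_ids: list[str]
    metric_ids: list[str]
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a (n, p, M) tensor")
        n, p, M = self.values.shape
        if not np.all(np.isfinite(self.values)):
            raise ValueError("panel values must all be finite (no NA/inf)")
        self.batch = np.asarray(self.batch)
        if self.batch.shape != (n,):
            raise ValueError("batch must give exactly one label per subject")
        if len(self.feature_ids) != p or len(self.metric_ids) != M:
            raise ValueError("feature/metric identifier lists do not match tensor shape")
        if not self.subject_ids:
            self.subject_ids = [f"s{i:04d}" for i in range(n)]
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length mismatch")
        if not isinstance(self.covariates, pd.DataFrame):
            self.covariates = pd.DataFrame(self.covariates)
        if len(self.covariates) != n:
            raise ValueError("covariates must have one row per subject")
        self.covariates = self.covariates.reset_index(drop=True)

    # -- basic geometry -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_metrics(self) -> int:
        return self.values.shape[2]

    @property
    def batches(self) -> list:
        """Unique batch labels in sorted order."""
        return sorted(pd.unique(self.batch).tolist())

    def batch_indices(self) -> dict:
        """Mapping batch label -> boolean subject mask."""
        return {b: np.asarray(self.batch == b) for b in self.batches}

    def batch_sizes(self) -> dict:
        return {b: int(np.sum(self.batch == b)) for b in self.batches}

    def with_values(self, values: np.ndarray) -> "PanelData":
        """Copy of the panel with a replaced value tensor."""
        return replace(self, values=np.array(values, dtype=float))

    def check_harmonizable(self, min_per_batch: int = 2) -> None:
        """Validate batch structure for harmonization (I >= 2, n_i >= 2)."""
        sizes = self.batch_sizes()
        if len(sizes) < 2:
            raise ValueError("harmonization requires at least 2 batches")
        for b, ni in sizes.items():
            if ni < min_per_batch:
                raise ValueError(
                    f"batch {b!r} has {ni} subjects; at least {min_per_batch} required"
                )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_DEFAULT_SCHEMA = {
    "subject": "subject",
    "batch": "batch",
    "feature": "feature",
    "metric": "metric",
    "value": "value",
}


def _sep_for(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_panel(
    path,
    layout: str = "long",
    schema: dict | None = None,
    covariates: list[str] | None = None,
) -> PanelData:
    """Read a panel from a long or wide CSV/TSV file.

    Long layout needs columns ``subject, batch, feature, metric, value``
    (renameable through ``schema``); wide layout needs ``subject, batch``
    plus one ``<feature>_<metric>`` column per cell. Covariate columns must
    be named explicitly. Missing cells and non-numeric values are errors;
    feature and metric identifiers are sorted lexicographically.
    """
    sch = dict(_DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    covariates = list(covariates or [])
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")

    if layout == "long":
        required = [sch[k] for k in ("subject", "batch", "feature", "metric", "value")]
    elif layout == "wide":
        required = [sch["subject"], sch["batch"]]
    else:
        raise ValueError(f"unknown layout {layout!r}")
    for col in required + covariates:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")

    if layout == "wide":
        value_cols = [c for c in df.columns if c not in required + covariates]
        bad = [c for c in value_cols if "_" not in c]
        if bad:
            raise ValueError(f"wide value columns must be '<feature>_<metric>': {bad}")
        long = df.melt(
            id_vars=required + covariates,
            value_vars=value_cols,
            var_name="__fm",
            value_name=sch["value"],
        )
        fm = long["__fm"].str.rsplit("_", n=1, expand=True)
        long[sch["feature"]], long[sch["metric"]] = fm[0], fm[1]
        df = long.drop(columns="__fm")

    sub_c, bat_c = sch["subject"], sch["batch"]
    fea_c, met_c, val_c = sch["feature"], sch["metric"], sch["value"]

    if df[val_c].isna().any():
        raise ValueError("panel contains NA values; missing data are not supported")
    vals = pd.to_numeric(df[val_c], errors="coerce")
    if vals.isna().any():
        raise ValueError("non-numeric entries in the value column")
    df = df.assign(**{val_c: vals.astype(float)})

    nb = df.groupby(sub_c)[bat_c].nunique()
    if (nb > 1).any():
        bad_subj = nb[nb > 1].index.tolist()
        raise ValueError(f"subjects with multiple batch labels: {bad_subj}")

    feature_ids = sorted(df[fea_c].astype(str).unique())
    metric_ids = sorted(df[met_c].astype(str).unique())
    subject_ids = sorted(df[sub_c].astype(str).unique())

    cube = df.pivot_table(
        index=sub_c,
        columns=[fea_c, met_c],
        values=val_c,
        aggfunc="first",
        sort=True,
    )
    full_cols = pd.MultiIndex.from_product([feature_ids, metric_ids])
    cube = cube.reindex(index=subject_ids, columns=full_cols)
    if cube.isna().any().any():
        raise ValueError("panel is not complete: every (subject, feature, metric) cell is required")

    n, p, M = len(subject_ids), len(feature_ids), len(metric_ids)
    values = cube.to_numpy().reshape(n, p, M)

    meta = df.drop_duplicates(sub_c).set_index(df.drop_duplicates(sub_c)[sub_c].astype(str))
    meta = meta.loc[subject_ids]
    batch = meta[bat_c].to_numpy()
    cov = meta[covariates].reset_index(drop=True).copy() if covariates else pd.DataFrame(index=range(n))
    for c in covariates:
        cov[c] = pd.to_numeric(cov[c], errors="raise")

    return PanelData(
        values=values,
        batch=batch,
        covariates=cov,
        feature_ids=feature_ids,
        metric_ids=metric_ids,
        subject_ids=subject_ids,
    )


def write_panel(data: PanelData, path, layout: str = "long") -> None:
    """Write a panel losslessly to CSV/TSV in long or wide layout."""
    sep = _sep_for(path)
    n, p, M = data.values.shape
    base = pd.DataFrame({"subject": data.subject_ids, "batch": data.batch})
    for c in data.covariates.columns:
        base[c] = data.covariates[c].to_numpy()

    if layout == "wide":
        wide = base.copy()
        for vi, v in enumerate(data.feature_ids):
            for mi, m in enumerate(data.metric_ids):
                wide[f"{v}_{m}"] = data.values[:, vi, mi]
        wide.to_csv(path, sep=sep, index=False, float_format="%.17g")
        return
    if layout != "long":
        raise ValueError(f"unknown layout {layout!r}")

    rows = base.loc[base.index.repeat(p * M)].reset_index(drop=True)
    feats = np.tile(np.repeat(data.feature_ids, M), n)
    mets = np.tile(data.metric_ids, n * p)
    rows["feature"] = feats
    rows["metric"] = mets
    rows["value"] = data.values.reshape(-1)
    rows.to_csv(path, sep=sep, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


@dataclass
class Standardization:
    """Per-(feature, metric) centering and positive scaling.

    ``mode='pooled_sd'`` centers each slice at its pooled (across-batch)
    mean and scales by the pooled sample SD (ddof=1), mirroring the
    standardization step of the original ComBat; ``mode='none'`` is the
    identity transform.
    """

    center: np.ndarray  # (p, M)
    scale: np.ndarray  # (p, M), strictly positive

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if np.any(self.scale <= 0):
            raise ValueError("standardization scale must be strictly positive")


def fit_standardization(residuals: np.ndarray, mode: str = "pooled_sd") -> Standardization:
    """Fit a standardization on an ``(n, p, M)`` residual tensor."""
    Z = np.asarray(residuals, dtype=float)
    if Z.ndim != 3:
        raise ValueError("residuals must be (n, p, M)")
    if not np.all(np.isfinite(Z)):
        raise ValueError("residuals must be finite")
    p, M = Z.shape[1], Z.shape[2]
    if mode == "none":
        return Standardization(center=np.zeros((p, M)), scale=np.ones((p, M)))
    if mode != "pooled_sd":
        raise ValueError(f"unknown standardization mode {mode!r}")
    center = Z.mean(axis=0)
    scale = Z.std(axis=0, ddof=1)
    if np.any(scale <= 0):
        bad = np.argwhere(scale <= 0)
        raise ValueError(f"constant (feature, metric) slices cannot be standardized: {bad.tolist()}")
    return Standardization(center=center, scale=scale)


def apply_standardization(Z: np.ndarray, s: Standardization) -> np.ndarray:
    return (np.asarray(Z, dtype=float) - s.center) / s.scale


def invert_standardization(Zs: np.ndarray, s: Standardization) -> np.ndarray:
    return np.asarray(Zs, dtype=float) * s.scale + s.center
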