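"""Counts -> standardized log-expression, the network-input pipeline.

Chain: CPM conversion, low-expression + GO-BP gene filtering, log2
transform, smoothed (group-aware) quantile normalization, empirical-Bayes
removal of unwanted covariates, and per-gene standardization.  Each step
consumes and returns an :class:`~stressnet.containers.ExpressionMatrix`
tagged with its stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .containers import ExpressionMatrix, SampleTable

log = logging.getLogger(__name__)


@dataclass
class GeneFilterConfig:
    """Low-expression and annotation filter settings.

    A gene is dropped when its CPM falls below ``cpm_threshold`` in at
    least ``ceil(sample_fraction * n_samples)`` samples, or (if
    ``require_go_bp``) when it carries no biological-process GO term.
    ``log_prior`` is the pseudo-value added before log2.
    """

    cpm_threshold: float = 10.0
    sample_fraction: float = 0.30
    require_go_bp: bool = True
    log_prior: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.sample_fraction <= 1):
            raise ValueError("sample_fraction must be in (0, 1]")
        if self.cpm_threshold <= 0:
            raise ValueError("cpm_threshold must be positive")
        if self.log_prior <= 0:
            raise ValueError("log_prior must be positive")


def compute_cpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Counts per million: scale each sample column to sum to 1e6."""
    counts.require_stage("counts")
    vals = counts.values
    if (vals.to_numpy() < 0).any():
        raise ValueError("negative counts")
    colsums = vals.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero):
        raise ValueError(f"samples with zero total counts: {zero.index.tolist()}")
    cpm = vals / colsums * 1e6
    return counts.advance(cpm, "cpm")


def filter_genes(
    cpm: ExpressionMatrix,
    cfg: GeneFilterConfig,
    go_map: dict[str, set[str]] | None = None,
) -> list[str]:
    """Gene ids surviving the low-expression and GO-BP filters, in input order."""
    cpm.require_stage("cpm")
    if cfg.require_go_bp and not go_map:
        raise ValueError("require_go_bp=True but no GO map supplied")
    go_map = go_map or {}
    S = cpm.n_samples
    cutoff = math.ceil(cfg.sample_fraction * S)
    low = (cpm.values < cfg.cpm_threshold).sum(axis=1)
    kept = []
    for gene in cpm.gene_ids:
        if low[gene] >= cutoff:
            continue
        if cfg.require_go_bp and not go_map.get(gene):
            continue
        kept.append(gene)
    if not kept:
        raise ValueError(
            "no genes survive filtering; relax cpm_threshold/sample_fraction "
            "or provide GO annotations"
        )
    return kept


def log_transform(cpm: ExpressionMatrix, prior: float = 0.5) -> ExpressionMatrix:
    """log2(CPM + prior)."""
    cpm.require_stage("cpm")
    if prior <= 0:
        raise ValueError("prior must be positive")
    return cpm.advance(np.log2(cpm.values + prior), "log")


def smooth_quantile_normalize(
    logmat: ExpressionMatrix,
    groups: pd.Series | dict[str, str],
    window_fraction: float = 0.05,
) -> ExpressionMatrix:
    """Group-aware smoothed quantile normalization.

    Each sample's sorted values are replaced by a convex combination of
    the overall mean quantile profile and its group's mean profile,
    ``w*overall + (1-w)*group``.  The per-quantile weight
    ``w = SSW/(SSB+SSW)`` (within-group over total sum of squares across
    samples' quantile profiles) is smoothed with a running median whose
    window spans ``window_fraction`` of the quantiles: quantiles where
    groups genuinely differ (large SSB) keep their group profile, the
    rest are driven to the common profile.  Ties within a sample receive
    the average of their reference values; rank order is restored per
    sample.
    """
    logmat.require_stage("log")
    vals = logmat.values
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    groups = groups.reindex(vals.columns)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    counts = groups.value_counts()
    singles = counts[counts < 2]
    if len(singles):
        raise ValueError(f"groups with a single sample: {singles.index.tolist()}")

    X = vals.to_numpy(float)
    n_genes, n_samples = X.shape
    order = np.argsort(X, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(X, order, axis=0)  # quantile x sample

    overall = sorted_vals.mean(axis=1)
    group_names = sorted(counts.index)
    group_profiles = {}
    ssb = np.zeros(n_genes)
    ssw = np.zeros(n_genes)
    for g in group_names:
        cols = np.flatnonzero((groups == g).to_numpy())
        prof = sorted_vals[:, cols].mean(axis=1)
        group_profiles[g] = prof
        ssb += len(cols) * (prof - overall) ** 2
        ssw += ((sorted_vals[:, cols] - prof[:, None]) ** 2).sum(axis=1)

    total = ssb + ssw
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(total > 0, ssw / np.where(total > 0, total, 1.0), 1.0)
    window = max(1, int(round(window_fraction * n_genes)))
    if window > 1:
        w = median_filter(w, size=window, mode="nearest")

    out = np.empty_like(X)
    for s in range(n_samples):
        ref = w * overall + (1 - w) * group_profiles[groups.iloc[s]]
        col_order = order[:, s]
        new_sorted = ref.copy()
        # average reference values over runs of tied input values
        col_sorted_input = sorted_vals[:, s]
        boundaries = np.flatnonzero(np.diff(col_sorted_input) != 0) + 1
        for a, b in zip(np.r_[0, boundaries], np.r_[boundaries, n_genes]):
            if b - a > 1:
                new_sorted[a:b] = new_sorted[a:b].mean()
        out[col_order, s] = new_sorted

    return logmat.advance(
        pd.DataFrame(out, index=vals.index, columns=vals.columns), "normalized"
    )


def _design_columns(samples: SampleTable, covariates: list[str]) -> pd.DataFrame:
    """Expand covariates to numeric design columns (dummy-coded, drop-first)."""
    parts = []
    tab = samples.table
    for cov in covariates:
        col = tab[cov]
        if col.dtype.kind in "biufc":
            parts.append(col.astype(float).to_frame(cov))
        else:
            parts.append(pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float))
    if not parts:
        return pd.DataFrame(index=tab.index)
    return pd.concat(parts, axis=1)


def eb_adjust(normalized: ExpressionMatrix, samples: SampleTable) -> ExpressionMatrix:
    """Remove unwanted-covariate variation with empirical-Bayes shrinkage.

    Per gene, a linear model on all (retained + unwanted) covariates is
    fitted; unwanted-covariate coefficients are shrunk toward their
    across-gene mean with weight tau^2/(tau^2 + s_g^2) (between-gene
    variance over between + per-gene sampling variance) and only the
    unwanted fitted component is subtracted.  Retained covariates are
    untouched, so biological contrasts survive.
    """
    normalized.require_stage("normalized", "log")
    samples.check_matches(normalized)
    tab = samples.subset(normalized.sample_ids)
    Xr = _design_columns(tab, tab.retained)
    Xu = _design_columns(tab, tab.unwanted)
    if Xu.shape[1] == 0:
        return normalized.advance(normalized.values.copy(), "adjusted")

    Y = normalized.values.to_numpy(float)  # genes x samples
    n = Y.shape[1]
    Xr_c = Xr.to_numpy(float) - Xr.to_numpy(float).mean(axis=0, keepdims=True)
    Xu_c = Xu.to_numpy(float) - Xu.to_numpy(float).mean(axis=0, keepdims=True)
    X = np.column_stack([np.ones(n), Xr_c, Xu_c])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        cols = ["intercept", *Xr.columns, *Xu.columns]
        raise ValueError(f"design matrix rank deficient; check columns {cols}")

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ XtX_inv.T  # genes x coefficients
    resid = Y - beta @ X.T
    dof = max(n - X.shape[1], 1)
    sigma2 = (resid**2).sum(axis=1) / dof  # per-gene residual variance

    u_slice = slice(1 + Xr_c.shape[1], X.shape[1])
    b_u = beta[:, u_slice]  # genes x unwanted coefficients
    b_bar = b_u.mean(axis=0)
    tau2 = b_u.var(axis=0)  # between-gene variance per coefficient
    diag = np.diag(XtX_inv)[u_slice]
    s2 = sigma2[:, None] * diag[None, :]  # per-gene sampling variance
    denom = tau2[None, :] + s2
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.where(denom > 0, tau2[None, :] / np.where(denom > 0, denom, 1.0), 1.0)
    b_shrunk = lam * b_u + (1 - lam) * b_bar[None, :]

    adjusted = Y - b_shrunk @ Xu_c.T
    return normalized.advance(
        pd.DataFrame(adjusted, index=normalized.values.index,
                     columns=normalized.values.columns),
        "adjusted",
    )


def standardize(adjusted: ExpressionMatrix) -> tuple[ExpressionMatrix, list[str]]:
    """Center each gene to mean 0 and scale to unit (population) variance.

    Zero-variance genes cannot enter the GGM and are dropped; their ids
    are returned alongside the standardized matrix and logged.
    """
    adjusted.require_stage("adjusted")
    vals = adjusted.values
    sd = vals.std(axis=1, ddof=0)
    dropped = sd.index[sd == 0].tolist()
    if len(dropped) == len(sd):
        raise ValueError("all genes have zero variance")
    if dropped:
        log.info("dropping %d zero-variance genes: %s", len(dropped), dropped[:10])
    kept = vals.loc[sd > 0]
    out = kept.sub(kept.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)
    return adjusted.advance(out, "standardized"), dropped


def run_preprocess(
    counts: ExpressionMatrix,
    samples: SampleTable,
    cfg: GeneFilterConfig | None = None,
    go_map: dict[str, set[str]] | None = None,
) -> tuple[ExpressionMatrix, list[str]]:
    """Full chain: CPM -> filter -> log2 -> qsmooth -> EB adjust -> standardize.

    Returns the standardized matrix and the list of zero-variance genes
    dropped at the final step.
    """
    cfg = cfg or GeneFilterConfig()
    samples.check_matches(counts)
    cpm = compute_cpm(counts)
    kept = filter_genes(cpm, cfg, go_map)
    cpm = ExpressionMatrix(cpm.values.loc[kept], stage="cpm")
    logged = log_transform(cpm, cfg.log_prior)
    groups = samples.table.loc[logged.sample_ids, "condition"]
    normalized = smooth_quantile_normalize(logged, groups)
    adjusted = eb_adjust(normalized, samples)
    return standardize(adjusted)
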