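"""Joint Gaussian graphical model estimation across conditions.

Estimates K condition-specific sparse precision matrices from
standardized expression by minimizing, over symmetric PD Theta_k,

    sum_k [ tr(S_k Theta_k) - log det Theta_k ]
      + lambda1 * sum_k sum_{i!=j} |theta_ij^k|
      + lambda2 * sum_{k=1}^{K-1} sum_{i!=j} W_ij^{k,k+1} |theta_ij^k - theta_ij^{k+1}|

where S_k is the per-condition correlation matrix and the fusion penalty
runs sequentially along a chain of conditions ordered by hierarchical
clustering.  The binary weights W (condition-adaptive fusion) are set by
a Fisher-z screening test: gene pairs whose correlation differs
significantly between neighbouring conditions are left unfused.

The solver is ADMM with consensus splitting: the Theta-update is an
eigenvalue problem per condition, the Z-update is an elementwise fused
lasso along the chain followed by soft thresholding, solved in closed
form for fused runs of length two and by a small projected-gradient
(FISTA) dual solve for longer runs.  Sample sizes n_k enter the
screening statistics and the AIC used for penalty selection,

    AIC = sum_k [ n_k tr(S_k Theta_k) - n_k log det Theta_k + 2 E_k ],

with E_k the number of nonzero upper-triangle off-diagonal entries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, SampleTable


@dataclass
class CovarianceSet:
    """Per-condition empirical correlation matrices with sample counts."""

    S: dict[str, np.ndarray]
    n: dict[str, int]
    gene_ids: list[str]
    conditions: list[str]

    def __post_init__(self) -> None:
        p = len(self.gene_ids)
        for name in self.conditions:
            mat = self.S[name]
            if mat.shape != (p, p):
                raise ValueError(f"covariance for {name} has wrong shape")
            if not np.allclose(mat, mat.T, atol=1e-8):
                raise ValueError(f"covariance for {name} not symmetric")
            if not np.allclose(np.diag(mat), 1.0, atol=1e-8):
                raise ValueError(f"covariance for {name} lacks unit diagonal")
            if self.n[name] < 2:
                raise ValueError(f"condition {name} has fewer than 2 samples")

    @property
    def p(self) -> int:
        return len(self.gene_ids)


@dataclass
class PenaltyConfig:
    """Penalties and ADMM settings for joint estimation."""

    lambda1: float = 0.03
    lambda2: float = 0.03
    grid: list[float] = field(default_factory=lambda: [0.01, 0.03, 0.05])
    admm_max_iter: int = 100
    admm_tol: float = 0.001
    admm_rho: float = 1.0
    truncation: float = 0.05
    adaptive: bool = True
    screening_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("penalties must be nonnegative")
        if not (0 < self.truncation < 1):
            raise ValueError("truncation must lie in (0, 1)")
        if self.admm_max_iter < 1:
            raise ValueError("admm_max_iter must be >= 1")


@dataclass
class FusionWeights:
    """Binary fusion indicators per consecutive condition pair in the chain."""

    chain: list[str]
    W: dict[tuple[str, str], np.ndarray]

    def __post_init__(self) -> None:
        for pair in zip(self.chain[:-1], self.chain[1:]):
            if pair not in self.W:
                raise ValueError(f"missing weight matrix for chain pair {pair}")
            mat = self.W[pair]
            if not np.array_equal(mat, mat.T):
                raise ValueError(f"weight matrix for {pair} not symmetric")

    @classmethod
    def all_ones(cls, chain: list[str], p: int) -> "FusionWeights":
        return cls(
            chain=list(chain),
            W={pair: np.ones((p, p)) for pair in zip(chain[:-1], chain[1:])},
        )


@dataclass
class PrecisionSet:
    """Estimated precision matrices plus solver diagnostics."""

    thetas: dict[str, np.ndarray]
    gene_ids: list[str]
    conditions: list[str]
    lambda1: float
    lambda2: float
    n_iter: int
    primal_residual: float
    dual_residual: float
    converged: bool

    def support(self, condition: str, tol: float = 1e-10) -> set[tuple[int, int]]:
        """Upper-triangle index pairs with |theta| above ``tol``."""
        theta = self.thetas[condition]
        iu = np.triu_indices_from(theta, k=1)
        mask = np.abs(theta[iu]) > tol
        return set(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))

    def edge_count(self, condition: str, tol: float = 1e-10) -> int:
        return len(self.support(condition, tol))


# ---------------------------------------------------------------------------
# empirical covariance and condition ordering


def empirical_covariance(
    standardized: ExpressionMatrix, samples: SampleTable
) -> CovarianceSet:
    """Per-condition correlation matrices from globally standardized data.

    Rows are re-centered within each condition before the cross product
    and the diagonal is rescaled to exactly one.
    """
    standardized.require_stage("standardized")
    samples.check_matches(standardized)
    S: dict[str, np.ndarray] = {}
    n: dict[str, int] = {}
    conditions = [
        c
        for c in samples.conditions
        if set(samples.samples_for(c)) & set(standardized.sample_ids)
    ]
    for cond in conditions:
        cols = [s for s in standardized.sample_ids if s in set(samples.samples_for(cond))]
        if len(cols) < 2:
            raise ValueError(f"condition {cond} has fewer than 2 samples")
        X = standardized.values[cols].to_numpy(float)
        X = X - X.mean(axis=1, keepdims=True)
        cov = X @ X.T / len(cols)
        d = np.sqrt(np.diag(cov))
        if (d == 0).any():
            bad = [standardized.gene_ids[i] for i in np.flatnonzero(d == 0)]
            raise ValueError(
                f"genes with zero variance within condition {cond}: {bad[:5]}"
            )
        cov = cov / np.outer(d, d)
        np.fill_diagonal(cov, 1.0)
        S[cond] = (cov + cov.T) / 2
        n[cond] = len(cols)
    return CovarianceSet(S=S, n=n, gene_ids=standardized.gene_ids, conditions=conditions)


def order_conditions(
    standardized: ExpressionMatrix, samples: SampleTable
) -> list[str]:
    """Fusion chain: leaf order of average-linkage clustering of
    per-condition mean expression profiles (Euclidean distance), with
    ties resolved deterministically by sorting condition names first."""
    standardized.require_stage("standardized")
    names = sorted(samples.conditions)
    if len(names) < 2:
        return names
    in_matrix = set(standardized.sample_ids)
    profiles = np.vstack(
        [
            standardized.values[
                [s for s in samples.samples_for(c) if s in in_matrix]
            ].to_numpy(float).mean(axis=1)
            for c in names
        ]
    )
    Z = linkage(pdist(profiles, metric="euclidean"), method="average")
    return [names[i] for i in leaves_list(Z)]


# ---------------------------------------------------------------------------
# condition-adaptive screening


def screening_weights(
    covs: CovarianceSet, chain: list[str], alpha: float = 0.05
) -> FusionWeights:
    """Fisher-z screen for condition-specific gene pairs.

    For each consecutive chain pair and gene pair, the difference of
    Fisher-transformed correlations is tested
    (z = (atanh r_k - atanh r_{k+1}) / sqrt(1/(n_k-3) + 1/(n_{k+1}-3)));
    two-sided p-values are BH-adjusted across all gene pairs of that
    condition pair and fusion is disabled (W=0) where q < alpha.
    """
    p = covs.p
    iu = np.triu_indices(p, k=1)
    W: dict[tuple[str, str], np.ndarray] = {}
    for a, b in zip(chain[:-1], chain[1:]):
        na, nb = covs.n[a], covs.n[b]
        if na < 4 or nb < 4:
            raise ValueError("screening requires at least 4 samples per condition")
        clamp = 1 - 1e-12
        ra = np.clip(covs.S[a][iu], -clamp, clamp)
        rb = np.clip(covs.S[b][iu], -clamp, clamp)
        z = (np.arctanh(ra) - np.arctanh(rb)) / np.sqrt(
            1.0 / (na - 3) + 1.0 / (nb - 3)
        )
        pvals = 2 * norm.sf(np.abs(z))
        reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")[:4]
        mat = np.ones((p, p))
        mat[iu] = np.where(reject, 0.0, 1.0)
        mat = np.minimum(mat, mat.T)
        np.fill_diagonal(mat, 1.0)
        W[(a, b)] = mat
    return FusionWeights(chain=list(chain), W=W)


# ---------------------------------------------------------------------------
# ADMM solver


def _theta_update(S: np.ndarray, ZU: np.ndarray, rho: float) -> np.ndarray:
    """argmin tr(S T) - logdet T + (rho/2)||T - ZU||_F^2 via eigendecomposition."""
    d, V = np.linalg.eigh(rho * ZU - S)
    t = (d + np.sqrt(d**2 + 4 * rho)) / (2 * rho)
    return (V * t) @ V.T


def _tv1d_batch(a: np.ndarray, gamma: float, tol: float = 1e-12,
                max_iter: int = 2000) -> np.ndarray:
    """Total-variation prox of many independent 1-D signals (columns share
    length L = a.shape[0]); FISTA on the box-constrained dual."""
    L, m = a.shape
    if L == 1 or gamma == 0:
        return a.copy()
    if L == 2:
        shift = np.clip((a[1] - a[0]) / 2, -gamma, gamma)
        return np.vstack([a[0] + shift, a[1] - shift])
    Da = np.diff(a, axis=0)
    u = np.zeros((L - 1, m))
    y = u.copy()
    t_mom = 1.0
    step = 0.25  # 1 / ||D D^T||, spectral norm <= 4
    scale = max(1.0, np.abs(a).max())
    for _ in range(max_iter):
        # grad = D D^T y - D a
        DTy = np.empty((L, m))
        DTy[0] = -y[0]
        DTy[-1] = y[-1]
        if L > 2:
            DTy[1:-1] = y[:-1] - y[1:]
        grad = np.diff(DTy, axis=0) - Da
        u_new = np.clip(y - step * grad, -gamma, gamma)
        t_new = (1 + np.sqrt(1 + 4 * t_mom**2)) / 2
        y = u_new + ((t_mom - 1) / t_new) * (u_new - u)
        delta = np.abs(u_new - u).max()
        u, t_mom = u_new, t_new
        if delta < tol * scale:
            break
    x = a.copy()
    x[0] -= -u[0]
    x[-1] -= u[-1]
    if L > 2:
        x[1:-1] -= u[:-1] - u[1:]
    return x


def _fused_prox(
    a: np.ndarray, bits: np.ndarray, gamma: float
) -> np.ndarray:
    """Weighted fused-lasso prox along the chain for all gene pairs.

    ``a`` is (K, m): each column a chain of values for one gene pair.
    ``bits`` is (K-1, m) binary: 1 fuses neighbouring conditions with
    strength gamma, 0 decouples them.  Pairs are grouped by their weight
    pattern; within a pattern the chain splits into maximal fused runs.
    """
    K, m = a.shape
    if K == 1 or gamma == 0:
        return a.copy()
    out = np.empty_like(a)
    codes = np.zeros(m, dtype=np.int64)
    for k in range(K - 1):
        codes |= bits[k].astype(np.int64) << k
    for code in np.unique(codes):
        cols = np.flatnonzero(codes == code)
        sub = a[:, cols]
        res = np.empty_like(sub)
        start = 0
        for k in range(K):
            fused_next = k < K - 1 and (code >> k) & 1
            if not fused_next:
                res[start : k + 1] = _tv1d_batch(sub[start : k + 1], gamma)
                start = k + 1
        out[:, cols] = res
    return out


def _soft(a: np.ndarray, thresh: float) -> np.ndarray:
    return np.sign(a) * np.maximum(np.abs(a) - thresh, 0.0)


def _admm(
    S_list: list[np.ndarray],
    lambda1: float,
    lambda2: float,
    bits: np.ndarray | None,
    rho: float,
    max_iter: int,
    tol: float,
) -> tuple[list[np.ndarray], int, float, float, bool]:
    """Consensus ADMM for the sequential fused graphical lasso."""
    K = len(S_list)
    p = S_list[0].shape[0]
    iu = np.triu_indices(p, k=1)
    Theta = [np.eye(p) for _ in range(K)]
    Z = [np.eye(p) for _ in range(K)]
    U = [np.zeros((p, p)) for _ in range(K)]
    primal = dual = np.inf
    converged = False
    n_iter = 0
    for it in range(1, max_iter + 1):
        n_iter = it
        for k in range(K):
            Theta[k] = _theta_update(S_list[k], Z[k] - U[k], rho)
        Z_old = [z.copy() for z in Z]
        A = np.vstack([(Theta[k] + U[k])[iu] for k in range(K)])
        if K > 1 and lambda2 > 0 and bits is not None:
            A = _fused_prox(A, bits, lambda2 / rho)
        A = _soft(A, lambda1 / rho)
        for k in range(K):
            z = np.zeros((p, p))
            z[iu] = A[k]
            z = z + z.T
            np.fill_diagonal(z, np.diag(Theta[k] + U[k]))  # diagonal unpenalized
            Z[k] = z
        for k in range(K):
            U[k] = U[k] + Theta[k] - Z[k]
        primal = np.sqrt(sum(np.sum((Theta[k] - Z[k]) ** 2) for k in range(K)))
        dual = rho * np.sqrt(sum(np.sum((Z[k] - Z_old[k]) ** 2) for k in range(K)))
        norm_ref = max(
            1.0,
            np.sqrt(sum(np.sum(t**2) for t in Theta)),
            np.sqrt(sum(np.sum(z**2) for z in Z)),
        )
        norm_u = max(1.0, rho * np.sqrt(sum(np.sum(u**2) for u in U)))
        if primal <= tol * norm_ref and dual <= tol * norm_u:
            converged = True
            break
    Z = [(z + z.T) / 2 for z in Z]
    return Z, n_iter, primal, dual, converged


@dataclass
class GlassoResult:
    """Single-condition graphical lasso estimate."""

    theta: np.ndarray
    converged: bool
    n_iter: int
    primal_residual: float
    dual_residual: float


def glasso_single(
    S: np.ndarray,
    lambda1: float,
    max_iter: int = 100,
    tol: float = 1e-3,
    rho: float = 1.0,
) -> GlassoResult:
    """L1-penalized precision estimation for one condition.

    Minimizes tr(S Theta) - logdet Theta + lambda1 * sum_{i!=j}|theta_ij|
    (diagonal unpenalized).  Non-convergence within ``max_iter`` is
    flagged on the result, not raised.
    """
    S = np.asarray(S, float)
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("S must be symmetric")
    Z, n_iter, primal, dual, converged = _admm(
        [S], lambda1, 0.0, None, rho, max_iter, tol
    )
    return GlassoResult(
        theta=Z[0], converged=converged, n_iter=n_iter,
        primal_residual=primal, dual_residual=dual,
    )


def glasso_objective(S: np.ndarray, theta: np.ndarray, lambda1: float) -> float:
    """Penalized negative log-likelihood (minimization convention)."""
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return np.inf
    off = np.abs(theta).sum() - np.abs(np.diag(theta)).sum()
    return float(np.trace(S @ theta) - logdet + lambda1 * off)


def joint_objective(
    covs: CovarianceSet,
    thetas: dict[str, np.ndarray],
    lambda1: float,
    lambda2: float,
    weights: FusionWeights,
) -> float:
    """Full sequential fused-lasso objective (minimization convention)."""
    total = 0.0
    for cond in weights.chain:
        total += glasso_objective(covs.S[cond], thetas[cond], lambda1)
    iu = np.triu_indices(covs.p, k=1)
    for a, b in zip(weights.chain[:-1], weights.chain[1:]):
        w = weights.W[(a, b)][iu]
        total += 2 * lambda2 * float(
            np.sum(w * np.abs(thetas[a][iu] - thetas[b][iu]))
        )
    return total


def joint_estimate(
    covs: CovarianceSet,
    cfg: PenaltyConfig,
    weights: FusionWeights | None = None,
) -> PrecisionSet:
    """Jointly estimate all condition precision matrices by ADMM.

    ``weights`` fixes the fusion chain and the binary condition-adaptive
    indicators; when omitted, the chain is the CovarianceSet condition
    order with all pairs fused.
    """
    if not covs.conditions:
        raise ValueError("empty condition chain")
    if weights is None:
        weights = FusionWeights.all_ones(covs.conditions, covs.p)
    chain = weights.chain
    if set(chain) != set(covs.conditions):
        raise ValueError("weights chain does not match covariance conditions")
    p = covs.p
    iu = np.triu_indices(p, k=1)
    bits = None
    if len(chain) > 1:
        bits = np.vstack(
            [weights.W[(a, b)][iu] for a, b in zip(chain[:-1], chain[1:])]
        )
    S_list = [covs.S[c] for c in chain]
    Z, n_iter, primal, dual, converged = _admm(
        S_list, cfg.lambda1, cfg.lambda2, bits,
        cfg.admm_rho, cfg.admm_max_iter, cfg.admm_tol,
    )
    thetas = {c: Z[k] for k, c in enumerate(chain)}
    if converged:
        for c, theta in thetas.items():
            if np.linalg.eigvalsh(theta).min() <= 0:
                raise RuntimeError(
                    f"converged precision matrix for {c} is not positive definite"
                )
    return PrecisionSet(
        thetas=thetas,
        gene_ids=covs.gene_ids,
        conditions=chain,
        lambda1=cfg.lambda1,
        lambda2=cfg.lambda2,
        n_iter=n_iter,
        primal_residual=primal,
        dual_residual=dual,
        converged=converged,
    )


def aic_score(covs: CovarianceSet, fit: PrecisionSet) -> float:
    """AIC = sum_k n_k tr(S_k Theta_k) - n_k logdet Theta_k + 2 E_k."""
    total = 0.0
    for cond in fit.conditions:
        theta = fit.thetas[cond]
        sign, logdet = np.linalg.slogdet(theta)
        if sign <= 0:
            return np.inf
        nk = covs.n[cond]
        total += nk * float(np.trace(covs.S[cond] @ theta)) - nk * logdet
        total += 2 * fit.edge_count(cond)
    return total


def aic_grid_search(
    covs: CovarianceSet,
    grid: list[float] | None = None,
    weights: FusionWeights | None = None,
    cfg: PenaltyConfig | None = None,
) -> tuple[PrecisionSet, pd.DataFrame]:
    """Fit every (lambda1, lambda2) pair on the grid and pick the lowest AIC.

    Ties break toward smaller lambda1 then smaller lambda2 (the iteration
    order, with strictly-better replacement).  Non-convergent fits stay
    in the table, flagged, and remain eligible.
    """
    cfg = cfg or PenaltyConfig()
    grid = sorted(grid if grid is not None else cfg.grid)
    if not grid:
        raise ValueError("empty penalty grid")
    rows = []
    best: PrecisionSet | None = None
    best_aic = np.inf
    for lam1, lam2 in itertools.product(grid, grid):
        trial = PenaltyConfig(
            lambda1=lam1, lambda2=lam2, grid=grid,
            admm_max_iter=cfg.admm_max_iter, admm_tol=cfg.admm_tol,
            admm_rho=cfg.admm_rho, truncation=cfg.truncation,
            adaptive=cfg.adaptive, screening_alpha=cfg.screening_alpha,
        )
        fit = joint_estimate(covs, trial, weights)
        aic = aic_score(covs, fit)
        rows.append(
            {
                "lambda1": lam1,
                "lambda2": lam2,
                "aic": aic,
                "edges": sum(fit.edge_count(c) for c in fit.conditions),
                "iterations": fit.n_iter,
                "converged": fit.converged,
            }
        )
        if aic < best_aic:
            best, best_aic = fit, aic
    assert best is not None
    return best, pd.DataFrame(rows)


def infer_networks_input(
    standardized: ExpressionMatrix,
    samples: SampleTable,
    cfg: PenaltyConfig | None = None,
) -> tuple[PrecisionSet, pd.DataFrame, FusionWeights]:
    """Convenience wrapper: ordering, screening, and AIC grid search."""
    cfg = cfg or PenaltyConfig()
    covs_order = order_conditions(standardized, samples)
    covs = empirical_covariance(standardized, samples)
    covs = CovarianceSet(
        S={c: covs.S[c] for c in covs_order},
        n={c: covs.n[c] for c in covs_order},
        gene_ids=covs.gene_ids,
        conditions=covs_order,
    )
    if cfg.adaptive and len(covs_order) > 1:
        weights = screening_weights(covs, covs_order, cfg.screening_alpha)
    else:
        weights = FusionWeights.all_ones(covs_order, covs.p)
    best, table = aic_grid_search(covs, cfg.grid, weights, cfg)
    return best, table, weights
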