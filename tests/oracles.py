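"""Independent slow reference implementations used only to cross-check
the package.  These are deliberately written with different algorithms
from the implementation they validate and must stay that way."""

from __future__ import annotations

import math

import numpy as np


def glasso_dual_oracle(
    S: np.ndarray, lam: float, max_iter: int = 50000, tol: float = 1e-11
) -> np.ndarray:
    """Projected gradient ascent on the graphical-lasso dual.

    maximize log det W subject to |W_ij - S_ij| <= lam (i != j) and
    W_ii = S_ii; the primal precision matrix is W^{-1}.  Small, slow,
    and independent of the ADMM solver.
    """
    S = np.asarray(S, float)
    p = S.shape[0]
    W = S.copy()
    off = ~np.eye(p, dtype=bool)
    step = 0.1
    logdet_prev = -np.inf
    for _ in range(max_iter):
        grad = np.linalg.inv(W)  # gradient of logdet
        W_new = W + step * grad
        # project into the box; diagonal pinned to S
        W_new[off] = np.clip(W_new[off], (S - lam)[off], (S + lam)[off])
        np.fill_diagonal(W_new, np.diag(S))
        sign, logdet = np.linalg.slogdet(W_new)
        if sign <= 0 or logdet < logdet_prev - 1e-12:
            step *= 0.5
            if step < 1e-12:
                break
            continue
        delta = np.abs(W_new - W).max()
        W = W_new
        logdet_prev = logdet
        if delta < tol:
            break
    return np.linalg.inv(W)


def flood_fill_components(nodes: list, edges: list[tuple]) -> int:
    """Connected-component count by explicit flood fill."""
    adjacency: dict = {n: set() for n in nodes}
    for a, b in edges:
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)
    seen: set = set()
    count = 0
    for start in adjacency:
        if start in seen:
            continue
        count += 1
        stack = [start]
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            stack.extend(adjacency[node] - seen)
    return count


def conservation_oracle(species: set[str], clade_map: dict[str, str]) -> str:
    """Brute-force clade-conservation rule, written from the rule text."""
    has_t = has_b = has_z = False
    for sp in species:
        clade = clade_map[sp]
        if clade == "tracheophyte":
            has_t = True
        elif clade == "bryophyte":
            has_b = True
        elif clade == "zygnematophyte":
            has_z = True
    if has_t and has_b and has_z:
        return "conserved_ancestral"
    if has_t and has_b:
        return "land_plant"
    return "other"


def hypergeom_enumeration(k: int, N: int, K: int, n: int) -> float:
    """Exact upper-tail hypergeometric probability by full enumeration."""
    denom = math.comb(N, n)
    total = 0
    for i in range(k, min(K, n) + 1):
        if n - i > N - K:
            continue
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / denom


def bh_stepup_oracle(pvals: list[float]) -> list[float]:
    """Hand-rolled BH step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m - 1, -1, -1):
        running = min(running, pvals[order[rank]] * m / (rank + 1))
        q_sorted[rank] = min(running, 1.0)
    out = [0.0] * m
    for rank, idx in enumerate(order):
        out[idx] = q_sorted[rank]
    return out
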