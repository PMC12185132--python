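"""GO overrepresentation analysis of gene sets.

Hypergeometric upper-tail tests of annotation terms in a query set
against the background that fed the network (term sizes are computed on
the background-projected annotation, not the raw one), with
Benjamini-Hochberg adjustment across tested terms.  Terms are used as
annotated; no GO-DAG ancestor propagation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentResult:
    term: str
    k: int  # hits in query
    n: int  # query size
    K: int  # term size in background
    N: int  # background size
    p: float
    q: float


def bh_adjust(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values (capped at 1, order-preserving)."""
    if not len(pvals):
        return []
    if any(p < 0 or p > 1 for p in pvals):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1].tolist()


def hypergeom_upper(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeom(N population, K marked, n drawn)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def ora(
    query: list[str],
    background: list[str],
    go_map: dict[str, set[str]],
    min_size: int = 10,
    max_size: int = 500,
    p_cut: float = 0.05,
    q_cut: float = 0.05,
) -> list[EnrichmentResult]:
    """Overrepresentation of GO terms in ``query`` against ``background``.

    Terms are restricted to those whose background-projected size K lies
    in [min_size, max_size]; p = P[X >= k] under the hypergeometric null;
    q-values are BH across all tested terms; output is filtered to
    p <= p_cut and q <= q_cut and sorted by (q, p, term).
    """
    if not go_map:
        raise ValueError("empty GO map")
    bg = set(background)
    offenders = sorted(set(query) - bg)
    if offenders:
        raise ValueError(f"query genes not in background: {offenders[:10]}")
    qset = set(query)

    term_genes: dict[str, set[str]] = {}
    for gene in bg:
        for term in go_map.get(gene, ()):
            term_genes.setdefault(term, set()).add(gene)

    N, n = len(bg), len(qset)
    tested = []
    for term in sorted(term_genes):
        K = len(term_genes[term])
        if not (min_size <= K <= max_size):
            continue
        k = len(term_genes[term] & qset)
        tested.append((term, k, K, hypergeom_upper(k, N, K, n)))
    if not tested:
        return []
    qvals = bh_adjust([t[3] for t in tested])
    results = [
        EnrichmentResult(term=term, k=k, n=n, K=K, N=N, p=p, q=q)
        for (term, k, K, p), q in zip(tested, qvals)
        if p <= p_cut and q <= q_cut
    ]
    return sorted(results, key=lambda r: (r.q, r.p, r.term))


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    cols = ["term", "k", "n", "K", "N", "p", "q"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results],
                        columns=cols)
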