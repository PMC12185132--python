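"""Synthetic data with known ground truth.

Generates (i) sets of sparse positive-definite precision matrices sharing
a common edge backbone, (ii) overdispersed RNA-seq-like count matrices
whose latent log-expression follows the corresponding multivariate
normal, with batch offsets and variable library sizes, and (iii)
multi-species panels of HOG-level edges with planted clade-conserved
pairs.  Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GroundTruth,
    Pair,
    SampleTable,
    SpeciesPanelTruth,
    canonical_pair,
)

#: Default nine-species panel and clade assignment mirroring a
#: streptophyte study design: four tracheophytes, two bryophytes, two
#: zygnematophytes, and a chlorophyte outgroup.
DEFAULT_CLADE_MAP: dict[str, str] = {
    "A.thaliana": "tracheophyte",
    "O.sativa": "tracheophyte",
    "Z.mays": "tracheophyte",
    "S.lycopersicum": "tracheophyte",
    "P.patens": "bryophyte",
    "M.polymorpha": "bryophyte",
    "Z.circumcarinatum": "zygnematophyte",
    "M.endlicherianum": "zygnematophyte",
    "C.reinhardtii": "outgroup",
}

#: Clades a HOG edge must touch to count as conserved since the last
#: common ancestor of land plants and zygnematophyte algae.
CONSERVED_CLADES = frozenset({"tracheophyte", "bryophyte", "zygnematophyte"})
LAND_PLANT_CLADES = frozenset({"tracheophyte", "bryophyte"})


def _all_pairs(p: int) -> list[Pair]:
    return list(itertools.combinations(range(p), 2))


def make_precision_set(
    p: int,
    K: int,
    shared_density: float,
    specific_density: float,
    magnitude: float = 0.3,
    seed: int = 0,
) -> GroundTruth:
    """Build K sparse PD precision matrices with a shared edge backbone.

    A fraction ``shared_density`` of the p(p-1)/2 off-diagonal positions
    receives an entry of +/- ``magnitude`` in every condition; each
    condition additionally receives ``specific_density`` private
    positions.  Diagonals start at 1 and are repaired to diagonal
    dominance (adding |min eigenvalue| + 0.1) whenever the minimum
    eigenvalue falls below 0.1, so every matrix is comfortably PD.

    Returns a :class:`~stressnet.containers.GroundTruth` recording the
    matrices and the exact shared/specific supports.
    """
    if p < 3:
        raise ValueError("p must be >= 3")
    if K < 1:
        raise ValueError("K must be >= 1")
    total = shared_density + specific_density
    if not (0 <= shared_density and 0 <= specific_density and total < 0.5):
        raise ValueError("need 0 <= shared_density + specific_density < 0.5")

    rng = np.random.default_rng(seed)
    pairs = _all_pairs(p)
    n_pairs = len(pairs)
    n_shared = int(np.floor(shared_density * n_pairs))
    n_specific = int(np.floor(specific_density * n_pairs))

    order = rng.permutation(n_pairs)
    shared_idx = order[:n_shared]
    remaining = order[n_shared:]
    shared = {pairs[i] for i in shared_idx}

    conditions = [f"cond{k + 1}" for k in range(K)]
    shared_signs = rng.choice([-1.0, 1.0], size=n_shared)

    precision: dict[str, np.ndarray] = {}
    specific: dict[str, set[Pair]] = {}
    for k, name in enumerate(conditions):
        theta = np.eye(p)
        for s, idx in zip(shared_signs, shared_idx):
            i, j = pairs[idx]
            theta[i, j] = theta[j, i] = s * magnitude
        # private positions drawn (without replacement) from the non-shared pool
        pick = rng.choice(len(remaining), size=n_specific, replace=False) if n_specific else []
        spec_pairs = {pairs[remaining[i]] for i in pick}
        for i, j in spec_pairs:
            theta[i, j] = theta[j, i] = rng.choice([-1.0, 1.0]) * magnitude
        min_eig = np.linalg.eigvalsh(theta).min()
        if min_eig < 0.1:
            theta += (abs(min_eig) + 0.1) * np.eye(p)
        assert np.linalg.eigvalsh(theta).min() > 0, "repair failed to make theta PD"
        precision[name] = theta
        specific[name] = spec_pairs

    return GroundTruth(
        precision_set=precision,
        shared_support=shared,
        specific_support=specific,
        condition_names=conditions,
    )


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def simulate_expression(
    truth: GroundTruth,
    n_per_condition: list[int],
    batch_offsets: dict[str, float] | None = None,
    libsize_range: tuple[float, float] = (5e5, 2e6),
    dispersion: float = 0.1,
    seed: int = 0,
    return_latent: bool = False,
) -> tuple[ExpressionMatrix, SampleTable] | tuple[ExpressionMatrix, SampleTable, pd.DataFrame]:
    """Simulate an overdispersed count matrix from a GGM ground truth.

    Per sample in condition k a latent gene vector z ~ MVN(0, Theta_k^-1)
    is drawn; expected expression is softplus(z + gene baseline + batch
    offset), converted to proportions and scaled to a library size drawn
    uniformly from ``libsize_range``.  Counts are negative-binomial
    (gamma-Poisson, dispersion ``dispersion``) and then rescaled so each
    column sums to its sampled library size up to rounding.  Batches are
    cycled within each condition so batch is never confounded with
    condition.
    """
    K = len(truth.condition_names)
    if len(n_per_condition) != K:
        raise ValueError("n_per_condition length must equal number of conditions")
    if any(n < 2 for n in n_per_condition):
        raise ValueError("need at least 2 samples per condition")
    lo, hi = libsize_range
    if lo <= 0 or hi <= 0 or hi < lo:
        raise ValueError("libsize_range must be a positive (low, high) pair")
    if batch_offsets is None:
        batch_offsets = {"batch1": 0.0}
    batch_names = sorted(batch_offsets)

    rng = np.random.default_rng(seed)
    p = truth.p
    baseline = rng.uniform(2.0, 6.0, size=p)  # per-gene log-scale abundance

    columns, cond_col, batch_col = [], [], []
    mats, latents = [], []
    for name, n_k in zip(truth.condition_names, n_per_condition):
        sigma = np.linalg.inv(truth.precision_set[name])
        z = rng.multivariate_normal(np.zeros(p), sigma, size=n_k, method="cholesky")
        latents.append(z.T)
        for s in range(n_k):
            batch = batch_names[s % len(batch_names)]
            sample_id = f"{name}_s{s + 1}"
            mu = _softplus(z[s] + baseline + batch_offsets[batch])
            libsize = rng.uniform(lo, hi)
            mean = mu / mu.sum() * libsize
            lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
            raw = rng.poisson(lam).astype(float)
            if raw.sum() > 0:
                counts = np.rint(raw * libsize / raw.sum())
            else:  # pragma: no cover - degenerate draw
                counts = raw
            mats.append(counts)
            columns.append(sample_id)
            cond_col.append(name)
            batch_col.append(batch)

    values = pd.DataFrame(
        np.column_stack(mats),
        index=[f"g{i + 1}" for i in range(p)],
        columns=columns,
    )
    meta = pd.DataFrame(
        {"sample": columns, "condition": cond_col, "batch": batch_col}
    )
    counts_mat = ExpressionMatrix(values=values, stage="counts")
    samples = SampleTable(table=meta)
    if return_latent:
        latent = pd.DataFrame(
            np.hstack(latents), index=values.index, columns=values.columns
        )
        return counts_mat, samples, latent
    return counts_mat, samples


def simulate_go_annotations(
    gene_ids: list[str],
    n_terms: int = 20,
    terms_per_gene: tuple[int, int] = (1, 4),
    annotated_fraction: float = 1.0,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Assign synthetic GO-BP-style term ids to genes (pipeline plumbing).

    A fraction ``annotated_fraction`` of genes receives between
    ``terms_per_gene[0]`` and ``terms_per_gene[1]`` terms drawn from a
    pool of ``n_terms`` identifiers shaped like real GO ids.
    """
    rng = np.random.default_rng(seed)
    pool = [f"GO:{7000000 + t:07d}" for t in range(n_terms)]
    lo, hi = terms_per_gene
    go_map: dict[str, set[str]] = {}
    for g in gene_ids:
        if rng.uniform() > annotated_fraction:
            continue
        k = int(rng.integers(lo, hi + 1))
        go_map[g] = set(rng.choice(pool, size=min(k, len(pool)), replace=False))
    return go_map


def _violating_species_set(
    rng: np.random.Generator, by_clade: dict[str, list[str]]
) -> list[str]:
    """Species set that misses >= 1 clade required by the conservation rule."""
    required = sorted(CONSERVED_CLADES & set(by_clade))
    drop = rng.choice(required)  # clade deliberately left without support
    allowed = [
        sp
        for clade, members in sorted(by_clade.items())
        if clade != drop
        for sp in members
    ]
    size = int(rng.integers(1, len(allowed) + 1))
    return sorted(rng.choice(allowed, size=size, replace=False))


def make_species_panel(
    clade_map: dict[str, str] | None = None,
    hogs: int = 40,
    conserved_fraction: float = 0.2,
    n_edges: int | None = None,
    conditions: tuple[str, ...] = ("control", "heat"),
    genes_per_hog: int = 2,
    seed: int = 0,
) -> SpeciesPanelTruth:
    """Plant a multi-species panel of HOG edges with known conservation.

    ``round(conserved_fraction * n_edges)`` HOG pairs are realized in at
    least one species of every clade required by the conservation rule;
    all other pairs are given species support that misses at least one
    required clade, so a correct classifier recovers exactly the planted
    set.  Each HOG owns ``genes_per_hog`` genes per species, and each
    realized HOG edge expands to one or more concrete gene-gene edges.
    """
    if clade_map is None:
        clade_map = dict(DEFAULT_CLADE_MAP)
    by_clade: dict[str, list[str]] = {}
    for sp, clade in clade_map.items():
        by_clade.setdefault(clade, []).append(sp)
    for clade in sorted(by_clade):
        by_clade[clade].sort()
    missing = CONSERVED_CLADES - set(by_clade)
    if missing:
        raise ValueError(f"clade map lacks required clades: {sorted(missing)}")

    if n_edges is None:
        n_edges = hogs
    rng = np.random.default_rng(seed)
    hog_ids = [f"N0.HOG{h + 1:07d}" for h in range(hogs)]
    all_hog_pairs = list(itertools.combinations(hog_ids, 2))
    if n_edges > len(all_hog_pairs):
        raise ValueError("more edges requested than available HOG pairs")
    chosen = rng.choice(len(all_hog_pairs), size=n_edges, replace=False)
    n_conserved = int(round(conserved_fraction * n_edges))

    species = sorted(clade_map)
    hog_maps: dict[str, dict[str, str]] = {}
    genes_of: dict[str, dict[str, list[str]]] = {}
    for sp in species:
        hog_maps[sp] = {}
        genes_of[sp] = {}
        for hog in hog_ids:
            names = [f"{sp}|{hog.split('HOG')[1]}_{g}" for g in range(genes_per_hog)]
            genes_of[sp][hog] = names
            for g in names:
                hog_maps[sp][g] = hog

    edge_lists: dict[str, dict[str, list[tuple[str, str]]]] = {
        sp: {c: [] for c in conditions} for sp in species
    }
    planted_conserved: set[tuple[str, str]] = set()

    for rank, idx in enumerate(chosen):
        ha, hb = all_hog_pairs[idx]
        if rank < n_conserved:
            support = sorted(
                {rng.choice(by_clade[clade]) for clade in sorted(CONSERVED_CLADES)}
            )
            planted_conserved.add((ha, hb))
        else:
            support = _violating_species_set(rng, by_clade)
        for sp in support:
            cond = conditions[int(rng.integers(len(conditions)))]
            ga = genes_of[sp][ha][int(rng.integers(genes_per_hog))]
            gb = genes_of[sp][hb][int(rng.integers(genes_per_hog))]
            edge_lists[sp][cond].append((ga, gb))

    return SpeciesPanelTruth(
        species=species,
        hog_maps=hog_maps,
        edge_lists=edge_lists,
        planted_conserved=planted_conserved,
    )
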