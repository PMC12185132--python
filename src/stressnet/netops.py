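"""Network construction, comparison, and cross-species conservation.

Precision matrices become per-condition gene networks by thresholding
partial correlations; condition networks are unioned per species,
projected into hierarchical-orthogroup (HOG) space using OrthoFinder
N0-style maps, compared across species, and each HOG edge is classified
by the clades of the species supporting it: an edge backed by at least
one tracheophyte, one bryophyte, and one zygnematophyte is inferred
conserved since the last common ancestor of land plants and
zygnematophyte algae; tracheophyte + bryophyte support only marks it
land-plant-specific.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import networkx as nx
import numpy as np
import pandas as pd

from .ggm import PrecisionSet

log = logging.getLogger(__name__)

CONSERVED_CLADES = frozenset({"tracheophyte", "bryophyte", "zygnematophyte"})
LAND_PLANT_CLADES = frozenset({"tracheophyte", "bryophyte"})


class ConservationLabel(str, Enum):
    CONSERVED_ANCESTRAL = "conserved_ancestral"
    LAND_PLANT = "land_plant"
    OTHER = "other"


@dataclass
class Network:
    """Per-condition (or union) gene graph; weights are partial correlations."""

    species: str
    condition: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}

    def weight(self, a: str, b: str) -> float:
        return self.graph.edges[a, b]["weight"]


@dataclass
class HogNetwork:
    """HOG-level graph; every edge carries (species, condition) provenance."""

    edges: dict[tuple[str, str], set[tuple[str, str]]] = field(default_factory=dict)
    dropped_unmapped: int = 0
    dropped_self_hog: int = 0

    def add(self, ha: str, hb: str, provenance: set[tuple[str, str]]) -> None:
        key = (ha, hb) if ha < hb else (hb, ha)
        self.edges.setdefault(key, set()).update(provenance)

    def species_of(self, pair: tuple[str, str]) -> set[str]:
        return {sp for sp, _ in self.edges[pair]}


def precision_to_network(
    theta: np.ndarray,
    gene_ids: list[str],
    tau: float = 0.05,
    species: str = "species",
    condition: str = "condition",
) -> Network:
    """Threshold partial correlations into an adjacency graph.

    Edge weight r_ij = -theta_ij / sqrt(theta_ii * theta_jj); an edge is
    kept iff |r_ij| >= tau.  All genes stay as nodes so isolated nodes
    count toward component statistics.
    """
    theta = np.asarray(theta, float)
    d = np.diag(theta)
    if (d <= 0).any():
        raise ValueError("precision matrix has nonpositive diagonal entries")
    scale = np.sqrt(d)
    pcorr = -theta / np.outer(scale, scale)
    g = nx.Graph()
    g.add_nodes_from(gene_ids)
    iu = np.triu_indices_from(theta, k=1)
    keep = np.abs(pcorr[iu]) >= tau
    for i, j in zip(iu[0][keep], iu[1][keep]):
        g.add_edge(gene_ids[i], gene_ids[j], weight=float(pcorr[i, j]))
    return Network(species=species, condition=condition, graph=g)


def networks_from_precision_set(
    fit: PrecisionSet, tau: float = 0.05, species: str = "species"
) -> dict[str, Network]:
    return {
        cond: precision_to_network(fit.thetas[cond], fit.gene_ids, tau, species, cond)
        for cond in fit.conditions
    }


def union_conditions(networks: list[Network]) -> Network:
    """Union of one species' condition networks.

    Edge weight is the maximum |weight| across contributing conditions
    (sign of the maximizing condition kept); each edge records the list
    of contributing conditions under the ``conditions`` attribute.
    """
    if not networks:
        raise ValueError("no networks to union")
    species = {n.species for n in networks}
    if len(species) != 1:
        raise ValueError(f"union across mixed species: {sorted(species)}")
    g = nx.Graph()
    for net in networks:
        g.add_nodes_from(net.graph.nodes)
        for a, b, data in net.graph.edges(data=True):
            if g.has_edge(a, b):
                attrs = g.edges[a, b]
                attrs["conditions"].append(net.condition)
                if abs(data["weight"]) > abs(attrs["weight"]):
                    attrs["weight"] = data["weight"]
            else:
                g.add_edge(a, b, weight=data["weight"], conditions=[net.condition])
    return Network(species=species.pop(), condition="union", graph=g)


def differential_edges(
    net_a: Network, net_b: Network
) -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    """(forming, dissolving): edges present only in A, resp. only in B."""
    if net_a.species != net_b.species:
        raise ValueError("differential comparison across species")
    ea, eb = net_a.edges, net_b.edges
    return ea - eb, eb - ea


def network_stats(net: Network, top_n: int = 10) -> dict:
    """Edge/node/component counts and top hubs by degree.

    Hub ties break lexicographically by gene id; isolated nodes count as
    singleton components.
    """
    g = net.graph
    comps = list(nx.connected_components(g))
    degree = dict(g.degree())
    hubs = sorted(degree, key=lambda n: (-degree[n], n))[:top_n]
    return {
        "edges": g.number_of_edges(),
        "nodes": g.number_of_nodes(),
        "components": len(comps),
        "largest_component": max((len(c) for c in comps), default=0),
        "hubs": [(h, degree[h]) for h in hubs],
    }


def neighborhood_of_set(net: Network, seeds: list[str]) -> list[str]:
    """First-degree neighbours of any seed gene, seeds excluded, sorted."""
    known = [s for s in seeds if s in net.graph]
    unknown = sorted(set(seeds) - set(known))
    if unknown:
        if not known:
            raise ValueError(f"no seed genes present in network: {unknown[:5]}")
        log.warning("skipping unknown seed genes: %s", unknown[:10])
    out: set[str] = set()
    for s in known:
        out.update(net.graph.neighbors(s))
    return sorted(out - set(seeds))


# ---------------------------------------------------------------------------
# orthogroup projection


def parse_hog_map(
    path, species_columns: list[str] | None = None
) -> dict[str, dict[str, str]]:
    """Read an OrthoFinder N0.tsv file into per-species gene->HOG maps.

    Expects the header ``HOG  OG  Gene Tree Parent Clade`` followed by
    one column per species containing comma-separated gene lists.  A
    gene assigned to two HOGs is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    fixed = ["HOG", "OG", "Gene Tree Parent Clade"]
    for col in fixed:
        if col not in df.columns:
            raise ValueError(f"N0 file lacks required column {col!r}")
    species = species_columns or [c for c in df.columns if c not in fixed]
    maps: dict[str, dict[str, str]] = {sp: {} for sp in species}
    for line, row in enumerate(df.itertuples(index=False), start=2):
        hog = row[df.columns.get_loc("HOG")]
        if not hog:
            raise ValueError(f"malformed N0 row at line {line}: empty HOG id")
        for sp in species:
            cell = row[df.columns.get_loc(sp)]
            if not cell:
                continue
            for gene in (g.strip() for g in cell.split(",")):
                if not gene:
                    continue
                prev = maps[sp].get(gene)
                if prev is not None and prev != hog:
                    raise ValueError(
                        f"gene {gene!r} assigned to both {prev} and {hog} "
                        f"(line {line})"
                    )
                maps[sp][gene] = hog
    return maps


def write_hog_map(maps: dict[str, dict[str, str]], path) -> None:
    """Write per-species gene->HOG maps back to the N0.tsv dialect."""
    hogs = sorted({h for m in maps.values() for h in m.values()})
    species = sorted(maps)
    rows = []
    for hog in hogs:
        row = {"HOG": hog, "OG": hog.replace("N0.HOG", "OG"), "Gene Tree Parent Clade": "n0"}
        for sp in species:
            genes = sorted(g for g, h in maps[sp].items() if h == hog)
            row[sp] = ", ".join(genes)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def project_to_hogs(net: Network, hog_map: dict[str, str]) -> HogNetwork:
    """Collapse a gene network into HOG space.

    Edges with an unmapped endpoint are dropped and counted; edges whose
    endpoints share a HOG (within-orthogroup paralog pairs) are dropped
    too, since they carry no cross-species signal.
    """
    out = HogNetwork()
    for a, b in net.edges:
        ha, hb = hog_map.get(a), hog_map.get(b)
        if ha is None or hb is None:
            out.dropped_unmapped += 1
            continue
        if ha == hb:
            out.dropped_self_hog += 1
            continue
        out.add(ha, hb, {(net.species, net.condition)})
    return out


def merge_hog_networks(hog_nets: list[HogNetwork]) -> HogNetwork:
    """Union of HOG networks with provenance merged per edge."""
    out = HogNetwork()
    for net in hog_nets:
        for pair, prov in net.edges.items():
            out.add(*pair, prov)
        out.dropped_unmapped += net.dropped_unmapped
        out.dropped_self_hog += net.dropped_self_hog
    return out


def intersect_across_species(hog_nets: list[HogNetwork]) -> HogNetwork:
    """HOG edges present in every input; provenance unioned."""
    if len(hog_nets) < 2:
        raise ValueError("need at least two HOG networks to intersect")
    common = set(hog_nets[0].edges)
    for net in hog_nets[1:]:
        common &= set(net.edges)
    out = HogNetwork()
    for pair in common:
        for net in hog_nets:
            out.add(*pair, net.edges[pair])
    return out


def classify_conservation(
    provenance: set[tuple[str, str]], clade_map: dict[str, str]
) -> ConservationLabel:
    """Clade-conservation rule on the species set supporting a HOG edge."""
    species = {sp for sp, _ in provenance}
    missing = species - set(clade_map)
    if missing:
        raise ValueError(f"species without clade assignment: {sorted(missing)}")
    clades = {clade_map[sp] for sp in species}
    if CONSERVED_CLADES <= clades:
        return ConservationLabel.CONSERVED_ANCESTRAL
    if LAND_PLANT_CLADES <= clades:
        return ConservationLabel.LAND_PLANT
    return ConservationLabel.OTHER


def classify_network(
    hog_net: HogNetwork, clade_map: dict[str, str]
) -> dict[tuple[str, str], ConservationLabel]:
    return {
        pair: classify_conservation(prov, clade_map)
        for pair, prov in sorted(hog_net.edges.items())
    }


def clade_sharing_tallies(
    hog_net: HogNetwork, clade_map: dict[str, str]
) -> pd.DataFrame:
    """Shared/exclusive edge counts per clade combination.

    For every unordered clade pair (X, Y): edges supported by >= 1
    species of each.  For every clade X: edges whose entire provenance
    lies within X ("exclusive"); exclusive sets are disjoint across
    clades by construction.
    """
    clades = sorted(set(clade_map.values()))
    if len(clades) < 2:
        raise ValueError("need at least two clades for sharing tallies")
    pair_counts = {
        (a, b): 0 for i, a in enumerate(clades) for b in clades[i + 1:]
    }
    exclusive = {c: 0 for c in clades}
    for pair, prov in hog_net.edges.items():
        edge_clades = {clade_map[sp] for sp, _ in prov}
        for (a, b) in pair_counts:
            if a in edge_clades and b in edge_clades:
                pair_counts[(a, b)] += 1
        if len(edge_clades) == 1:
            exclusive[next(iter(edge_clades))] += 1
    rows = [
        {"clade_a": a, "clade_b": b, "kind": "shared", "edges": n}
        for (a, b), n in pair_counts.items()
    ] + [
        {"clade_a": c, "clade_b": c, "kind": "exclusive", "edges": n}
        for c, n in exclusive.items()
    ]
    return pd.DataFrame(rows)
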