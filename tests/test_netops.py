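"""Network construction, set algebra, HOG projection, and the
clade-conservation classifier (checked exhaustively against an oracle)."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import conservation_oracle, flood_fill_components
from stressnet import netops, synth
from stressnet.netops import ConservationLabel, HogNetwork, Network


def toy_net(edges, species="sp", condition="c", nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a, b, *w in edges:
        g.add_edge(a, b, weight=w[0] if w else 1.0)
    return Network(species=species, condition=condition, graph=g)


class TestPrecisionToNetwork:
    def test_two_gene_partial_correlation(self):
        theta = np.array([[1.0, -0.3], [-0.3, 1.0]])
        net = netops.precision_to_network(theta, ["a", "b"], tau=0.05)
        assert net.edges == {("a", "b")}
        assert net.weight("a", "b") == pytest.approx(0.3)

    def test_truncation_drops_weak_edges(self):
        theta = np.array([[1.0, -0.04], [-0.04, 1.0]])
        net = netops.precision_to_network(theta, ["a", "b"], tau=0.05)
        assert net.edges == set()
        assert net.nodes == {"a", "b"}  # isolated nodes retained

    def test_diagonal_precision_gives_empty_graph(self):
        net = netops.precision_to_network(np.eye(4) * 2, list("wxyz"), tau=0.05)
        stats = netops.network_stats(net)
        assert stats["edges"] == 0 and stats["components"] == 4

    def test_nonpositive_diagonal_rejected(self):
        theta = np.array([[0.0, 0.1], [0.1, 1.0]])
        with pytest.raises(ValueError):
            netops.precision_to_network(theta, ["a", "b"])


class TestUnionAndDifference:
    def test_disjoint_union(self):
        u = netops.union_conditions(
            [toy_net([("a", "b")], condition="c1"),
             toy_net([("c", "d")], condition="c2")]
        )
        assert u.edges == {("a", "b"), ("c", "d")}
        assert u.condition == "union"

    def test_union_idempotent_and_max_weight(self):
        n1 = toy_net([("a", "b", 0.2)], condition="c1")
        n2 = toy_net([("a", "b", -0.6)], condition="c2")
        u = netops.union_conditions([n1, n2])
        assert u.edges == {("a", "b")}
        assert u.weight("a", "b") == pytest.approx(-0.6)  # max |weight|, sign kept
        again = netops.union_conditions([n1, n1])
        assert again.edges == n1.edges

    def test_union_mixed_species_rejected(self):
        with pytest.raises(ValueError):
            netops.union_conditions(
                [toy_net([("a", "b")], species="s1"),
                 toy_net([("a", "b")], species="s2")]
            )

    def test_differential_edges_identities(self):
        a = toy_net([("a", "b"), ("b", "c")])
        b = toy_net([("b", "c"), ("c", "d")])
        forming, dissolving = netops.differential_edges(a, b)
        assert forming == {("a", "b")} and dissolving == {("c", "d")}
        same_f, same_d = netops.differential_edges(a, a)
        assert same_f == set() == same_d
        assert len(forming) + len(a.edges & b.edges) == len(a.edges)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**20))
    def test_union_size_bounded_by_sum(self, bits):
        pairs = list(itertools.combinations(range(7), 2))
        e1 = [(f"g{a}", f"g{b}") for i, (a, b) in enumerate(pairs) if bits >> i & 1]
        e2 = [(f"g{a}", f"g{b}") for i, (a, b) in enumerate(pairs) if bits >> (i + 10) & 1]
        u = netops.union_conditions(
            [toy_net(e1, condition="c1"), toy_net(e2, condition="c2")]
        )
        assert len(u.edges) <= len(e1) + len(e2)
        assert (len(u.edges) == len(e1) + len(e2)) == (not set(e1) & set(e2))


class TestStatsAndNeighborhood:
    def test_path_graph_stats(self):
        net = toy_net([("a", "b"), ("b", "c")])
        s = netops.network_stats(net)
        assert (s["edges"], s["nodes"], s["components"]) == (2, 3, 1)
        assert s["hubs"][0] == ("b", 2)

    def test_component_count_matches_flood_fill(self):
        rng = np.random.default_rng(12)
        nodes = [f"g{i}" for i in range(30)]
        edges = [
            (nodes[i], nodes[j])
            for i, j in itertools.combinations(range(30), 2)
            if rng.uniform() < 0.05
        ]
        net = toy_net(edges, nodes=nodes)
        assert netops.network_stats(net)["components"] == flood_fill_components(
            nodes, edges
        )

    def test_neighborhood_excludes_seeds(self):
        net = toy_net([("a", "b"), ("b", "c")])
        assert netops.neighborhood_of_set(net, ["b"]) == ["a", "c"]
        assert netops.neighborhood_of_set(net, ["a", "b"]) == ["c"]

    def test_unknown_seeds_skipped_all_unknown_raises(self):
        net = toy_net([("a", "b")])
        assert netops.neighborhood_of_set(net, ["a", "zz"]) == ["b"]
        with pytest.raises(ValueError):
            netops.neighborhood_of_set(net, ["zz"])


N0_TEXT = (
    "HOG\tOG\tGene Tree Parent Clade\tspeciesA\tspeciesB\n"
    "N0.HOG0000001\tOG01\tn0\tgeneA1, geneA2\tgeneB1\n"
    "N0.HOG0000002\tOG02\tn0\tgeneA3\t\n"
)


class TestHogMap:
    def test_parse_constructed_row(self, tmp_path):
        path = tmp_path / "N0.tsv"
        path.write_text(N0_TEXT)
        maps = netops.parse_hog_map(path)
        assert maps["speciesA"] == {
            "geneA1": "N0.HOG0000001",
            "geneA2": "N0.HOG0000001",
            "geneA3": "N0.HOG0000002",
        }
        assert maps["speciesB"] == {"geneB1": "N0.HOG0000001"}

    def test_round_trip(self, tmp_path):
        p1 = tmp_path / "N0.tsv"
        p1.write_text(N0_TEXT)
        maps = netops.parse_hog_map(p1)
        p2 = tmp_path / "again.tsv"
        netops.write_hog_map(maps, p2)
        assert netops.parse_hog_map(p2) == maps

    def test_duplicate_gene_rejected(self, tmp_path):
        bad = (
            "HOG\tOG\tGene Tree Parent Clade\tspeciesA\n"
            "N0.HOG0000001\tOG01\tn0\tgeneA1\n"
            "N0.HOG0000002\tOG02\tn0\tgeneA1\n"
        )
        path = tmp_path / "bad.tsv"
        path.write_text(bad)
        with pytest.raises(ValueError, match="geneA1"):
            netops.parse_hog_map(path)


class TestProjection:
    def test_many_to_one_collapse(self):
        net = toy_net([("a1", "b1"), ("a2", "b1")], species="sp", condition="heat")
        hog = netops.project_to_hogs(net, {"a1": "H1", "a2": "H1", "b1": "H2"})
        assert set(hog.edges) == {("H1", "H2")}
        assert hog.edges[("H1", "H2")] == {("sp", "heat")}

    def test_self_hog_and_unmapped_dropped(self):
        net = toy_net([("a1", "a2"), ("a1", "x")], species="sp", condition="c")
        hog = netops.project_to_hogs(net, {"a1": "H1", "a2": "H1"})
        assert hog.edges == {}
        assert hog.dropped_self_hog == 1
        assert hog.dropped_unmapped == 1

    def test_intersection_subset_of_inputs(self):
        h1, h2 = HogNetwork(), HogNetwork()
        h1.add("H1", "H2", {("s1", "c")})
        h1.add("H2", "H3", {("s1", "c")})
        h2.add("H1", "H2", {("s2", "c")})
        inter = netops.intersect_across_species([h1, h2])
        assert set(inter.edges) == {("H1", "H2")}
        assert inter.edges[("H1", "H2")] == {("s1", "c"), ("s2", "c")}
        disjoint = netops.intersect_across_species([h1, HogNetwork()])
        assert disjoint.edges == {}

    def test_identical_inputs_intersect_to_identity(self):
        h = HogNetwork()
        h.add("H1", "H2", {("s", "c")})
        inter = netops.intersect_across_species([h, h])
        assert set(inter.edges) == set(h.edges)


class TestConservationRule:
    @pytest.mark.parametrize(
        "species,expected",
        [
            ({"O.sativa", "P.patens", "Z.circumcarinatum"}, "conserved_ancestral"),
            ({"A.thaliana", "M.polymorpha"}, "land_plant"),
            ({"M.endlicherianum", "Z.circumcarinatum"}, "other"),
            ({"C.reinhardtii"}, "other"),
        ],
    )
    def test_rule_examples(self, species, expected):
        prov = {(sp, "heat") for sp in species}
        label = netops.classify_conservation(prov, synth.DEFAULT_CLADE_MAP)
        assert label.value == expected

    def test_exhaustive_against_oracle_over_all_species_subsets(self):
        species = sorted(synth.DEFAULT_CLADE_MAP)
        assert len(species) == 9
        count = 0
        for r in range(1, 10):
            for subset in itertools.combinations(species, r):
                prov = {(sp, "c") for sp in subset}
                mine = netops.classify_conservation(prov, synth.DEFAULT_CLADE_MAP)
                ref = conservation_oracle(set(subset), synth.DEFAULT_CLADE_MAP)
                assert mine.value == ref
                count += 1
        assert count == 511

    def test_unmapped_species_rejected(self):
        with pytest.raises(ValueError):
            netops.classify_conservation({("mystery", "c")}, synth.DEFAULT_CLADE_MAP)


class TestCladeTallies:
    def test_toy_panel_counts(self):
        clade_map = {"t1": "T", "b1": "B"}
        h = HogNetwork()
        h.add("H1", "H2", {("t1", "c"), ("b1", "c")})
        h.add("H3", "H4", {("t1", "c"), ("b1", "c")})
        h.add("H5", "H6", {("t1", "c"), ("b1", "c")})
        h.add("H7", "H8", {("t1", "c")})
        h.add("H1", "H9", {("t1", "c")})
        df = netops.clade_sharing_tallies(h, clade_map)
        shared = df[(df["kind"] == "shared")]["edges"].iloc[0]
        excl_t = df[(df["kind"] == "exclusive") & (df["clade_a"] == "T")]["edges"].iloc[0]
        excl_b = df[(df["kind"] == "exclusive") & (df["clade_a"] == "B")]["edges"].iloc[0]
        assert (shared, excl_t, excl_b) == (3, 2, 0)

    def test_partition_identity_on_random_panels(self):
        rng = np.random.default_rng(13)
        clade_map = {f"sp{i}": c for i, c in enumerate("TTBBZ")}
        h = HogNetwork()
        n_edges = 50
        for e in range(n_edges):
            size = int(rng.integers(1, 5))
            sps = rng.choice(sorted(clade_map), size=size, replace=False)
            h.add(f"H{e}", f"H{e + 100}", {(sp, "c") for sp in sps})
        df = netops.clade_sharing_tallies(h, clade_map)
        exclusive_total = df[df["kind"] == "exclusive"]["edges"].sum()
        multi = sum(
            1 for prov in h.edges.values()
            if len({clade_map[sp] for sp, _ in prov}) > 1
        )
        assert exclusive_total + multi == n_edges
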