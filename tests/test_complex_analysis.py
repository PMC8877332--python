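import itertools

import networkx as nx
import pytest

from conftest import make_gi
from fnmotifs.complex_analysis import (
    COMPLEX, bridging_fnms, build_complex_network, consensus_gi,
    merge_complexes, restricted_betweenness,
)
from fnmotifs.fnm_filter import find_fnms
from fnmotifs.graphlets import enumerate_all
from fnmotifs.network_io import ComplexMap, POSITIVE, NEGATIVE


def record(nodes, gi_edges=(), ppi=None):
    """Build an FNMRecord via the real filter on a tiny network."""
    net = ppi or nx.complete_graph(sorted(nodes))
    gi = make_gi(gi_edges) if gi_edges else nx.Graph()
    occs = enumerate_all(net, len(nodes))
    table = find_fnms(occs, gi, threshold=0.0, require_span=False)
    for r in table.records:
        if r.occurrence.node_set == frozenset(nodes):
            return r
    raise AssertionError("record not found")


class TestBuildComplexNetwork:
    def test_ppi_edge_to_auxiliary(self):
        cmap = ComplexMap({"C1": frozenset({"A", "X"})})
        rec = record({"A", "B", "C"})
        cnet = build_complex_network([rec], cmap, nx.Graph([("A", "B")]))
        assert cnet.has_edge("C1", "B")
        assert cnet["C1"]["B"]["n_ppi"] == 1
        assert cnet.nodes["B"]["type"] == "auxiliary"

    def test_repeated_gi_edges_accumulate(self):
        cmap = ComplexMap({"C1": frozenset({"A"}), "C2": frozenset({"C"})})
        gi_edges = [("A", "C", NEGATIVE)]
        r1 = record({"A", "B", "C"}, gi_edges)
        r2 = record({"A", "C", "D"}, gi_edges)
        cnet = build_complex_network([r1, r2], cmap, nx.Graph())
        assert cnet["C1"]["C2"]["n_gi_neg"] == 2

    def test_multi_complex_gene_dropped(self):
        cmap = ComplexMap({"C1": frozenset({"A", "B"}), "C2": frozenset({"A"})})
        rec = record({"A", "X", "Y"})
        cnet = build_complex_network([rec], cmap, nx.complete_graph(["A", "X", "Y"]))
        assert "A" not in cnet and "C2" not in cnet

    def test_edge_multiplicity_conserved(self, std_bundle, enum_net):
        table = find_fnms(enumerate_all(enum_net, 4), std_bundle.gi)
        recs = [v[0] for v in table.by_node_set.values()]
        cmap = std_bundle.complexes
        g2c, multi = cmap.gene_to_complex, cmap.multi_complex
        cnet = build_complex_network(recs, cmap, enum_net)
        total = sum(d["n_ppi"] + d["n_gi_pos"] + d["n_gi_neg"]
                    for _, _, d in cnet.edges(data=True))
        expected = 0
        for r in recs:
            for u, v in itertools.combinations(sorted(r.occurrence.node_set), 2):
                mu = g2c.get(u, u) if u not in multi else None
                mv = g2c.get(v, v) if v not in multi else None
                if mu is None or mv is None or mu == mv:
                    continue
                if enum_net.has_edge(u, v):
                    expected += 1
            for pair, _ in r.gi_edges:
                u, v = sorted(pair)
                mu = g2c.get(u, u) if u not in multi else None
                mv = g2c.get(v, v) if v not in multi else None
                if mu is not None and mv is not None and mu != mv:
                    expected += 1
        assert total == expected


class TestConsensusGI:
    def test_score_formula(self):
        cnet = nx.Graph()
        cnet.add_node("C1", type=COMPLEX)
        cnet.add_node("C2", type=COMPLEX)
        cnet.add_edge("C1", "C2", n_ppi=0, n_gi_pos=3, n_gi_neg=1)
        scores, _ = consensus_gi(cnet)
        assert scores[0].score == pytest.approx(0.5)

    def test_all_negative_is_minus_one_and_antisymmetry(self):
        cnet = nx.Graph()
        for n in ("C1", "C2", "C3"):
            cnet.add_node(n, type=COMPLEX)
        cnet.add_edge("C1", "C2", n_ppi=0, n_gi_pos=0, n_gi_neg=4)
        cnet.add_edge("C1", "C3", n_ppi=0, n_gi_pos=4, n_gi_neg=0)
        scores, _ = consensus_gi(cnet)
        by_pair = {(s.complex_a, s.complex_b): s.score for s in scores}
        assert by_pair[("C1", "C2")] == -1.0
        assert by_pair[("C1", "C3")] == 1.0

    def test_overlap_partition(self):
        cnet = nx.Graph()
        for n in ("C1", "C2", "C3"):
            cnet.add_node(n, type=COMPLEX)
        cnet.add_edge("C1", "C2", n_ppi=1, n_gi_pos=0, n_gi_neg=0)
        cnet.add_edge("C1", "C3", n_ppi=0, n_gi_pos=1, n_gi_neg=0)
        cnet.add_edge("C2", "C3", n_ppi=1, n_gi_pos=0, n_gi_neg=1)
        _, fr = consensus_gi(cnet)
        assert fr == {"ppi_and_gi": pytest.approx(1 / 3),
                      "ppi_only": pytest.approx(1 / 3),
                      "gi_only": pytest.approx(1 / 3)}


def oracle_betweenness(net, endpoints):
    """Exhaustive shortest-path enumeration."""
    bc = {v: 0.0 for v in net if v not in endpoints}
    ends = sorted(endpoints)
    for i, s in enumerate(ends):
        for t in ends[i + 1:]:
            if not nx.has_path(net, s, t):
                continue
            paths = list(nx.all_shortest_paths(net, s, t))
            for v in bc:
                through = sum(1 for p in paths if v in p[1:-1])
                bc[v] += through / len(paths)
    return bc


class TestRestrictedBetweenness:
    def test_single_bridge(self):
        net = nx.Graph([("C1", "x"), ("x", "C2")])
        assert restricted_betweenness(net, {"C1", "C2"})["x"] == pytest.approx(1.0)

    def test_star_three_endpoints(self):
        net = nx.Graph([("C1", "x"), ("C2", "x"), ("C3", "x")])
        assert restricted_betweenness(net, {"C1", "C2", "C3"})["x"] == pytest.approx(3.0)

    def test_parallel_paths_split(self):
        net = nx.Graph([("C1", "x"), ("x", "C2"), ("C1", "y"), ("y", "C2")])
        bc = restricted_betweenness(net, {"C1", "C2"})
        assert bc["x"] == pytest.approx(0.5) and bc["y"] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_oracle_on_random_graphs(self, seed):
        rng = nx.utils.create_random_state(seed)
        net = nx.gnp_random_graph(12, 0.25, seed=seed)
        net = nx.relabel_nodes(net, {i: f"N{i:02d}" for i in net})
        nodes = sorted(net.nodes())
        endpoints = set(rng.choice(nodes, size=4, replace=False))
        got = restricted_betweenness(net, endpoints)
        want = oracle_betweenness(net, endpoints)
        for v in want:
            assert got[v] == pytest.approx(want[v], abs=1e-12)

    def test_designed_bottleneck_ranks_first(self):
        net = nx.Graph()
        for c in ("C1", "C2", "C3", "C4"):
            net.add_edge(c, "hub")
            net.add_edge(c, f"leaf_{c}")
        bc = restricted_betweenness(net, {"C1", "C2", "C3", "C4"})
        assert max(bc, key=bc.get) == "hub"


class TestBridging:
    def test_selection_and_grouping(self):
        a = record({"TF1", "E1", "X"})
        b = record({"TF2", "E2", "X"})
        c = record({"TF3", "Y", "Z"})
        groups = bridging_fnms([a, b, c], frozenset({"TF1", "TF2", "TF3"}),
                               frozenset({"E1", "E2"}))
        assert len(groups) == 1 and len(groups[0]) == 2

    def test_one_side_only_not_selected(self):
        a = record({"TF1", "TF2", "X"})
        groups = bridging_fnms([a], frozenset({"TF1", "TF2"}), frozenset({"E1"}))
        assert groups == []


class TestMergeComplexes:
    def test_gene_network_merging(self):
        net = nx.Graph([("A", "B"), ("B", "C"), ("A", "C")])
        cmap = ComplexMap({"C1": frozenset({"A", "B"})})
        cnet = merge_complexes(net, cmap)
        assert set(cnet.nodes()) == {"C1", "C"}
        assert cnet["C1"]["C"]["n_ppi"] == 2  # A-C and B-C both map here
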