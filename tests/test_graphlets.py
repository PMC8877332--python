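import itertools

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from fnmotifs.graphlets import (
    brute_force_census, canonical_topology, compositions, decode_graph6,
    encode_graph6, enumerate_all, enumerate_from_source, occurrences_from_tsv,
    occurrences_to_tsv,
)


def occ_key(table):
    return {(o.source, o.layers) for o in table.occurrences}


class TestCompositions:
    @pytest.mark.parametrize("k,expected", [
        (3, [(1, 1, 1), (1, 2)]),
        (4, [(1, 1, 1, 1), (1, 1, 2), (1, 2, 1), (1, 3)]),
    ])
    def test_small_k(self, k, expected):
        assert compositions(k) == expected

    @pytest.mark.parametrize("k", [3, 4, 5, 6])
    def test_count_and_shape(self, k):
        comps = compositions(k)
        assert len(comps) == 2 ** (k - 2)
        assert len(set(comps)) == len(comps)
        for c in comps:
            assert c[0] == 1 and sum(c) == k and all(p >= 1 for p in c)

    def test_k_below_2_rejected(self):
        with pytest.raises(ValueError):
            compositions(1)


class TestGraph6:
    def test_reference_encodings(self):
        assert encode_graph6(nx.complete_graph(3)) == "Bw"
        assert encode_graph6(nx.Graph([(0, 1)])) == "A_"

    def test_roundtrip_all_graphs_up_to_5(self):
        for n in range(2, 6):
            pairs = list(itertools.combinations(range(n), 2))
            for bits in range(2 ** len(pairs)):
                g = nx.empty_graph(n)
                g.add_edges_from(p for i, p in enumerate(pairs) if bits >> i & 1)
                back = decode_graph6(encode_graph6(g))
                assert set(back.edges()) == {tuple(sorted(e)) for e in g.edges()}

    def test_roundtrip_sampled_n6(self):
        for seed in range(200):
            g = nx.gnp_random_graph(6, 0.5, seed=seed)
            back = decode_graph6(encode_graph6(g))
            assert set(back.edges()) == {tuple(sorted(e)) for e in g.edges()}

    def test_matches_reference_codec(self):
        for seed in range(20):
            g = nx.gnp_random_graph(6, 0.5, seed=seed)
            ref = nx.to_graph6_bytes(g, header=False).decode().strip()
            assert encode_graph6(g) == ref

    def test_malformed_decode(self):
        with pytest.raises(ValueError):
            decode_graph6("B\x01")
        with pytest.raises(ValueError):
            decode_graph6("Bwww")


class TestCanonicalTopology:
    def test_isomorphism_invariance_p3(self):
        a = nx.Graph([("a", "b"), ("b", "c")])
        b = nx.Graph([("c", "a"), ("a", "b")])
        assert canonical_topology(a) == canonical_topology(b)

    def test_k3_any_labeling(self):
        for labels in itertools.permutations("xyz"):
            g = nx.Graph(itertools.combinations(labels, 2))
            assert canonical_topology(g) == "Bw"

    def test_all_11_classes_on_4_nodes_distinct(self):
        pairs = list(itertools.combinations(range(4), 2))
        labels = set()
        for bits in range(2 ** 6):
            g = nx.empty_graph(4)
            g.add_edges_from(p for i, p in enumerate(pairs) if bits >> i & 1)
            labels.add(canonical_topology(g))
        assert len(labels) == 11

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6), k=st.integers(3, 6))
    def test_invariant_under_relabeling(self, seed, k):
        g = nx.gnp_random_graph(k, 0.5, seed=seed)
        base = canonical_topology(g)
        for pseed in range(4):
            perm = list(range(k))
            rng = nx.utils.create_random_state(pseed)
            rng.shuffle(perm)
            h = nx.relabel_nodes(g, dict(zip(range(k), perm)))
            assert canonical_topology(h) == base


class TestEnumeration:
    def test_triangle_single_occurrence(self, triangle):
        occs = list(enumerate_from_source(triangle, "A", 3))
        assert len(occs) == 1
        assert occs[0].composition == (1, 2)
        assert occs[0].layers == (frozenset({"A"}), frozenset({"B", "C"}))

    def test_path_layering(self, path3):
        occs = list(enumerate_from_source(path3, "A", 3))
        assert len(occs) == 1
        assert occs[0].composition == (1, 1, 1)

    def test_per_source_equals_k_times_unique(self, triangle, path3):
        for g in (triangle, path3):
            t = enumerate_all(g, 3)
            assert t.n_per_source == 3 and t.n_unique == 1

    def test_square_cycle_triples(self):
        g = nx.cycle_graph(4)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g})
        t = brute_force_census(g, 3)
        assert t.n_unique == 4

    def test_k4_all_triangles(self):
        t = brute_force_census(nx.relabel_nodes(nx.complete_graph(4), str), 3)
        assert t.n_unique == 4
        assert all(o.topology == "Bw" for o in t.occurrences)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("k", [3, 4])
    def test_matches_brute_force(self, seed, k):
        g = nx.gnp_random_graph(12, 0.3, seed=seed)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g})
        fast, slow = enumerate_all(g, k), brute_force_census(g, k)
        assert occ_key(fast) == occ_key(slow)
        assert fast.n_per_source == k * fast.n_unique

    def test_layer_sizes_match_a_composition(self):
        g = nx.gnp_random_graph(15, 0.25, seed=7)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g})
        for k in (3, 4, 5):
            comps = set(compositions(k))
            t = enumerate_all(g, k)
            assert t.occurrences, "census should be nonempty on this graph"
            assert all(o.composition in comps for o in t.occurrences)

    def test_layers_are_bfs_distances(self):
        g = nx.gnp_random_graph(12, 0.35, seed=3)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g})
        for occ in enumerate_all(g, 4).occurrences:
            sub = g.subgraph(occ.node_set)
            dist = nx.single_source_shortest_path_length(sub, occ.source)
            for i, layer in enumerate(occ.layers):
                assert all(dist[v] == i for v in layer)

    def test_tsv_roundtrip(self, tmp_path):
        g = nx.gnp_random_graph(10, 0.3, seed=2)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g})
        t = enumerate_all(g, 4)
        path = tmp_path / "occ.tsv"
        occurrences_to_tsv(t, path)
        back = occurrences_from_tsv(path)[4]
        assert occ_key(back) == occ_key(t)
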