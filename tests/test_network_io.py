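import networkx as nx
import numpy as np
import pandas as pd
import pytest

from fnmotifs import network_io as nio


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadPPI:
    def test_dedup_and_self_loops(self, tmp_path):
        p = write(tmp_path, "e.tsv", "a\tb\nb\ta\na\ta\nb\tc\n")
        net = nio.read_ppi(p)
        assert set(map(frozenset, net.edges())) == {frozenset("AB"), frozenset("BC")}

    def test_biogrid_physical_filter(self, tmp_path):
        header = ("Systematic Name Interactor A\tSystematic Name Interactor B\t"
                  "Experimental System Type\n")
        p = write(tmp_path, "b.tsv", header +
                  "ya\tyb\tphysical\nyb\tyc\tphysical\nya\tyc\tgenetic\n")
        assert nio.read_ppi(p, preset="biogrid_tab", physical_only=True).number_of_edges() == 2
        assert nio.read_ppi(p, preset="biogrid_tab").number_of_edges() == 3

    def test_missing_column_names_column(self, tmp_path):
        p = write(tmp_path, "b.tsv", "foo\tbar\nx\ty\n")
        with pytest.raises(nio.FormatError, match="Systematic Name"):
            nio.read_ppi(p, preset="biogrid_tab")

    def test_roundtrip_edge_list(self, tmp_path):
        net = nx.gnp_random_graph(15, 0.3, seed=4)
        net = nx.relabel_nodes(net, {i: f"G{i}" for i in net})
        out = tmp_path / "rt.tsv"
        nio.write_edge_list(net, out)
        back = nio.read_ppi(out)
        assert set(back.nodes()) == {n for n in net if net.degree(n) > 0}
        assert set(map(frozenset, back.edges())) == set(map(frozenset, net.edges()))


class TestThresholdGI:
    def test_tails_of_1_to_100(self):
        rows = [{"gene_a": f"A{i}", "gene_b": f"B{i}", "score": float(i)}
                for i in range(1, 101)]
        gi = nio.threshold_gi(pd.DataFrame(rows), 0.05)
        signs = nx.get_edge_attributes(gi, "sign")
        neg = [gi[u][v]["score"] for (u, v), s in signs.items() if s == nio.NEGATIVE]
        pos = [gi[u][v]["score"] for (u, v), s in signs.items() if s == nio.POSITIVE]
        assert 4 <= len(neg) <= 7 and 4 <= len(pos) <= 7
        assert max(neg) < min(pos)

    def test_symmetric_thirds(self):
        rows = [{"gene_a": "a", "gene_b": "b", "score": -1.0},
                {"gene_a": "c", "gene_b": "d", "score": 0.0},
                {"gene_a": "e", "gene_b": "f", "score": 1.0}]
        gi = nio.threshold_gi(pd.DataFrame(rows), 1 / 3)
        assert gi.number_of_edges() == 2
        assert gi["A"]["B"]["sign"] == nio.NEGATIVE
        assert gi["E"]["F"]["sign"] == nio.POSITIVE

    def test_duplicate_pair_keeps_strongest(self):
        df = pd.DataFrame([
            {"gene_a": "a", "gene_b": "b", "score": -3.0},
            {"gene_a": "b", "gene_b": "a", "score": 2.0},
        ])
        cleaned = nio.clean_gi_table(df)
        assert len(cleaned) == 1
        assert cleaned["score"].iloc[0] == -3.0

    def test_degenerate_scores_error(self):
        df = pd.DataFrame([{"gene_a": "a", "gene_b": "b", "score": 1.0},
                           {"gene_a": "c", "gene_b": "d", "score": 1.0}])
        with pytest.raises(ValueError, match="identical"):
            nio.threshold_gi(df)

    def test_edge_count_bound_and_sign_function_of_score(self):
        rng = np.random.default_rng(0)
        rows = [{"gene_a": f"x{i}", "gene_b": f"y{i}", "score": float(s)}
                for i, s in enumerate(rng.normal(size=400))]
        frac = 0.1
        gi = nio.threshold_gi(pd.DataFrame(rows), frac)
        assert gi.number_of_edges() <= 2 * frac * 400 + 2
        neg_scores = [d["score"] for _, _, d in gi.edges(data=True) if d["sign"] == nio.NEGATIVE]
        pos_scores = [d["score"] for _, _, d in gi.edges(data=True) if d["sign"] == nio.POSITIVE]
        assert max(neg_scores) < min(pos_scores)


class TestFilters:
    def test_intracomplex_removal(self):
        net = nx.Graph([("A", "B"), ("A", "C")])
        cmap = nio.ComplexMap({"C1": frozenset({"A", "B"})})
        out = nio.remove_intracomplex_edges(net, cmap)
        assert set(map(frozenset, out.edges())) == {frozenset("AC")}
        assert set(out.nodes()) == {"A", "B", "C"}

    def test_no_annotation_identity(self):
        net = nx.Graph([("A", "B")])
        out = nio.remove_intracomplex_edges(net, nio.ComplexMap({}))
        assert set(out.edges()) == set(net.edges())

    def test_multi_complex_shared_membership_triggers(self):
        cmap = nio.ComplexMap({"C1": frozenset({"A", "B"}), "C2": frozenset({"B"})})
        net = nx.Graph([("A", "B")])
        assert nio.remove_intracomplex_edges(net, cmap).number_of_edges() == 0

    def test_degree_filter_strict(self):
        star = nx.star_graph(60)
        star = nx.relabel_nodes(star, {i: f"N{i}" for i in star})
        out = nio.filter_degree(star, 50)
        assert "N0" not in out and out.number_of_edges() == 0
        # degree exactly d_max is removed
        star50 = nx.relabel_nodes(nx.star_graph(50), {i: f"M{i}" for i in range(51)})
        assert "M0" not in nio.filter_degree(star50, 50)

    def test_degree_filter_single_pass(self):
        # chain of hubs: degrees computed before deletion, no cascade
        net = nx.Graph()
        for i in range(5):
            net.add_edge(f"H{i}", f"H{i+1}")
        out = nio.filter_degree(net, 2)
        assert set(out.nodes()) == {"H0", "H5"}

    def test_filtered_max_degree_below_dmax(self, std_bundle):
        out = nio.filter_degree(std_bundle.ppi, 6)
        assert all(d < 6 for _, d in out.degree())


class TestAnnotationReaders:
    def test_complexes_multi_membership(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("C1\ta\nC1\tb\nC2\tb\nC2\tc\n")
        cmap = nio.read_complexes(p)
        assert cmap.gene_to_complex == {"A": "C1", "C": "C2"}
        assert cmap.multi_complex == {"B"}

    def test_pair_file_unordered(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("a\tb\nb\ta\nc\td\n")
        assert len(nio.read_gene_pairs(p)) == 2

    def test_expression_missing_cell(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("gene\tc1\tc2\tc3\tc4\ng1\t1\t2\t3\t4\ng2\t1\t\t3\t4\ng3\t0\t0\t0\t0\n")
        m = nio.read_expression(p)
        assert m.shape == (3, 4)
        assert m.isna().sum().sum() == 1

    def test_graphml_roundtrip(self, tmp_path, std_bundle):
        out = tmp_path / "n.graphml"
        nio.write_graphml(std_bundle.ppi, out)
        back = nx.read_graphml(out)
        assert set(back.nodes()) == set(std_bundle.ppi.nodes())
        assert set(map(frozenset, back.edges())) == set(map(frozenset, std_bundle.ppi.edges()))
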