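"""Complex-level analyses of FNMs.

Protein complexes act as functional units, so the gene-level edges captured
inside FNMs are merged onto joint complex nodes: single-complex genes map to
their complex, genes in no complex stay as auxiliary nodes, and genes in
several complexes are dropped.  Edges accumulate PPI / positive-GI /
negative-GI counts; repeated occurrences of the same gene-level edge in
different FNMs each count.  On the merged map we score consensus GI signs
between complex pairs, compute betweenness of auxiliary nodes restricted to
shortest paths between complexes, and extract FNMs that bridge two gene
systems (e.g. transcription factors and metabolic enzymes).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from fnmotifs.fnm_filter import FNMRecord
from fnmotifs.network_io import ComplexMap, POSITIVE
from fnmotifs.stats_enrichment import mann_whitney_u

__all__ = [
    "build_complex_network", "consensus_gi", "restricted_betweenness",
    "rank_auxiliary", "bridging_fnms", "merge_complexes",
]

COMPLEX = "complex"
AUXILIARY = "auxiliary"


def _map_gene(g: str, g2c: dict[str, str], multi: frozenset[str]):
    if g in multi:
        return None, None
    if g in g2c:
        return g2c[g], COMPLEX
    return g, AUXILIARY


def build_complex_network(fnms: list[FNMRecord], cmap: ComplexMap,
                          ppi: nx.Graph) -> nx.Graph:
    """Merge the PPI and GI edges inside FNMs onto complex-level nodes.

    ``fnms`` should be the deduplicated node-set view (one record per FNM).
    Node attribute ``type`` is "complex" or "auxiliary"; complex nodes carry
    their member gene set.  Edge attributes ``n_ppi``, ``n_gi_pos``,
    ``n_gi_neg`` accumulate over all FNMs; self-edges (both endpoints in the
    same complex) are skipped.
    """
    g2c = cmap.gene_to_complex
    multi = cmap.multi_complex
    cnet = nx.Graph()

    def add(u: str, v: str, kind: str) -> None:
        mu, tu = _map_gene(u, g2c, multi)
        mv, tv = _map_gene(v, g2c, multi)
        if mu is None or mv is None or mu == mv:
            return
        for node, t in ((mu, tu), (mv, tv)):
            if node not in cnet:
                cnet.add_node(node, type=t)
                if t == COMPLEX:
                    cnet.nodes[node]["genes"] = set(cmap.members[node])
        if not cnet.has_edge(mu, mv):
            cnet.add_edge(mu, mv, n_ppi=0, n_gi_pos=0, n_gi_neg=0)
        cnet[mu][mv][kind] += 1

    for rec in fnms:
        nodes = sorted(rec.occurrence.node_set)
        for i, u in enumerate(nodes):
            for v in nodes[i + 1:]:
                if ppi.has_edge(u, v):
                    add(u, v, "n_ppi")
        for pair, sign in rec.gi_edges:
            u, v = sorted(pair)
            add(u, v, "n_gi_pos" if sign == POSITIVE else "n_gi_neg")
    return cnet


def merge_complexes(net: nx.Graph, cmap: ComplexMap) -> nx.Graph:
    """Merge a plain gene-level network onto complex nodes (comparison maps).

    Same mapping rules as :func:`build_complex_network`, applied to every
    edge of ``net`` with unit PPI counts; used to build the filtered-PPI and
    full-PPI comparison networks for the betweenness analysis.
    """
    g2c = cmap.gene_to_complex
    multi = cmap.multi_complex
    cnet = nx.Graph()
    for u, v in net.edges():
        mu, tu = _map_gene(u, g2c, multi)
        mv, tv = _map_gene(v, g2c, multi)
        if mu is None or mv is None or mu == mv:
            continue
        for node, t in ((mu, tu), (mv, tv)):
            if node not in cnet:
                cnet.add_node(node, type=t)
        if not cnet.has_edge(mu, mv):
            cnet.add_edge(mu, mv, n_ppi=0, n_gi_pos=0, n_gi_neg=0)
        cnet[mu][mv]["n_ppi"] += 1
    return cnet


@dataclass(frozen=True)
class ConsensusGIScore:
    """Signed coherence of the GI edges aggregated between two complexes."""

    complex_a: str
    complex_b: str
    n_pos: int
    n_neg: int

    @property
    def score(self) -> float:
        return (self.n_pos - self.n_neg) / (self.n_pos + self.n_neg)


def consensus_gi(cnet: nx.Graph):
    """Per complex-pair consensus GI scores and the PPI/GI overlap partition.

    The score (n_pos - n_neg) / (n_pos + n_neg) is +1/-1 when all GIs
    between a complex pair share one sign.  The overlap partition classifies
    complex-pair edges into both-PPI-and-GI, PPI-only and GI-only fractions.
    """
    scores: list[ConsensusGIScore] = []
    both = ppi_only = gi_only = 0
    for u, v, d in cnet.edges(data=True):
        if cnet.nodes[u]["type"] != COMPLEX or cnet.nodes[v]["type"] != COMPLEX:
            continue
        a, b = sorted((u, v))
        has_gi = d["n_gi_pos"] + d["n_gi_neg"] > 0
        has_ppi = d["n_ppi"] > 0
        if has_gi:
            scores.append(ConsensusGIScore(a, b, d["n_gi_pos"], d["n_gi_neg"]))
        if has_ppi and has_gi:
            both += 1
        elif has_ppi:
            ppi_only += 1
        elif has_gi:
            gi_only += 1
    total = both + ppi_only + gi_only
    fractions = {
        "ppi_and_gi": both / total if total else 0.0,
        "ppi_only": ppi_only / total if total else 0.0,
        "gi_only": gi_only / total if total else 0.0,
    }
    scores.sort(key=lambda s: (s.complex_a, s.complex_b))
    return scores, fractions


def restricted_betweenness(net: nx.Graph, endpoints: set) -> dict:
    """Betweenness of non-endpoint nodes over complex-pair shortest paths.

    B(v) = sum over unordered endpoint pairs (s, t) of sigma_st(v)/sigma_st,
    with sigma_st the number of shortest s-t paths and sigma_st(v) those
    through v.  Unweighted, unnormalized; disconnected pairs contribute 0.
    """
    missing = [s for s in endpoints if s not in net]
    if missing:
        raise ValueError(f"endpoints not in network: {missing[:3]}")
    ends = sorted(endpoints)
    others = [v for v in net.nodes() if v not in endpoints]
    bc = {v: 0.0 for v in others}
    # per-source BFS: distances and shortest-path counts
    info = {}
    for s in ends:
        dist = {s: 0}
        sigma = {s: 1.0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for w in net[u]:
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        sigma[w] = 0.0
                        nxt.append(w)
                    if dist[w] == dist[u] + 1:
                        sigma[w] += sigma[u]
            frontier = nxt
        info[s] = (dist, sigma)
    for i, s in enumerate(ends):
        ds, ss = info[s]
        for t in ends[i + 1:]:
            if t not in ds or ss[t] == 0:
                continue
            dt, st = info[t]
            d = ds[t]
            for v in others:
                if v in ds and v in dt and ds[v] + dt[v] == d:
                    bc[v] += ss[v] * st[v] / ss[t]
    return bc


def rank_auxiliary(networks: dict[str, nx.Graph]) -> pd.DataFrame:
    """Rank auxiliary nodes by restricted betweenness across networks.

    ``networks`` maps a name (e.g. "fnm", "ppi_dmax", "ppi_all") to a
    complex-merged graph with node ``type`` attributes.  Returns a tidy
    table (network, node, betweenness, rank) plus, in ``.attrs``, per-network
    total/effective auxiliary counts and pairwise rank-comparison
    Wilcoxon-Mann-Whitney p-values.
    """
    rows = []
    sizes = {}
    dists = {}
    for name, net in networks.items():
        endpoints = {n for n, d in net.nodes(data=True) if d.get("type") == COMPLEX}
        bc = restricted_betweenness(net, endpoints)
        aux = sorted(bc, key=lambda v: (-bc[v], v))
        for rank, v in enumerate(aux, 1):
            rows.append({"network": name, "node": v,
                         "betweenness": bc[v], "rank": rank})
        sizes[name] = {
            "n_auxiliary": len(bc),
            "n_effective": sum(1 for b in bc.values() if b > 0),
            "n_complexes": len(endpoints),
        }
        dists[name] = list(bc.values())
    df = pd.DataFrame(rows)
    pvals = {}
    names = sorted(networks)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if dists[a] and dists[b]:
                _, p = mann_whitney_u(dists[a], dists[b])
                pvals[(a, b)] = p
    df.attrs["sizes"] = sizes
    df.attrs["wmw_pvalues"] = pvals
    return df


def bridging_fnms(fnms: list[FNMRecord], set_a: frozenset[str],
                  set_b: frozenset[str]) -> list[list[FNMRecord]]:
    """Groups of interlinked FNMs connecting gene system A to gene system B.

    Selects FNMs containing at least one gene of each set, then groups the
    selected FNMs into connected components by shared genes.  Groups are
    returned largest first (ties by smallest member index).
    """
    selected = [
        (i, r) for i, r in enumerate(fnms)
        if r.occurrence.node_set & set_a and r.occurrence.node_set & set_b
    ]
    g = nx.Graph()
    g.add_nodes_from(i for i, _ in selected)
    for ai in range(len(selected)):
        i, ri = selected[ai]
        for bi in range(ai + 1, len(selected)):
            j, rj = selected[bi]
            if ri.occurrence.node_set & rj.occurrence.node_set:
                g.add_edge(i, j)
    by_index = dict(selected)
    comps = sorted((sorted(c) for c in nx.connected_components(g)),
                   key=lambda c: (-len(c), c[0] if c else 0))
    return [[by_index[i] for i in comp] for comp in comps]
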