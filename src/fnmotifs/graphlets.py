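"""Exhaustive layered graphlet enumeration and graph6 topology labels.

Every connected induced k-node subgraph containing a chosen source node has
a unique breadth-first layering: layer i holds the nodes at distance i from
the source *within the induced subgraph*.  The layer sizes form an integer
composition (1, c_1, ..., c_L) of k, so the census can be organized as one
depth-first search per composition: layer i+1 is drawn from neighbors of
layer i that touch no earlier layer.  Each subgraph is therefore emitted
exactly once per source, and k times in total across sources.

Topologies are pooled by a canonical graph6 label computed by exhaustive
search over vertex orderings, which is exact and cheap for k <= 6.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator

import networkx as nx

__all__ = [
    "compositions", "enumerate_from_source", "enumerate_all",
    "encode_graph6", "decode_graph6", "canonical_topology",
    "brute_force_census", "GraphletOccurrence", "OccurrenceTable",
]


def compositions(k: int) -> list[tuple[int, ...]]:
    """All layer-size classes for motif size ``k``.

    These are the tuples ``(1, c_1, ..., c_L)`` where ``(c_1, ...)`` runs over
    the ``2**(k-2)`` integer compositions of ``k - 1``, in lexicographic order.
    """
    if k < 2:
        raise ValueError("motif size k must be >= 2")

    def _comps(n: int) -> Iterator[tuple[int, ...]]:
        if n == 0:
            yield ()
            return
        for first in range(1, n + 1):
            for rest in _comps(n - first):
                yield (first, *rest)

    return sorted((1, *c) for c in _comps(k - 1))


@dataclass(frozen=True)
class GraphletOccurrence:
    """One layered occurrence of a connected induced k-subgraph.

    ``layers[0]`` is the singleton source layer; ``layers[i]`` the nodes at
    induced-subgraph distance i from the source.  ``topology`` is the
    canonical graph6 label of the induced PPI subgraph.
    """

    source: str
    layers: tuple[frozenset[str], ...]
    topology: str

    @property
    def node_set(self) -> frozenset[str]:
        return frozenset().union(*self.layers)

    @property
    def k(self) -> int:
        return sum(len(l) for l in self.layers)

    @property
    def composition(self) -> tuple[int, ...]:
        return tuple(len(l) for l in self.layers)

    @property
    def last_layer(self) -> frozenset[str]:
        return self.layers[-1]


@dataclass
class OccurrenceTable:
    """Per-source occurrences plus the deduplicated node-set view.

    ``occurrences`` lists every (source, layering) pair; ``by_node_set`` maps
    each unique connected induced k-subgraph to its k per-source occurrences.
    """

    k: int
    occurrences: list[GraphletOccurrence] = field(default_factory=list)

    @property
    def by_node_set(self) -> dict[frozenset[str], list[GraphletOccurrence]]:
        out: dict[frozenset[str], list[GraphletOccurrence]] = {}
        for occ in self.occurrences:
            out.setdefault(occ.node_set, []).append(occ)
        return out

    @property
    def n_per_source(self) -> int:
        return len(self.occurrences)

    @property
    def n_unique(self) -> int:
        return len({occ.node_set for occ in self.occurrences})

    def topology_counts(self, deduplicated: bool = False) -> dict[str, int]:
        counts: dict[str, int] = {}
        if deduplicated:
            seen: set[frozenset[str]] = set()
            for occ in self.occurrences:
                if occ.node_set not in seen:
                    seen.add(occ.node_set)
                    counts[occ.topology] = counts.get(occ.topology, 0) + 1
        else:
            for occ in self.occurrences:
                counts[occ.topology] = counts.get(occ.topology, 0) + 1
        return counts


# ---------------------------------------------------------------- graph6

def encode_graph6(graph: nx.Graph) -> str:
    """Encode a simple undirected graph (<= 62 nodes) in graph6.

    Size byte ``n + 63``, then the upper-triangle adjacency bits in
    column-major order packed into 6-bit chunks, each offset by 63.
    """
    nodes = sorted(graph.nodes())
    n = len(nodes)
    if n > 62:
        raise ValueError("single-byte graph6 supports at most 62 nodes")
    index = {v: i for i, v in enumerate(nodes)}
    bits = [0] * (n * (n - 1) // 2)
    pos = 0
    for j in range(1, n):
        for i in range(j):
            bits[pos] = 1 if graph.has_edge(nodes[i], nodes[j]) else 0
            pos += 1
    out = [chr(n + 63)]
    for start in range(0, len(bits), 6):
        chunk = bits[start:start + 6]
        chunk += [0] * (6 - len(chunk))
        val = 0
        for b in chunk:
            val = (val << 1) | b
        out.append(chr(val + 63))
    return "".join(out)


def decode_graph6(text: str) -> nx.Graph:
    """Decode a single-byte-header graph6 string to a graph on nodes 0..n-1."""
    if not text or any(ord(c) < 63 or ord(c) > 126 for c in text):
        raise ValueError(f"malformed graph6 string: {text!r}")
    n = ord(text[0]) - 63
    need = (n * (n - 1) // 2 + 5) // 6
    body = text[1:]
    if len(body) != need:
        raise ValueError(f"graph6 string has wrong length for n={n}")
    bits: list[int] = []
    for c in body:
        val = ord(c) - 63
        bits.extend((val >> shift) & 1 for shift in range(5, -1, -1))
    g = nx.empty_graph(n)
    pos = 0
    for j in range(1, n):
        for i in range(j):
            if bits[pos]:
                g.add_edge(i, j)
            pos += 1
    return g


def _bit_key(adj: list[list[bool]], perm: tuple[int, ...], n: int) -> tuple[int, ...]:
    return tuple(
        1 if adj[perm[i]][perm[j]] else 0
        for j in range(1, n) for i in range(j)
    )


def canonical_topology(graph: nx.Graph, k: int | None = None) -> str:
    """Canonical graph6 label: lexicographically maximal upper-triangle bits.

    Exhaustive over all k! vertex orderings -- exact and fast for k <= 6.
    Isomorphic graphs map to identical strings.
    """
    nodes = sorted(graph.nodes())
    n = len(nodes)
    if k is not None and n != k:
        raise ValueError("graph order does not match k")
    adj = [[False] * n for _ in range(n)]
    for u, v in graph.edges():
        i, j = nodes.index(u), nodes.index(v)
        adj[i][j] = adj[j][i] = True
    best = max(_bit_key(adj, perm, n) for perm in itertools.permutations(range(n)))
    g = nx.empty_graph(n)
    pos = 0
    for j in range(1, n):
        for i in range(j):
            if best[pos]:
                g.add_edge(i, j)
            pos += 1
    return encode_graph6(g)


# topology labels recur constantly during a census; memoize on the induced
# edge bitmask under the sorted node order
_CANON_CACHE: dict[tuple[int, int], str] = {}


def _canonical_from_nodes(nodes: tuple[str, ...], adj: dict[str, set[str]]) -> str:
    n = len(nodes)
    mask = 0
    pos = 0
    for j in range(1, n):
        nj = nodes[j]
        for i in range(j):
            if nodes[i] in adj[nj]:
                mask |= 1 << pos
            pos += 1
    key = (n, mask)
    cached = _CANON_CACHE.get(key)
    if cached is not None:
        return cached
    g = nx.empty_graph(n)
    pos = 0
    for j in range(1, n):
        for i in range(j):
            if mask >> pos & 1:
                g.add_edge(i, j)
            pos += 1
    label = canonical_topology(g)
    _CANON_CACHE[key] = label
    return label


# ---------------------------------------------------------------- census

def enumerate_from_source(net: nx.Graph, source: str, k: int) -> Iterator[GraphletOccurrence]:
    """Yield every connected induced k-subgraph containing ``source`` once.

    Layer i+1 candidates are neighbors of the chosen layer-i nodes excluding
    all previously layered nodes and any neighbor of layers <= i-1, which
    makes the emitted layering the BFS-distance layering of the subgraph.
    Candidate subsets are taken in sorted order for deterministic output.
    """
    if source not in net:
        raise KeyError(f"source node {source!r} not in network")
    adj = {n: set(net[n]) for n in net}
    yield from _enumerate(adj, source, k)


def _enumerate(adj: dict[str, set[str]], source: str, k: int) -> Iterator[GraphletOccurrence]:
    stack_layers: list[frozenset[str]] = [frozenset((source,))]

    def rec(remaining: int, chosen: set[str], frontier: frozenset[str],
            banned: set[str]) -> Iterator[GraphletOccurrence]:
        # banned = chosen nodes + neighbors of layers before the frontier
        if remaining == 0:
            nodes = tuple(sorted(chosen))
            yield GraphletOccurrence(
                source=source,
                layers=tuple(stack_layers),
                topology=_canonical_from_nodes(nodes, adj),
            )
            return
        cand = sorted(set().union(*(adj[u] for u in frontier)) - banned)
        if not cand:
            return
        next_banned = banned | set(cand)
        for size in range(1, min(remaining, len(cand)) + 1):
            for combo in itertools.combinations(cand, size):
                layer = frozenset(combo)
                stack_layers.append(layer)
                yield from rec(remaining - size, chosen | layer, layer, next_banned)
                stack_layers.pop()

    yield from rec(k - 1, {source}, frozenset((source,)), {source})


def enumerate_all(net: nx.Graph, k: int) -> OccurrenceTable:
    """Census over every node as source.

    The per-source occurrence count equals k times the number of unique
    connected induced k-subgraphs, since every subgraph is found once from
    each of its k members.
    """
    adj = {n: set(net[n]) for n in net}
    table = OccurrenceTable(k=k)
    for source in sorted(net.nodes()):
        table.occurrences.extend(_enumerate(adj, source, k))
    return table


def brute_force_census(net: nx.Graph, k: int) -> OccurrenceTable:
    """Oracle census: try all node subsets of size k, keep connected ones.

    Layerings are computed independently by BFS from each member.  Only
    tractable on small graphs; used to validate the layered enumeration.
    """
    table = OccurrenceTable(k=k)
    nodes = sorted(net.nodes())
    adj = {n: set(net[n]) for n in net}
    for subset in itertools.combinations(nodes, k):
        sub = set(subset)
        induced = {u: adj[u] & sub for u in subset}
        # connectivity by BFS from the first member
        seen = {subset[0]}
        queue = [subset[0]]
        while queue:
            u = queue.pop()
            for w in induced[u]:
                if w not in seen:
                    seen.add(w)
                    queue.append(w)
        if len(seen) != k:
            continue
        label = _canonical_from_nodes(subset, adj)
        for source in subset:
            dist = {source: 0}
            frontier = [source]
            layers: list[frozenset[str]] = [frozenset((source,))]
            while frontier:
                nxt = frozenset(w for u in frontier for w in induced[u] if w not in dist)
                for w in nxt:
                    dist[w] = len(layers)
                if nxt:
                    layers.append(nxt)
                frontier = list(nxt)
            table.occurrences.append(
                GraphletOccurrence(source=source, layers=tuple(layers), topology=label)
            )
    return table


# ---------------------------------------------------------------- serialization

def occurrences_from_tsv(path) -> dict[int, OccurrenceTable]:
    """Read back per-source occurrence tables, keyed by motif size."""
    tables: dict[int, OccurrenceTable] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            source, k_s, _comp, assign, _nodes, label = line.rstrip("\n").split("\t")
            k = int(k_s)
            layer_map: dict[int, set[str]] = {}
            for item in assign.split(";"):
                g, i = item.rsplit(":", 1)
                layer_map.setdefault(int(i), set()).add(g)
            layers = tuple(frozenset(layer_map[i]) for i in sorted(layer_map))
            tables.setdefault(k, OccurrenceTable(k=k)).occurrences.append(
                GraphletOccurrence(source=source, layers=layers, topology=label)
            )
    return tables


def occurrences_to_tsv(table: OccurrenceTable, path) -> None:
    """Write the per-source occurrence table with layer assignments."""
    with open(path, "w") as fh:
        fh.write("source\tk\tcomposition\tlayers\tnode_set\tgraph6\n")
        for occ in table.occurrences:
            comp = ",".join(str(c) for c in occ.composition)
            assign = ";".join(
                f"{g}:{i}" for i, layer in enumerate(occ.layers) for g in sorted(layer)
            )
            nodes = ",".join(sorted(occ.node_set))
            fh.write(f"{occ.source}\t{occ.k}\t{comp}\t{assign}\t{nodes}\t{occ.topology}\n")
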