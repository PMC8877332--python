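"""Filter graphlet occurrences into functional network motifs (FNMs).

A PPI graphlet occurrence qualifies as an FNM when genetic interactions
cover at least half of all C(k,2) node pairs ("at least 50%" is read as the
integer ceiling, so k=3 needs 2/3 pairs and k=6 needs 8/15), and the source
node genetically interacts with every node of its most distant layer --
GIs that span the full graphlet.  GI sign plays no role in the decision and
is carried along as annotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx

from fnmotifs.graphlets import GraphletOccurrence, OccurrenceTable
from fnmotifs.network_io import POSITIVE

__all__ = ["FNMRecord", "FNMTable", "count_gi_edges", "is_fnm", "find_fnms"]


@dataclass(frozen=True)
class FNMRecord:
    """A graphlet occurrence annotated with its GI content and FNM status."""

    occurrence: GraphletOccurrence
    gi_edges: frozenset[tuple[frozenset[str], str]]  # (pair, sign)
    pos_count: int
    neg_count: int
    source_distant_ok: bool
    is_fnm: bool

    @property
    def gi_count(self) -> int:
        return self.pos_count + self.neg_count

    @property
    def gi_possible(self) -> int:
        k = self.occurrence.k
        return k * (k - 1) // 2

    @property
    def gi_fraction(self) -> float:
        return self.gi_count / self.gi_possible


def count_gi_edges(occurrence: GraphletOccurrence, gi: nx.Graph):
    """GI edges among all unordered node pairs of the occurrence, with signs."""
    edges: set[tuple[frozenset[str], str]] = set()
    pos = neg = 0
    nodes = sorted(occurrence.node_set)
    for i, u in enumerate(nodes):
        if u not in gi:
            continue
        for v in nodes[i + 1:]:
            if gi.has_edge(u, v):
                sign = gi[u][v]["sign"]
                edges.add((frozenset((u, v)), sign))
                if sign == POSITIVE:
                    pos += 1
                else:
                    neg += 1
    return frozenset(edges), pos, neg


def is_fnm(occurrence: GraphletOccurrence, gi: nx.Graph,
           threshold: float = 0.5, require_span: bool = True) -> FNMRecord:
    """Decide FNM status of one occurrence.

    ``threshold`` is the minimum GI coverage of the C(k,2) node pairs,
    applied as ``gi_count >= ceil(threshold * C(k,2))``; ``require_span``
    additionally demands a direct source GI to every most-distant-layer node.
    """
    edges, pos, neg = count_gi_edges(occurrence, gi)
    k = occurrence.k
    needed = math.ceil(threshold * k * (k - 1) / 2)
    span_ok = all(
        gi.has_edge(occurrence.source, v) for v in occurrence.last_layer
    )
    status = (pos + neg) >= needed and (span_ok or not require_span)
    return FNMRecord(
        occurrence=occurrence,
        gi_edges=edges,
        pos_count=pos,
        neg_count=neg,
        source_distant_ok=span_ok,
        is_fnm=status,
    )


@dataclass
class FNMTable:
    """All annotated occurrences plus the FNM views.

    ``records`` covers every occurrence; ``fnms`` the qualifying ones;
    ``by_node_set`` deduplicates FNMs to node sets, keeping every qualifying
    source's record.
    """

    k: int
    records: list[FNMRecord]

    @property
    def fnms(self) -> list[FNMRecord]:
        return [r for r in self.records if r.is_fnm]

    @property
    def by_node_set(self) -> dict[frozenset[str], list[FNMRecord]]:
        out: dict[frozenset[str], list[FNMRecord]] = {}
        for r in self.fnms:
            out.setdefault(r.occurrence.node_set, []).append(r)
        return out

    def topology_counts(self, deduplicated: bool = False) -> dict[str, int]:
        counts: dict[str, int] = {}
        if deduplicated:
            for recs in self.by_node_set.values():
                t = recs[0].occurrence.topology
                counts[t] = counts.get(t, 0) + 1
        else:
            for r in self.fnms:
                t = r.occurrence.topology
                counts[t] = counts.get(t, 0) + 1
        return counts


def find_fnms(occurrences: OccurrenceTable, gi: nx.Graph,
              threshold: float = 0.5, require_span: bool = True) -> FNMTable:
    """Apply the FNM test to every occurrence of a census table."""
    records = [
        is_fnm(occ, gi, threshold=threshold, require_span=require_span)
        for occ in occurrences.occurrences
    ]
    return FNMTable(k=occurrences.k, records=records)


def fnms_to_tsv(table: FNMTable, path) -> None:
    """Write the annotated occurrence table (FNM flags and GI content)."""
    with open(path, "w") as fh:
        fh.write("source\tk\tcomposition\tnode_set\tgraph6\t"
                 "gi_count\tgi_possible\tpos\tneg\tspan\tis_fnm\tgi_edges\n")
        for r in table.records:
            occ = r.occurrence
            comp = ",".join(str(c) for c in occ.composition)
            nodes = ",".join(sorted(occ.node_set))
            gi_str = ";".join(
                f"{'|'.join(sorted(pair))}:{sign}"
                for pair, sign in sorted(r.gi_edges, key=lambda e: sorted(e[0]))
            )
            fh.write(
                f"{occ.source}\t{occ.k}\t{comp}\t{nodes}\t{occ.topology}\t"
                f"{r.gi_count}\t{r.gi_possible}\t{r.pos_count}\t{r.neg_count}\t"
                f"{int(r.source_distant_ok)}\t{int(r.is_fnm)}\t{gi_str}\n"
            )
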