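"""Agglomerate FNMs by shared genes and report cluster statistics.

Clustering is greedy max-overlap agglomeration: repeatedly merge the pair of
current clusters whose union gene sets share the most genes, as long as the
shared count reaches ``min_overlap``.  Overlap is an absolute shared-gene
count (two shared genes is the weakest nontrivial overlap between k >= 3
motifs).  Singleton clusters are the "non-clustered" motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = ["MotifCluster", "cluster_fnms", "cluster_stats"]


@dataclass
class MotifCluster:
    """A set of FNMs agglomerated by gene overlap."""

    cluster_id: int
    motif_ids: list[int]
    genes: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.motif_ids)


def cluster_fnms(fnms: list[frozenset[str]], min_overlap: int = 2,
                 method: str = "greedy") -> list[MotifCluster]:
    """Cluster deduplicated FNM node sets by shared genes.

    ``method="greedy"`` merges maximally overlapping clusters first, ties
    broken by the smallest (id, id) pair; ``method="components"`` instead
    takes connected components of the pairwise-overlap graph.  Cluster ids
    are the smallest member motif index.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if method == "components":
        g = nx.Graph()
        g.add_nodes_from(range(len(fnms)))
        for i in range(len(fnms)):
            for j in range(i + 1, len(fnms)):
                if len(fnms[i] & fnms[j]) >= min_overlap:
                    g.add_edge(i, j)
        comps = [sorted(c) for c in nx.connected_components(g)]
        return [
            MotifCluster(cluster_id=c[0], motif_ids=c,
                         genes=frozenset().union(*(fnms[i] for i in c)))
            for c in sorted(comps)
        ]
    if method != "greedy":
        raise ValueError(f"unknown method {method!r}")

    clusters: dict[int, MotifCluster] = {
        i: MotifCluster(cluster_id=i, motif_ids=[i], genes=fnms[i])
        for i in range(len(fnms))
    }
    overlap: dict[tuple[int, int], int] = {}
    ids = sorted(clusters)
    for a_i, a in enumerate(ids):
        for b in ids[a_i + 1:]:
            ov = len(clusters[a].genes & clusters[b].genes)
            if ov >= min_overlap:
                overlap[(a, b)] = ov

    while overlap:
        # largest overlap first; ties by smallest (id, id)
        (a, b), _ = min(overlap.items(), key=lambda kv: (-kv[1], kv[0]))
        merged = MotifCluster(
            cluster_id=a,
            motif_ids=sorted(clusters[a].motif_ids + clusters[b].motif_ids),
            genes=clusters[a].genes | clusters[b].genes,
        )
        del clusters[b]
        clusters[a] = merged
        for key in [k for k in overlap if a in k or b in k]:
            del overlap[key]
        for other in clusters:
            if other == a:
                continue
            ov = len(merged.genes & clusters[other].genes)
            if ov >= min_overlap:
                overlap[tuple(sorted((a, other)))] = ov
    return [clusters[i] for i in sorted(clusters)]


def cluster_stats(clusters: list[MotifCluster], fnms: list[frozenset[str]],
                  net: nx.Graph | None = None) -> dict:
    """Clustered vs non-clustered counts, gene tallies and per-gene summaries.

    Returns a dict with motif-level fractions, the gene universes of all vs
    non-clustered FNMs, and a per-gene table of motif membership counts and
    PPI degree split by clustered/non-clustered gene group.
    """
    clustered = [c for c in clusters if c.size > 1]
    singletons = [c for c in clusters if c.size == 1]
    n = len(fnms)
    all_genes = frozenset().union(*fnms) if fnms else frozenset()
    nonclust_genes = (
        frozenset().union(*(c.genes for c in singletons)) if singletons else frozenset()
    )
    clustered_genes = (
        frozenset().union(*(c.genes for c in clustered)) if clustered else frozenset()
    )

    membership: dict[str, int] = {}
    for nodes in fnms:
        for g in nodes:
            membership[g] = membership.get(g, 0) + 1
    rows = []
    for g in sorted(all_genes):
        rows.append({
            "gene": g,
            "n_motifs": membership[g],
            "degree": net.degree(g) if net is not None and g in net else None,
            "clustered": g in clustered_genes,
        })
    return {
        "n_fnms": n,
        "n_clustered_motifs": sum(c.size for c in clustered),
        "n_nonclustered_motifs": len(singletons),
        "clustered_fraction": (sum(c.size for c in clustered) / n) if n else 0.0,
        "nonclustered_fraction": (len(singletons) / n) if n else 0.0,
        "n_genes_all": len(all_genes),
        "n_genes_nonclustered": len(nonclust_genes),
        "gene_fraction_nonclustered": (len(nonclust_genes) / len(all_genes))
        if all_genes else 0.0,
        "gene_table": pd.DataFrame(rows),
    }


def clusters_to_tsv(clusters: list[MotifCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tsize\tn_genes\tmember_motif_ids\n")
        for c in clusters:
            ids = ",".join(str(i) for i in c.motif_ids)
            fh.write(f"{c.cluster_id}\t{c.size}\t{len(c.genes)}\t{ids}\n")
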