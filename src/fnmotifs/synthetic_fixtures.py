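"""Seeded synthetic fixtures: paired PPI + GI networks with planted FNMs.

The generator emulates the shape of the real inputs -- a physical
interaction network, a quantitative GI score table whose distribution tails
define significant interactions, protein-complex annotations, flat gene
lists (essential, TF, metabolic), suppressor pairs, and a gene x condition
log-ratio expression matrix -- at a scale where the full pipeline runs in
seconds.  Planted motifs are constructed to satisfy the FNM criteria
(GI coverage at the ceiling of the threshold, source-to-distant-layer GIs
present), with their GI scores placed beyond the extremes of the background
score distribution so they are significant at any reasonable tail fraction.
The generator makes no attempt to match yeast topology statistics (degree
exponents, clustering spectra); it provides ground truth, not realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from fnmotifs.graphlets import GraphletOccurrence, canonical_topology, decode_graph6
from fnmotifs.fnm_filter import is_fnm
from fnmotifs.network_io import (
    ComplexMap, POSITIVE, NEGATIVE, clean_gi_table, threshold_gi,
    write_edge_list,
)

__all__ = ["PlantedMotif", "FixtureSpec", "FixtureBundle", "generate",
           "generate_expression"]


@dataclass(frozen=True)
class PlantedMotif:
    """One motif to plant: size, optional fixed topology, GI content."""

    k: int
    topology: str | None = None      # graph6; None = random connected
    gi_density: float = 0.5          # fraction of C(k,2) pairs with a GI
    sign_mix: float = 0.5            # probability a planted GI is positive
    coexpressed: bool = False
    bridging: bool = False           # tag one gene TF and one metabolic
    complex_members: int = 0         # genes drawn from distinct complexes


def _default_planted() -> list[PlantedMotif]:
    return [
        PlantedMotif(k=3, coexpressed=True),
        PlantedMotif(k=3),
        PlantedMotif(k=4, coexpressed=True, bridging=True),
        PlantedMotif(k=4),
        PlantedMotif(k=5, coexpressed=True, complex_members=2),
        PlantedMotif(k=5, bridging=True),
        PlantedMotif(k=6, coexpressed=True, complex_members=2),
        PlantedMotif(k=6, complex_members=2),
    ]


@dataclass(frozen=True)
class FixtureSpec:
    """Conditions of a synthetic study; defaults give a small dense test bed."""

    n_genes: int = 120
    ppi_p: float = 0.012             # Erdos-Renyi background edge probability
    n_complexes: int = 8
    complex_size: tuple[int, int] = (3, 5)
    planted: tuple[PlantedMotif, ...] = field(
        default_factory=lambda: tuple(_default_planted()))
    n_background_gi_pairs: int = 1200
    gi_tail_fraction: float = 0.05
    fnm_threshold: float = 0.5
    essential_rate: float = 0.15
    essential_multiplier: float = 3.0   # rate boost inside planted motifs
    n_suppressor_pairs: int = 40
    suppressor_base_rate: float = 0.3
    suppressor_multiplier: float = 3.0  # planted-motif suppressor-pair odds boost
    n_tf_genes: int = 15
    n_metabolic_genes: int = 30
    n_conditions: int = 20
    expression_effect: float = 2.0
    expression_noise_sd: float = 1.0
    expression_missing_rate: float = 0.01
    seed: int = 0


@dataclass
class FixtureBundle:
    """In-memory fixture: all pipeline inputs plus the ground-truth manifest."""

    spec: FixtureSpec
    ppi: nx.Graph
    gi_table: pd.DataFrame
    gi: nx.Graph
    complexes: ComplexMap
    essential_genes: frozenset[str]
    tf_genes: frozenset[str]
    metabolic_genes: frozenset[str]
    suppressor_pairs: frozenset[frozenset[str]]
    expression: pd.DataFrame
    manifest: pd.DataFrame
    planted_occurrences: list[GraphletOccurrence]


def _random_connected(k: int, rng: np.random.Generator) -> nx.Graph:
    while True:
        g = nx.gnp_random_graph(k, 0.5, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            return g


def _bfs_layers(g: nx.Graph, source) -> tuple[frozenset, ...]:
    layers = [frozenset((source,))]
    seen = {source}
    frontier = [source]
    while frontier:
        nxt = {w for u in frontier for w in g[u]} - seen
        if nxt:
            layers.append(frozenset(nxt))
            seen |= nxt
        frontier = sorted(nxt)
    return tuple(layers)


def generate(spec: FixtureSpec, outdir=None) -> FixtureBundle:
    """Build the full fixture bundle; optionally write all input files.

    Deterministic: the same spec (including seed) regenerates byte-identical
    files.  Raises when the spec is infeasible (motifs larger than the gene
    pool, planted GI edges exceeding the significance-tail capacity, or a
    planted motif failing its own FNM criteria).
    """
    rng = np.random.default_rng(spec.seed)
    if any(p.k < 2 for p in spec.planted):
        raise ValueError("planted motif size must be >= 2")
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]

    need = (sum(p.k - p.complex_members for p in spec.planted)
            + spec.n_complexes * spec.complex_size[1])
    if need > spec.n_genes:
        raise ValueError(f"spec infeasible: needs {need} genes, has {spec.n_genes}")
    if sum(p.complex_members for p in spec.planted) > spec.n_complexes:
        raise ValueError("spec infeasible: more planted complex-member slots "
                         "than complexes (each complex is used at most once)")

    # background PPI
    g_idx = nx.gnp_random_graph(spec.n_genes, spec.ppi_p,
                                seed=int(rng.integers(2**31)))
    ppi = nx.relabel_nodes(g_idx, {i: genes[i] for i in range(spec.n_genes)})
    ppi.add_nodes_from(genes)

    # complexes: disjoint gene blocks at the end of the namespace, as cliques
    cursor = spec.n_genes
    members: dict[str, frozenset[str]] = {}
    for c in range(spec.n_complexes):
        size = int(rng.integers(spec.complex_size[0], spec.complex_size[1] + 1))
        cursor -= size
        block = frozenset(genes[cursor:cursor + size])
        members[f"CPX{c:03d}"] = block
        for u in block:
            for v in block:
                if u < v:
                    ppi.add_edge(u, v)
    cmap = ComplexMap(members)
    complex_genes = frozenset().union(*members.values()) if members else frozenset()

    # planted motifs: disjoint blocks from the front of the namespace
    cursor = 0
    planted_occurrences: list[GraphletOccurrence] = []
    planted_gi: list[tuple[str, str, str]] = []  # (a, b, sign)
    manifest_rows = []
    complex_queue = sorted(members)  # each complex contributes at most one motif gene
    for mid, pm in enumerate(spec.planted):
        topo = decode_graph6(pm.topology) if pm.topology else _random_connected(pm.k, rng)
        if topo.number_of_nodes() != pm.k or not nx.is_connected(topo):
            raise ValueError(f"planted motif {mid}: topology must be connected on k nodes")
        n_aux = pm.k - pm.complex_members
        block = genes[cursor:cursor + n_aux]
        cursor += n_aux
        for _ in range(pm.complex_members):
            cid = complex_queue.pop(0)
            block = block + [sorted(members[cid])[0]]
        mapping = {i: block[i] for i in range(pm.k)}
        # make the induced subgraph exactly the planted topology
        for i in range(pm.k):
            for j in range(i + 1, pm.k):
                u, v = mapping[i], mapping[j]
                if topo.has_edge(i, j):
                    ppi.add_edge(u, v)
                elif ppi.has_edge(u, v):
                    ppi.remove_edge(u, v)
        source = mapping[0]
        layers = _bfs_layers(nx.relabel_nodes(topo, mapping), source)
        # GI edges: span pairs first, then fill to the coverage ceiling
        pairs = [(mapping[i], mapping[j])
                 for i in range(pm.k) for j in range(i + 1, pm.k)]
        forced = {tuple(sorted((source, v))) for v in layers[-1]}
        cgenes = block[n_aux:]
        for i in range(len(cgenes)):        # complex pairs always interact
            for j in range(i + 1, len(cgenes)):
                forced.add(tuple(sorted((cgenes[i], cgenes[j]))))
        needed = max(math.ceil(pm.gi_density * len(pairs)), len(forced))
        chosen = [p for p in pairs if tuple(sorted(p)) in forced]
        rest = [p for p in pairs if tuple(sorted(p)) not in forced]
        extra = rng.permutation(len(rest))[:needed - len(chosen)]
        chosen += [rest[i] for i in extra]
        for a, b in chosen:
            sign = POSITIVE if rng.random() < pm.sign_mix else NEGATIVE
            planted_gi.append((a, b, sign))
        manifest_rows.append({
            "motif_id": mid, "k": pm.k, "source": source,
            "nodes": ",".join(sorted(block)),
            "coexpressed": pm.coexpressed, "bridging": pm.bridging,
            "expected_fnm": True,
        })
        planted_occurrences.append(
            GraphletOccurrence(source=source, layers=layers,
                               topology=canonical_topology(topo))
        )

    # background GI scores ~ N(0, 1) on random non-planted pairs
    planted_pairs = {frozenset((a, b)) for a, b, _ in planted_gi}
    bg_pairs: set[frozenset[str]] = set()
    while len(bg_pairs) < spec.n_background_gi_pairs:
        i, j = rng.integers(0, spec.n_genes, size=2)
        if i == j:
            continue
        pair = frozenset((genes[i], genes[j]))
        if pair not in planted_pairs:
            bg_pairs.add(pair)
    bg_sorted = sorted(tuple(sorted(p)) for p in bg_pairs)
    bg_scores = rng.normal(0.0, 1.0, size=len(bg_sorted))

    n_tail = spec.gi_tail_fraction * (len(bg_sorted) + len(planted_gi))
    n_planted_neg = sum(1 for _, _, s in planted_gi if s == NEGATIVE)
    n_planted_pos = len(planted_gi) - n_planted_neg
    if n_planted_neg > 0.9 * n_tail or n_planted_pos > 0.9 * n_tail:
        raise ValueError("spec infeasible: planted GI edges exceed the "
                         "significance-tail capacity")
    lo = float(bg_scores.min()) - 1.0
    hi = float(bg_scores.max()) + 1.0
    rows = [{"gene_a": a, "gene_b": b, "score": s}
            for (a, b), s in zip(bg_sorted, bg_scores)]
    for a, b, sign in planted_gi:
        offset = float(rng.uniform(0.0, 1.0))
        score = hi + offset if sign == POSITIVE else lo - offset
        rows.append({"gene_a": a, "gene_b": b, "score": score})
    gi_table = clean_gi_table(pd.DataFrame(rows))
    gi = threshold_gi(gi_table, spec.gi_tail_fraction)

    # verify every planted motif passes its own FNM criteria
    for occ, row in zip(planted_occurrences, manifest_rows):
        rec = is_fnm(occ, gi, threshold=spec.fnm_threshold)
        if not rec.is_fnm:
            raise AssertionError(f"planted motif {row['motif_id']} failed the "
                                 "FNM criteria (generator bug)")

    # gene annotations
    planted_gene_set = {g for occ in planted_occurrences for g in occ.node_set}
    boosted = min(1.0, spec.essential_rate * spec.essential_multiplier)
    essential = frozenset(
        g for g in genes
        if rng.random() < (boosted if g in planted_gene_set else spec.essential_rate)
    )

    suppressors: set[frozenset[str]] = set()
    p_hit = min(1.0, spec.suppressor_base_rate * spec.suppressor_multiplier)
    for occ in planted_occurrences:
        if rng.random() < p_hit:
            nodes = sorted(occ.node_set)
            i, j = rng.choice(len(nodes), size=2, replace=False)
            suppressors.add(frozenset((nodes[i], nodes[j])))
    while len(suppressors) < spec.n_suppressor_pairs:
        i, j = rng.integers(0, spec.n_genes, size=2)
        if i != j:
            suppressors.add(frozenset((genes[i], genes[j])))

    tf: set[str] = set()
    metabolic: set[str] = set()
    for occ, pm in zip(planted_occurrences, spec.planted):
        if pm.bridging:
            nodes = sorted(occ.node_set)
            tf.add(nodes[0])
            metabolic.add(nodes[-1])
    free = [g for g in genes if g not in planted_gene_set and g not in complex_genes]
    picks = rng.choice(len(free), size=min(len(free),
                       spec.n_tf_genes + spec.n_metabolic_genes), replace=False)
    for i, p in enumerate(picks):
        (tf if i < spec.n_tf_genes else metabolic).add(free[p])

    # expression with planted co-expressed groups
    groups = [sorted(occ.node_set)
              for occ, pm in zip(planted_occurrences, spec.planted)
              if pm.coexpressed]
    expression = generate_expression(
        genes, groups, spec.n_conditions, spec.expression_effect,
        spec.expression_noise_sd, seed=int(rng.integers(2**31)),
        missing_rate=spec.expression_missing_rate,
    )

    manifest = pd.DataFrame(manifest_rows)
    bundle = FixtureBundle(
        spec=spec, ppi=ppi, gi_table=gi_table, gi=gi, complexes=cmap,
        essential_genes=essential, tf_genes=frozenset(tf),
        metabolic_genes=frozenset(metabolic),
        suppressor_pairs=frozenset(suppressors), expression=expression,
        manifest=manifest, planted_occurrences=planted_occurrences,
    )
    if outdir is not None:
        _write_bundle(bundle, outdir)
    return bundle


def generate_expression(genes, planted_groups, n_conditions: int,
                        effect: float, noise_sd: float, seed: int = 0,
                        missing_rate: float = 0.0) -> pd.DataFrame:
    """Log-ratio expression matrix with shared latent responses per group.

    Genes of a planted group get ``effect * latent + N(0, noise_sd)`` per
    condition, with one latent response vector per group; all other genes
    are pure noise.  A small fraction of entries may be blanked to NaN.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    rng = np.random.default_rng(seed)
    conditions = [f"cond{j:02d}" for j in range(n_conditions)]
    data = rng.normal(0.0, noise_sd, size=(len(genes), n_conditions))
    index = {g: i for i, g in enumerate(genes)}
    for group in planted_groups:
        latent = rng.normal(0.0, 1.0, size=n_conditions)
        for g in group:
            data[index[g]] += effect * latent
    if missing_rate > 0:
        mask = rng.random(data.shape) < missing_rate
        data[mask] = np.nan
    return pd.DataFrame(data, index=list(genes), columns=conditions)


def _write_bundle(bundle: FixtureBundle, outdir) -> None:
    import os

    os.makedirs(outdir, exist_ok=True)
    join = lambda name: os.path.join(outdir, name)
    write_edge_list(bundle.ppi, join("ppi.tsv"))
    bundle.gi_table.to_csv(join("gi_scores.tsv"), sep="\t", index=False,
                           header=False, float_format="%.6f")
    with open(join("complexes.tsv"), "w") as fh:
        for cid in sorted(bundle.complexes.members):
            for g in sorted(bundle.complexes.members[cid]):
                fh.write(f"{cid}\t{g}\n")
    for name, geneset in (("essential.txt", bundle.essential_genes),
                          ("tfs.txt", bundle.tf_genes),
                          ("metabolic.txt", bundle.metabolic_genes)):
        with open(join(name), "w") as fh:
            fh.writelines(f"{g}\n" for g in sorted(geneset))
    with open(join("suppressors.tsv"), "w") as fh:
        for pair in sorted(tuple(sorted(p)) for p in bundle.suppressor_pairs):
            fh.write(f"{pair[0]}\t{pair[1]}\n")
    bundle.expression.round(6).to_csv(join("expression.tsv"), sep="\t",
                                      index_label="gene")
    bundle.manifest.to_csv(join("manifest.tsv"), sep="\t", index=False)
    with open(join("manifest_summary.txt"), "w") as fh:
        fh.write(f"genes: {bundle.spec.n_genes}\n"
                 f"ppi edges: {bundle.ppi.number_of_edges()}\n"
                 f"gi pairs scored: {len(bundle.gi_table)}\n"
                 f"significant gi edges: {bundle.gi.number_of_edges()}\n"
                 f"planted motifs: {len(bundle.manifest)}\n")
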