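"""End-to-end pipeline: build networks, census, FNM filter, null models,
clustering, complex map, co-regulation and enrichment, into a run directory.

Every stage is deterministic given the configuration (which includes the
seed); a run directory is stamped with a hash of the configuration, and
stages refuse to mix intermediates produced under a different one.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import yaml

from fnmotifs import (
    network_io, graphlets, fnm_filter, randomization, motif_clustering,
    complex_analysis, coregulation, stats_enrichment,
)

log = logging.getLogger("fnmotifs")

__all__ = ["PipelineConfig", "run"]


@dataclass
class PipelineConfig:
    """All knobs of the analysis, defaults at the study's stated settings."""

    # inputs
    ppi_path: str = ""
    ppi_preset: str = "edge_list"
    physical_only: bool = False
    gi_path: str = ""
    complexes_path: str = ""
    essential_path: str = ""
    tf_path: str = ""
    metabolic_path: str = ""
    suppressor_path: str = ""
    expression_path: str = ""
    # analysis settings
    ks: tuple[int, ...] = (3, 4, 5, 6)
    d_max: int = 50                 # hub cutoff; 25 and 100 as variants
    dmax_before_intracomplex: bool = False
    gi_tail_fraction: float = 0.05
    gi_degree_filtered: bool = False  # apply d_max to the GI net for the FNM test
    fnm_threshold: float = 0.5
    require_span: bool = True
    R: int = 30
    swaps_per_edge: float = 10.0
    min_overlap: int = 2
    cluster_method: str = "greedy"
    complex_use: str = "nonclustered"  # or "all"
    coreg_quantiles: tuple[float, float] = (0.95, 0.99)
    control_n: int = 1000
    seed: int = 1

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.ks = tuple(cfg.ks)
        cfg.coreg_quantiles = tuple(cfg.coreg_quantiles)
        return cfg

    @property
    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _check_lock(cfg: PipelineConfig, outdir: str) -> None:
    lock = os.path.join(outdir, "config.lock")
    if os.path.exists(lock):
        with open(lock) as fh:
            existing = fh.read().strip()
        if existing != cfg.hash:
            raise RuntimeError(
                f"run directory {outdir} was produced under a different "
                f"configuration ({existing} != {cfg.hash}); refusing to mix"
            )
    else:
        os.makedirs(outdir, exist_ok=True)
        with open(lock, "w") as fh:
            fh.write(cfg.hash + "\n")
        cfg.to_yaml(os.path.join(outdir, "config.yaml"))


def build_networks(cfg: PipelineConfig):
    """Stage 1: read and filter the PPI and GI networks and annotations."""
    ppi_raw = network_io.read_ppi(cfg.ppi_path, preset=cfg.ppi_preset,
                                  physical_only=cfg.physical_only)
    cmap = (network_io.read_complexes(cfg.complexes_path)
            if cfg.complexes_path else network_io.ComplexMap({}))
    if cfg.dmax_before_intracomplex:
        net = network_io.filter_degree(ppi_raw, cfg.d_max)
        net = network_io.remove_intracomplex_edges(net, cmap)
    else:
        net = network_io.remove_intracomplex_edges(ppi_raw, cmap)
        net = network_io.filter_degree(net, cfg.d_max)
    gi_table = network_io.read_gi_scores(cfg.gi_path)
    gi = network_io.threshold_gi(gi_table, cfg.gi_tail_fraction)
    if cfg.gi_degree_filtered:
        gi = network_io.filter_degree(gi, cfg.d_max)
    return ppi_raw, net, gi, cmap


def run(cfg: PipelineConfig, outdir: str) -> dict:
    """Execute all stages; write TSV/GraphML outputs, a log, and a summary.

    Returns the summary dict (also written as summary.json / summary.tsv).
    """
    _check_lock(cfg, outdir)
    join = lambda name: os.path.join(outdir, name)
    summary: dict = {"config_hash": cfg.hash, "seed": cfg.seed}

    log.info("stage build: reading and filtering networks")
    ppi_raw, net, gi, cmap = build_networks(cfg)
    network_io.write_edge_list(net, join("enum_net.tsv"))
    network_io.write_signed_gi(gi, join("gi_signed.tsv"))
    summary["n_genes_enum_net"] = net.number_of_nodes()
    summary["n_edges_enum_net"] = net.number_of_edges()
    summary["n_gi_edges"] = gi.number_of_edges()

    log.info("stage enumerate/fnm: census for k in %s", cfg.ks)
    occ_tables: dict[int, graphlets.OccurrenceTable] = {}
    fnm_tables: dict[int, fnm_filter.FNMTable] = {}
    for k in cfg.ks:
        occ = graphlets.enumerate_all(net, k)
        occ_tables[k] = occ
        graphlets.occurrences_to_tsv(occ, join(f"occurrences_k{k}.tsv"))
        ft = fnm_filter.find_fnms(occ, gi, cfg.fnm_threshold, cfg.require_span)
        fnm_tables[k] = ft
        fnm_filter.fnms_to_tsv(ft, join(f"fnm_k{k}.tsv"))
        summary[f"n_occurrences_k{k}"] = occ.n_per_source
        summary[f"n_unique_subgraphs_k{k}"] = occ.n_unique
        summary[f"n_fnm_occurrences_k{k}"] = len(ft.fnms)
        summary[f"n_fnm_unique_k{k}"] = len(ft.by_node_set)
        log.info("k=%d: %d occurrences, %d FNM occurrences",
                 k, occ.n_per_source, len(ft.fnms))

    log.info("stage randomize: R=%d null models", cfg.R)
    for k in cfg.ks:
        for mode in ("ppi_random", "gi_random"):
            ms = randomization.randomized_motif_summary(
                net, gi, k, mode=mode, R=cfg.R, seed=cfg.seed,
                swaps_per_edge=cfg.swaps_per_edge,
                threshold=cfg.fnm_threshold, require_span=cfg.require_span)
            ms.to_tsv(join(f"motif_summary_{mode}_k{k}.tsv"))
            finite = ms.table["z"].dropna()
            summary[f"median_z_{mode}_k{k}"] = (
                float(np.median(finite)) if len(finite) else None)

    log.info("stage cluster")
    dedup: list[tuple[int, frozenset[str], fnm_filter.FNMRecord]] = []
    for k in cfg.ks:
        for nodes, recs in sorted(fnm_tables[k].by_node_set.items(),
                                  key=lambda kv: sorted(kv[0])):
            dedup.append((k, nodes, recs[0]))
    node_sets = [nodes for _, nodes, _ in dedup]
    clusters = motif_clustering.cluster_fnms(node_sets, cfg.min_overlap,
                                             method=cfg.cluster_method)
    motif_clustering.clusters_to_tsv(clusters, join("clusters.tsv"))
    cstats = motif_clustering.cluster_stats(clusters, node_sets, net)
    cstats["gene_table"].to_csv(join("cluster_genes.tsv"), sep="\t", index=False)
    for key in ("n_fnms", "n_clustered_motifs", "n_nonclustered_motifs",
                "clustered_fraction", "nonclustered_fraction",
                "n_genes_all", "n_genes_nonclustered",
                "gene_fraction_nonclustered"):
        summary[f"cluster_{key}"] = cstats[key]

    log.info("stage complexnet")
    singleton_ids = {c.motif_ids[0] for c in clusters if c.size == 1}
    if cfg.complex_use == "nonclustered" and singleton_ids:
        chosen = [rec for i, (_, _, rec) in enumerate(dedup) if i in singleton_ids]
    else:
        chosen = [rec for _, _, rec in dedup]
    cnet = complex_analysis.build_complex_network(chosen, cmap, net)
    if cnet.number_of_nodes():
        flat = cnet.copy()
        for n, d in flat.nodes(data=True):
            if "genes" in d:  # GraphML only takes scalar attributes
                d["genes"] = ",".join(sorted(d["genes"]))
        nx.write_graphml(flat, join("complex_network.graphml"))
    scores, fractions = complex_analysis.consensus_gi(cnet)
    with open(join("consensus_gi.tsv"), "w") as fh:
        fh.write("complex_a\tcomplex_b\tn_pos\tn_neg\tscore\n")
        for s in scores:
            fh.write(f"{s.complex_a}\t{s.complex_b}\t{s.n_pos}\t{s.n_neg}\t"
                     f"{s.score:.4f}\n")
    summary["complexpair_ppi_and_gi_fraction"] = fractions["ppi_and_gi"]
    summary["complexpair_ppi_only_fraction"] = fractions["ppi_only"]
    summary["complexpair_gi_only_fraction"] = fractions["gi_only"]
    summary["n_consensus_pairs"] = len(scores)
    summary["mean_abs_consensus"] = (
        float(np.mean([abs(s.score) for s in scores])) if scores else None)

    comparison = {
        "fnm": cnet,
        "ppi_dmax": complex_analysis.merge_complexes(net, cmap),
        "ppi_all": complex_analysis.merge_complexes(ppi_raw, cmap),
    }
    comparison = {k: v for k, v in comparison.items() if v.number_of_nodes()}
    if comparison:
        ranking = complex_analysis.rank_auxiliary(comparison)
        ranking.to_csv(join("betweenness_ranking.tsv"), sep="\t", index=False)
        for name, sizes in ranking.attrs["sizes"].items():
            summary[f"betweenness_n_aux_{name}"] = sizes["n_auxiliary"]
            summary[f"betweenness_n_effective_{name}"] = sizes["n_effective"]
        for (a, b), p in ranking.attrs["wmw_pvalues"].items():
            summary[f"betweenness_wmw_p_{a}_vs_{b}"] = p

    if cfg.tf_path and cfg.metabolic_path:
        tfs = network_io.read_gene_set(cfg.tf_path)
        met = network_io.read_gene_set(cfg.metabolic_path)
        groups = complex_analysis.bridging_fnms([r for _, _, r in dedup], tfs, met)
        summary["n_bridging_groups"] = len(groups)
        with open(join("bridging_groups.tsv"), "w") as fh:
            fh.write("group\tn_fnms\tgenes\n")
            for gidx, grp in enumerate(groups):
                genes = sorted(set().union(*(r.occurrence.node_set for r in grp)))
                fh.write(f"{gidx}\t{len(grp)}\t{','.join(genes)}\n")

    if cfg.expression_path:
        log.info("stage coreg")
        expr = network_io.read_expression(cfg.expression_path)
        ks_per_motif = [k for k, _, _ in dedup]
        coreg = coregulation.coregulation_table(
            node_sets, expr, quantiles=cfg.coreg_quantiles, ks=ks_per_motif)
        coreg.drop(columns=[]).round(6).to_csv(join("coregulation.tsv"),
                                               sep="\t", index=False)
        defined = coreg["score"].dropna()
        summary["coreg_n_scored"] = int(len(defined))
        summary["coreg_mean_score"] = float(defined.mean()) if len(defined) else None
        summary["coreg_top5_count"] = int(coreg["top5"].sum())
        summary["coreg_top1_count"] = int(coreg["top1"].sum())

    log.info("stage enrich")
    all_records = [r for k in cfg.ks for r in fnm_tables[k].records]
    fnm_sets = [r.occurrence.node_set for r in all_records if r.is_fnm]
    ppi_sets = [r.occurrence.node_set for r in all_records if not r.is_fnm]
    if cfg.suppressor_path and fnm_sets and ppi_sets:
        pairs = network_io.read_gene_pairs(cfg.suppressor_path)
        hit_fnm = sum(1 for nodes in fnm_sets if any(p <= nodes for p in pairs))
        hit_ppi = sum(1 for nodes in ppi_sets if any(p <= nodes for p in pairs))
        f_fnm = hit_fnm / len(fnm_sets)
        f_ppi = hit_ppi / len(ppi_sets)
        table = [[hit_fnm, len(fnm_sets) - hit_fnm],
                 [hit_ppi, len(ppi_sets) - hit_ppi]]
        odds, p = stats_enrichment.fisher_exact_2x2(table)
        summary["suppressor_fraction_fnm"] = f_fnm
        summary["suppressor_fraction_ppi"] = f_ppi
        summary["suppressor_fisher_p"] = p
        profile: dict[tuple[int, int], int] = {}
        for r in all_records:
            if r.is_fnm:
                key = (r.occurrence.k, r.gi_count)
                profile[key] = profile.get(key, 0) + 1
        try:
            control = stats_enrichment.matched_control_motifs(
                all_records, profile, n=cfg.control_n, seed=cfg.seed)
            f_ctrl = stats_enrichment.suppressor_fraction(
                [r.occurrence.node_set for r in control], pairs)
            summary["suppressor_fraction_ctrl"] = f_ctrl
        except ValueError:
            summary["suppressor_fraction_ctrl"] = None
    if cfg.essential_path and fnm_sets and ppi_sets:
        ess = network_io.read_gene_set(cfg.essential_path)
        fr_fnm = stats_enrichment.motif_gene_fractions(fnm_sets, ess)
        fr_ppi = stats_enrichment.motif_gene_fractions(ppi_sets, ess)
        _, p = stats_enrichment.mann_whitney_u(fr_fnm, fr_ppi)
        summary["essential_fraction_fnm"] = float(fr_fnm.mean())
        summary["essential_fraction_ppi"] = float(fr_ppi.mean())
        summary["essential_wmw_p"] = p
    if cmap.members and fnm_sets and ppi_sets:
        subunits = frozenset(g for gs in cmap.members.values() for g in gs)
        fr_fnm = stats_enrichment.motif_gene_fractions(fnm_sets, subunits)
        fr_ppi = stats_enrichment.motif_gene_fractions(ppi_sets, subunits)
        _, p = stats_enrichment.mann_whitney_u(fr_fnm, fr_ppi)
        summary["subunit_fraction_fnm"] = float(fr_fnm.mean())
        summary["subunit_fraction_ppi"] = float(fr_ppi.mean())
        summary["subunit_wmw_p"] = p

    with open(join("summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(join("summary.tsv"), "w") as fh:
        fh.write("key\tvalue\n")
        for key in sorted(summary):
            fh.write(f"{key}\t{summary[key]}\n")
    log.info("run complete: %s", outdir)
    return summary
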