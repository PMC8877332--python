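"""Readers, filters and writers for the interaction data the pipeline consumes.

Networks are plain :class:`networkx.Graph` objects over gene identifiers
(systematic ORF names, upper-cased).  The signed GI network carries per-edge
``sign`` ("+" / "-") and ``score`` attributes.  Expression data is a pandas
DataFrame (genes x conditions, log-ratios, NaN for missing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

POSITIVE = "+"
NEGATIVE = "-"

# column names of the BioGRID tab-style preset
_BIOGRID_A = "Systematic Name Interactor A"
_BIOGRID_B = "Systematic Name Interactor B"
_BIOGRID_TYPE = "Experimental System Type"


class FormatError(ValueError):
    """Raised when an input file does not match the declared format."""


def _norm(gene: str) -> str:
    return str(gene).strip().upper()


@dataclass
class ComplexMap:
    """Protein-complex annotation: complex id -> member gene set.

    ``gene_to_complex`` maps only genes annotated to exactly one complex;
    genes in several complexes are listed in ``multi_complex`` and excluded
    from the single-valued mapping.
    """

    members: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def gene_to_complex(self) -> dict[str, str]:
        counts: dict[str, list[str]] = {}
        for cid, genes in self.members.items():
            for g in genes:
                counts.setdefault(g, []).append(cid)
        return {g: cids[0] for g, cids in counts.items() if len(cids) == 1}

    @property
    def multi_complex(self) -> frozenset[str]:
        counts: dict[str, int] = {}
        for genes in self.members.values():
            for g in genes:
                counts[g] = counts.get(g, 0) + 1
        return frozenset(g for g, c in counts.items() if c > 1)

    def share_complex(self, a: str, b: str) -> bool:
        """True when both genes are members of at least one common complex."""
        return any(a in genes and b in genes for genes in self.members.values())


def read_ppi(path, preset: str = "edge_list", physical_only: bool = False) -> nx.Graph:
    """Read a PPI edge table into a simple undirected graph.

    ``preset="edge_list"`` expects two gene columns (no header needed);
    ``preset="biogrid_tab"`` expects a header with the systematic interactor
    name columns and the experimental system type column, the latter used by
    ``physical_only`` to keep physical interactions and drop genetic ones.
    Self-loops and duplicate edges are dropped.
    """
    if preset == "edge_list":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 2:
            raise FormatError(f"{path}: edge list needs two columns, found {df.shape[1]}")
        a, b = df.iloc[:, 0], df.iloc[:, 1]
    elif preset == "biogrid_tab":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in (_BIOGRID_A, _BIOGRID_B, _BIOGRID_TYPE):
            if col not in df.columns:
                raise FormatError(f"{path}: missing required column {col!r}")
        if physical_only:
            df = df[df[_BIOGRID_TYPE].str.strip().str.lower() == "physical"]
        a, b = df[_BIOGRID_A], df[_BIOGRID_B]
    else:
        raise ValueError(f"unknown preset {preset!r}")

    net = nx.Graph()
    for u, v in zip(a, b):
        u, v = _norm(u), _norm(v)
        if u != v:
            net.add_edge(u, v)
    if net.number_of_edges() == 0:
        warnings.warn(f"{path}: no edges after filtering", stacklevel=2)
    return net


def read_gi_scores(path) -> pd.DataFrame:
    """Read a (gene_a, gene_b, score) TSV into a cleaned GI score table.

    Self-pairs are dropped; duplicate unordered pairs are collapsed to the
    score of maximal absolute value (strongest evidence).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["gene_a", "gene_b", "score"],
                     dtype={0: str, 1: str, 2: float}, skiprows=_header_rows(path))
    return clean_gi_table(df)


def _header_rows(path) -> int:
    with open(path) as fh:
        first = fh.readline()
    fields = first.rstrip("\n").split("\t")
    if len(fields) >= 3:
        try:
            float(fields[2])
            return 0
        except ValueError:
            return 1
    return 0


def clean_gi_table(df: pd.DataFrame) -> pd.DataFrame:
    """Normalize identifiers, drop self-pairs, keep the strongest score per pair."""
    df = df.copy()
    df["gene_a"] = df["gene_a"].map(_norm)
    df["gene_b"] = df["gene_b"].map(_norm)
    df = df[df["gene_a"] != df["gene_b"]]
    lo = [min(a, b) for a, b in zip(df["gene_a"], df["gene_b"])]
    hi = [max(a, b) for a, b in zip(df["gene_a"], df["gene_b"])]
    df = df.assign(gene_a=lo, gene_b=hi)
    df = df.loc[df["score"].abs().groupby([df["gene_a"], df["gene_b"]]).idxmax()]
    return df.reset_index(drop=True)


def threshold_gi(table: pd.DataFrame, tail_fraction: float = 0.05) -> nx.Graph:
    """Build the signed GI network from the score-distribution tails.

    Pairs with score at or below the ``tail_fraction`` empirical quantile
    become negative edges, pairs at or above the ``1 - tail_fraction``
    quantile positive edges (linear-interpolation quantiles, inclusive
    comparison).  Everything in between is considered non-significant.
    """
    if not 0 < tail_fraction < 0.5:
        raise ValueError("tail_fraction must lie in (0, 0.5)")
    if len(table) == 0:
        raise ValueError("empty GI score table")
    table = clean_gi_table(table)
    scores = table["score"].to_numpy(float)
    if np.all(scores == scores[0]):
        raise ValueError("all GI scores identical: quantile thresholds degenerate")
    lo = float(np.quantile(scores, tail_fraction))
    hi = float(np.quantile(scores, 1.0 - tail_fraction))
    gi = nx.Graph()
    for a, b, s in zip(table["gene_a"], table["gene_b"], scores):
        if s <= lo:
            gi.add_edge(a, b, sign=NEGATIVE, score=float(s))
        elif s >= hi:
            gi.add_edge(a, b, sign=POSITIVE, score=float(s))
    return gi


def remove_intracomplex_edges(net: nx.Graph, cmap: ComplexMap) -> nx.Graph:
    """Drop PPI edges between subunits of the same annotated complex.

    Edges are removed whenever the two genes share membership in any complex,
    multi-complex genes included.  The node set is unchanged.
    """
    out = net.copy()
    out.remove_edges_from([(u, v) for u, v in net.edges() if cmap.share_complex(u, v)])
    return out


def filter_degree(net: nx.Graph, d_max: int) -> nx.Graph:
    """Delete hub nodes of degree >= ``d_max`` (degrees taken before deletion).

    Excluding the most highly connected hubs keeps exhaustive enumeration
    tractable and focuses the census on specific interactions rather than
    promiscuous hubs.
    """
    if d_max < 2:
        raise ValueError("d_max must be >= 2")
    out = net.copy()
    out.remove_nodes_from([n for n, d in net.degree() if d >= d_max])
    return out


def read_complexes(path) -> ComplexMap:
    """Read complex annotations as (complex_id, gene) rows or ``id<TAB>g1,g2,..`` lines."""
    members: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected at least 2 tab-separated fields")
            cid = parts[0].strip()
            genes = [g for p in parts[1:] for g in p.split(",") if g.strip()]
            members.setdefault(cid, set()).update(_norm(g) for g in genes)
    return ComplexMap({cid: frozenset(gs) for cid, gs in members.items()})


def read_gene_set(path) -> frozenset[str]:
    """Read a flat one-gene-per-line list (unknown genes kept verbatim)."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                genes.add(_norm(g.split("\t")[0]))
    return frozenset(genes)


def read_gene_pairs(path) -> frozenset[frozenset[str]]:
    """Read unordered gene pairs (e.g. suppressor interactions) from a 2-column TSV."""
    pairs: set[frozenset[str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated genes")
            a, b = _norm(parts[0]), _norm(parts[1])
            if a != b:
                pairs.add(frozenset((a, b)))
    return frozenset(pairs)


def read_expression(path) -> pd.DataFrame:
    """Read a gene x condition log-ratio matrix; empty cells become NaN."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = [_norm(g) for g in df.index]
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate gene identifiers")
    if df.shape[1] < 1:
        raise FormatError(f"{path}: expression matrix needs >= 1 condition column")
    return df.astype(float)


# ---------------------------------------------------------------- writers

def write_edge_list(net: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.edges()):
            fh.write(f"{u}\t{v}\n")


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path)


def write_signed_gi(gi: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tscore\tsign\n")
        for u, v in sorted(tuple(sorted(e)) for e in gi.edges()):
            d = gi[u][v]
            fh.write(f"{u}\t{v}\t{d['score']}\t{d['sign']}\n")


def gi_pairs(gi: nx.Graph) -> frozenset[frozenset[str]]:
    """The unordered node pairs of the signed GI network."""
    return frozenset(frozenset(e) for e in gi.edges())
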