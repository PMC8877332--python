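"""Degree-preserving null models and motif over-representation z-scores.

Randomization uses the edge-switching model: repeated double-edge swaps
(u-v, x-y) -> (u-x, v-y), rejecting swaps that would create self-loops or
duplicate edges.  Every node keeps its exact degree; edge attributes (GI
sign and score) ride along with their edge, so the sign multiset is also
conserved.  Motif counts on R rewired networks give the null mean, standard
deviation and z-score per topology.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from fnmotifs.graphlets import enumerate_all
from fnmotifs.fnm_filter import find_fnms

__all__ = ["rewire", "randomized_motif_summary", "MotifCountSummary"]


def rewire(net: nx.Graph, swaps_per_edge: float = 10.0, seed: int = 0) -> nx.Graph:
    """Degree-preserving randomization by attempted double-edge swaps.

    ``ceil(swaps_per_edge * |E|)`` swaps are attempted; invalid swaps
    (self-loop or duplicate edge) are rejected, which preserves the uniform
    stationary distribution over graphs with the given degree sequence.
    """
    m = net.number_of_edges()
    if m < 2:
        warnings.warn("fewer than 2 edges: nothing to rewire", stacklevel=2)
        return net.copy()
    rng = np.random.default_rng(seed)
    out = net.copy()
    edges = [tuple(e) for e in out.edges()]
    attempts = math.ceil(swaps_per_edge * m)
    for _ in range(attempts):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        u, v = edges[i]
        x, y = edges[j]
        if rng.integers(0, 2):
            x, y = y, x
        # proposed: u-x, v-y
        if u == x or v == y or out.has_edge(u, x) or out.has_edge(v, y):
            continue
        attr_uv = dict(out[u][v])
        attr_xy = dict(out[x][y])
        out.remove_edge(u, v)
        out.remove_edge(x, y)
        out.add_edge(u, x, **attr_uv)
        out.add_edge(v, y, **attr_xy)
        edges[i] = (u, x)
        edges[j] = (v, y)
    return out


@dataclass
class MotifCountSummary:
    """Observed vs null motif counts per topology (graph6-keyed)."""

    k: int
    mode: str
    R: int
    seed: int
    table: pd.DataFrame  # columns: graph6, observed, null_mean, null_sd, z

    def to_tsv(self, path) -> None:
        df = self.table.copy()
        df["k"] = self.k
        df["R"] = self.R
        df["mode"] = self.mode
        df["seed"] = self.seed
        df.to_csv(path, sep="\t", index=False)


def randomized_motif_summary(net: nx.Graph, gi: nx.Graph | None, k: int,
                             mode: str = "ppi_random", R: int = 30,
                             seed: int = 0, swaps_per_edge: float = 10.0,
                             threshold: float = 0.5,
                             require_span: bool = True) -> MotifCountSummary:
    """Observed vs randomized motif counts with per-topology z-scores.

    ``mode="ppi_random"`` re-enumerates plain PPI graphlets on R rewired PPI
    networks; ``mode="gi_random"`` keeps the PPI fixed and recomputes FNMs
    against R rewired GI networks.  Replicate r derives its seed as
    ``seed + r`` so runs are reproducible across machines.  Counts are
    per-source occurrence counts.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if mode == "ppi_random":
        observed = enumerate_all(net, k).topology_counts()
        replicates = [
            enumerate_all(rewire(net, swaps_per_edge, seed=seed + r), k).topology_counts()
            for r in range(R)
        ]
    elif mode == "gi_random":
        if gi is None:
            raise ValueError("gi_random mode needs a GI network")
        # the PPI is fixed in this mode, so the census is enumerated once
        occ = enumerate_all(net, k)
        observed = find_fnms(occ, gi, threshold, require_span).topology_counts()
        replicates = [
            find_fnms(occ, rewire(gi, swaps_per_edge, seed=seed + r),
                      threshold, require_span).topology_counts()
            for r in range(R)
        ]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    topologies = sorted(set(observed) | {t for rep in replicates for t in rep})
    rows = []
    for t in topologies:
        null = np.array([rep.get(t, 0) for rep in replicates], dtype=float)
        mean = float(null.mean())
        sd = float(null.std(ddof=1)) if R > 1 else 0.0
        obs = observed.get(t, 0)
        z = (obs - mean) / sd if sd > 0 else float("nan")
        rows.append({"graph6": t, "observed": obs, "null_mean": mean,
                     "null_sd": sd, "z": z})
    columns = ["graph6", "observed", "null_mean", "null_sd", "z"]
    return MotifCountSummary(k=k, mode=mode, R=R, seed=seed,
                             table=pd.DataFrame(rows, columns=columns))
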