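"""Transcriptional co-regulation of FNMs from an expression matrix.

A motif's co-regulation score is the mean pairwise cosine similarity of its
genes' expression profiles (log-ratio changes across conditions).  Missing
values are handled pairwise-complete: each gene pair is compared over the
conditions where both have data, and a pair needs at least two shared
conditions and nonzero profiles to be defined.  Scores are pooled across
motif sizes for the top-5% / top-1% flags (inclusive thresholds); per-k
empirical CDFs are also reported.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd

__all__ = ["cosine", "motif_coregulation", "coregulation_table"]


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity over the shared (both non-missing) condition mask.

    NaN when fewer than two shared conditions or either masked vector is all
    zeros.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    mask = ~(np.isnan(u) | np.isnan(v))
    if mask.sum() < 2:
        return float("nan")
    uu, vv = u[mask], v[mask]
    nu, nv = np.linalg.norm(uu), np.linalg.norm(vv)
    if nu == 0 or nv == 0:
        return float("nan")
    return float(np.dot(uu, vv) / (nu * nv))


def motif_coregulation(genes, expr: pd.DataFrame) -> tuple[float, int]:
    """Mean pairwise cosine over a motif's genes; (score, n_genes_with_data).

    Genes without an expression profile are excluded; the score is NaN when
    no gene pair has a defined similarity.
    """
    present = [g for g in sorted(genes) if g in expr.index]
    vals = []
    for a, b in itertools.combinations(present, 2):
        c = cosine(expr.loc[a].to_numpy(), expr.loc[b].to_numpy())
        if not math.isnan(c):
            vals.append(c)
    score = float(np.mean(vals)) if vals else float("nan")
    return score, len(present)


def coregulation_table(fnms: list[frozenset[str]], expr: pd.DataFrame,
                       quantiles: tuple[float, float] = (0.95, 0.99),
                       ks: list[int] | None = None) -> pd.DataFrame:
    """Score every FNM and flag the top quantiles of the pooled distribution.

    Returns one row per motif (motif_id, k, score, n_genes_with_data, top5,
    top1); ``.attrs["thresholds"]`` holds the empirical quantile cutoffs and
    ``.attrs["cdf_by_k"]`` the per-size empirical CDF tables.
    """
    rows = []
    for i, nodes in enumerate(fnms):
        score, n = motif_coregulation(nodes, expr)
        rows.append({"motif_id": i, "k": ks[i] if ks else len(nodes),
                     "score": score, "n_genes_with_data": n})
    df = pd.DataFrame(rows)
    defined = df["score"].dropna()
    q_lo, q_hi = quantiles
    if len(defined):
        t_lo = float(np.quantile(defined, q_lo))
        t_hi = float(np.quantile(defined, q_hi))
    else:
        t_lo = t_hi = float("nan")
    df["top5"] = df["score"] >= t_lo
    df["top1"] = df["score"] >= t_hi
    df.loc[df["score"].isna(), ["top5", "top1"]] = False

    cdfs = {}
    for k, grp in df.dropna(subset=["score"]).groupby("k"):
        s = np.sort(grp["score"].to_numpy())
        cdfs[int(k)] = pd.DataFrame({
            "score": s, "cdf": np.arange(1, len(s) + 1) / len(s),
        })
    df.attrs["thresholds"] = {q_lo: t_lo, q_hi: t_hi}
    df.attrs["cdf_by_k"] = cdfs
    return df
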