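"""Enrichment statistics for motif gene content.

Fisher's exact test (two-sided by the minimum-likelihood rule) compares
motif-level contingency tables such as suppressor-pair containment in FNMs
vs conventional PPI motifs; the Wilcoxon-Mann-Whitney test compares
per-motif fraction distributions (essential genes, complex subunits).  The
GI-matched control sampler draws non-FNM PPI motifs stratified to the
(k, gi_count) histogram of the FNMs, so enrichment cannot be explained by
GI content alone.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter

import numpy as np
from scipy import stats

from fnmotifs.fnm_filter import FNMRecord

__all__ = [
    "fisher_exact_2x2", "mann_whitney_u", "matched_control_motifs",
    "motif_gene_fractions", "suppressor_fraction",
]


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns (conditional-MLE odds ratio, p).  The two-sided p sums the
    hypergeometric probabilities of all tables at the observed margins that
    are no more likely than the observed one.  A zero margin carries no
    information: p = 1 and the odds ratio is NaN.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    if 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
        return float("nan"), 1.0
    _, p = stats.fisher_exact(t, alternative="two-sided")
    oddsratio = stats.contingency.odds_ratio(t, kind="conditional").statistic
    return float(oddsratio), float(p)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    # U for x by pairwise comparison, ties counted half
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def mann_whitney_u(x, y, exact_cutoff: int = 12) -> tuple[float, float]:
    """Wilcoxon-Mann-Whitney rank-sum test, two-sided.

    Exact p by enumeration of all group assignments when the combined sample
    size is at most ``exact_cutoff`` (correct under ties); otherwise the
    tie-corrected normal approximation with continuity correction.
    Returns (U for x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    u = _u_statistic(x, y)
    n, m = len(x), len(y)
    mu = n * m / 2.0
    if n + m <= exact_cutoff:
        pooled = np.concatenate([x, y])
        dev = abs(u - mu)
        hits = total = 0
        for idx in itertools.combinations(range(n + m), n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(idx)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u_perm - mu) >= dev - 1e-12:
                hits += 1
        return u, hits / total
    _, p = stats.mannwhitneyu(x, y, alternative="two-sided",
                              method="asymptotic", use_continuity=True)
    return u, float(p)


def matched_control_motifs(records: list[FNMRecord],
                           fnm_profile: dict[tuple[int, int], int],
                           n: int, seed: int = 0) -> list[FNMRecord]:
    """Sample non-FNM motifs matching the FNM (k, gi_count) histogram.

    Allocation across strata is proportional (largest-remainder rounding).
    Strata with too few non-FNM candidates are sampled with replacement
    (logged); strata with none are dropped and the allocation renormalized.
    """
    if not fnm_profile or sum(fnm_profile.values()) == 0:
        raise ValueError("empty FNM profile")
    pool: dict[tuple[int, int], list[FNMRecord]] = {}
    for r in records:
        if r.is_fnm:
            continue
        pool.setdefault((r.occurrence.k, r.gi_count), []).append(r)

    usable = {s: c for s, c in fnm_profile.items() if c > 0 and pool.get(s)}
    dropped = set(fnm_profile) - set(usable)
    if dropped:
        warnings.warn(f"no control candidates for strata {sorted(dropped)}; "
                      "allocation renormalized", stacklevel=2)
    if not usable:
        raise ValueError("no stratum has control candidates")

    total = sum(usable.values())
    strata = sorted(usable)
    raw = {s: n * usable[s] / total for s in strata}
    alloc = {s: int(raw[s]) for s in strata}
    short = n - sum(alloc.values())
    for s in sorted(strata, key=lambda s: (raw[s] - alloc[s], s), reverse=True)[:short]:
        alloc[s] += 1

    rng = np.random.default_rng(seed)
    sample: list[FNMRecord] = []
    for s in strata:
        candidates = pool[s]
        want = alloc[s]
        if want <= len(candidates):
            idx = rng.choice(len(candidates), size=want, replace=False)
        else:
            warnings.warn(f"stratum {s}: {want} requested but only "
                          f"{len(candidates)} candidates; sampling with "
                          "replacement", stacklevel=2)
            idx = rng.choice(len(candidates), size=want, replace=True)
        sample.extend(candidates[i] for i in idx)
    return sample


def motif_gene_fractions(motifs: list[frozenset[str]],
                         gene_property: frozenset[str]) -> np.ndarray:
    """Per-motif fraction of nodes with the property (e.g. essential genes)."""
    return np.array([
        len(nodes & gene_property) / len(nodes) for nodes in motifs
    ])


def suppressor_fraction(motifs: list[frozenset[str]],
                        pairs: frozenset[frozenset[str]]) -> float:
    """Share of motifs whose node set contains both members of >= 1 pair."""
    if not motifs:
        return 0.0
    hits = sum(
        1 for nodes in motifs
        if any(pair <= nodes for pair in pairs)
    )
    return hits / len(motifs)
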