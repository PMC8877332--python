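# Methods

## The FNM model

A graphlet occurrence is a connected induced k-node subgraph of the PPI
network together with a designated source node. Within the induced
subgraph, every node has a unique breadth-first distance from the source;
grouping nodes by distance gives ordered layers whose sizes form an integer
composition (1, c₁, …, c_L) of k. There are 2^(k−2) such compositions, and
the census enumerates each composition class by depth-first search: layer
i+1 is chosen among neighbors of the chosen layer-i nodes that touch no
earlier layer. This yields every connected induced k-subgraph through the
source exactly once, already layered — no isomorphism tests or rejection
steps are needed during enumeration. Summed over all sources, each unique
subgraph is found exactly k times (once per member), which the tests use as
a structural identity.

An occurrence is a functional network motif (FNM) when

1. genetic interactions cover at least a threshold fraction (default 50%)
   of all C(k,2) node pairs, read as the integer ceiling
   `gi_count ≥ ⌈t·C(k,2)⌉` — so k=3 needs 2 of 3 pairs, k=5 needs 5 of 10,
   k=6 needs 8 of 15; and
2. the source node has a direct GI with every node of the most distant
   layer (the "span" condition). When the composition has a single
   non-source layer this coincides with source-to-all-others.

Source–distant GI pairs count toward the same coverage budget as any other
pair (each pair counted once). GI sign does not enter the decision; signs
are carried as annotations. Both choices are the weakest readings of the
criterion and are exposed (`threshold`, `require_span`).

FNM status is source-dependent: the same node set may qualify from one
source and not another. Both views are therefore kept — per-source
occurrence counts (used for topology count summaries and z-scores) and the
deduplicated node-set view (used for clustering, the complex map,
co-regulation and enrichment).

## Input processing

- GI significance: the signed GI network keeps score-table pairs at or
  below the empirical `tail_fraction` quantile (negative) or at or above
  the `1 − tail_fraction` quantile (positive); default 0.05 per tail.
  Quantiles use linear interpolation; comparisons are inclusive. Duplicate
  measurements of a pair collapse to the score of maximal absolute value
  before quantile computation (strongest evidence). A table with all
  scores identical has no meaningful tails and is rejected.
- Intra-complex edges are removed before enumeration: a PPI edge is
  dropped when its two genes share membership in any annotated complex
  (multi-complex genes included — the conservative reading). The intent is
  to find links *between* functional units, not complex architecture.
- Hub removal: nodes of degree ≥ d_max (default 50; 25 and 100 as tested
  variants) are deleted in a single pass on pre-deletion degrees. The
  default filter order is intra-complex removal first, then the degree
  filter, so that d_max constrains the network actually searched;
  `dmax_before_intracomplex` switches the order. The GI network used for
  the FNM test is unfiltered by default (`gi_degree_filtered` switches).
- Gene identifiers are upper-cased; no alias resolution is attempted.

## Null models

Randomization uses the switching model: `⌈10·|E|⌉` attempted double-edge
swaps (u–v, x–y) → (u–x, v–y), rejecting self-loops and duplicate edges.
Degree sequences are preserved exactly; edge attributes travel with their
edge, so the GI sign multiset is conserved. The signed GI graph is rewired
as one network (per-sign-class rewiring would additionally preserve signed
degrees; the single-network variant is the default because the FNM
criterion ignores sign). Per-topology z = (observed − null mean)/null sd
over R replicates, R = 30 by default, where the null mean of total counts
is stable to well under 10% relative change between R = 15 and R = 30 on
the test fixtures. Replicate r derives its seed as `seed + r`, making runs
reproducible across machines. In `gi_random` mode the PPI census is
enumerated once and only the FNM annotation is recomputed per replicate.

## Downstream analyses

- **Clustering**: greedy agglomeration merging the pair of clusters with
  the largest absolute gene overlap first (ties: smallest id pair),
  stopping below `min_overlap` (default 2 — the weakest nontrivial overlap
  between k ≥ 3 motifs). Overlap is absolute shared-gene count, not
  Jaccard. A connected-components mode is available; the greedy default
  follows the "iteratively merge maximally overlapping" description, and
  both the metric and threshold are deliberate assumptions, flagged here
  because no canonical choice exists.
- **Complex map**: every PPI and GI edge inside an FNM is mapped through
  gene→complex. Single-complex genes become their complex node, genes in no
  complex auxiliary nodes, multi-complex genes are dropped. Repeated
  occurrences of the same gene-level edge in different FNMs each count, so
  edge weights are (FNM, edge) incidence counts. The consensus GI score per
  complex pair is (n₊ − n₋)/(n₊ + n₋) ∈ [−1, 1]; ±1 means perfectly
  coherent sign. The pipeline builds the map from non-clustered FNMs by
  default (`complex_use="all"` uses every FNM).
- **Restricted betweenness**: B(v) = Σ over unordered complex-node pairs
  (s,t) of σ_st(v)/σ_st, unweighted shortest paths, unnormalized raw sums
  (rankings are scale-invariant, so normalization is cosmetic).
  Disconnected pairs contribute zero. Comparison networks (degree-filtered
  and full PPI merged through the same complex mapping) are ranked with the
  same function and compared by WMW on the auxiliary-node distributions.
- **Co-regulation**: mean pairwise cosine similarity of log-ratio
  expression profiles over a motif's genes. Missing data is handled
  pairwise-complete (each pair compared over conditions where both have
  values; ≥ 2 shared conditions and nonzero masked vectors required);
  profiles are used as given, since cosine on expression *changes* is the
  intended measure — no centering or imputation. Top-5%/1% flags use
  inclusive thresholds at the empirical quantiles of the score distribution
  pooled across k (per-k CDFs are also emitted).
- **Enrichment**: Fisher's exact test (two-sided by the minimum-likelihood
  rule, conditional-MLE odds ratio) for suppressor-pair containment; WMW
  (exact enumeration up to combined n = 12 — correct under ties — else
  tie-corrected normal approximation with continuity correction) for
  per-motif fraction distributions. The GI-matched control samples non-FNM
  occurrences stratified to the FNM (k, gi_count) histogram by proportional
  allocation with largest-remainder rounding; exhausted strata fall back to
  sampling with replacement (logged), empty strata are renormalized away.

## Synthetic study conditions

The fixture generator builds all pipeline inputs with ground truth. The
standard study: 120 genes, Erdős–Rényi background PPI at p = 0.012, 8
complexes of 3–5 genes added as cliques (so intra-complex removal is
exercised), and 8 planted motifs — two per size k = 3..6, with GI coverage
at the threshold ceiling, half co-expressed, two bridging (one TF-tagged
and one metabolic-tagged gene), and three containing two genes from
distinct complexes (populating the complex-pair map). Background GI scores
are standard normal on 1200 random pairs; planted GI scores are placed
beyond the extremes of the background distribution, so they are significant
at any tail fraction whose capacity exceeds the planted edge count (the
generator verifies this and also re-checks every planted motif against the
FNM criteria, failing loudly on violation). Background edges inside a
planted node set are removed so the induced subgraph equals the planted
topology and the designated source's layering is deterministic. Expression
profiles of co-expressed groups share a latent condition response
(effect 2.0, noise sd 1.0, 20 conditions, 1% missing cells).

These sizes make the complete pipeline (census for k = 3..6 plus 30
randomizations in both modes) run in well under a minute, which is what the
package treats as its standard demonstration scale.

What the fixtures do *not* emulate: yeast-like degree distributions
(scale-free tails, hubs), clustering spectra, correlated GI/PPI structure,
realistic complex overlap, or biologically structured expression programs.
Passing tests therefore demonstrate algorithmic correctness and the
stated selectivity/recovery properties under controlled conditions — not
that real-data motif counts or enrichment magnitudes will match any
particular study.

## Numerical and degenerate-input choices

- Canonical topology labels are computed by exhaustive search over all k!
  vertex orderings for the lexicographically maximal upper-triangle bit
  string, encoded in graph6. Exact for k ≤ 6 (≤ 720 permutations), cached
  on the induced edge bitmask, and free of external canonical-labeling
  dependencies. The graph6 codec is the single-byte-header form (n ≤ 62),
  byte-compatible with the standard encoding.
- DFS candidate sets are iterated in sorted identifier order; all outputs
  are deterministic for a fixed input and seed.
- z-scores are flagged undefined (NaN) when the null sd is zero rather
  than forced to zero.
- Rewiring a network with fewer than two edges returns it unchanged with a
  warning; a triangle admits no valid swap and passes through unchanged.
- Motifs with fewer than two expression-profiled genes get an undefined
  co-regulation score and are excluded from quantile flags.
- Fisher tables with a zero margin return p = 1 with an undefined odds
  ratio.

## Known limitations

- Enumeration is exact and exhaustive; cost grows steeply with density and
  k. The degree filter is what keeps k = 6 tractable, mirroring its
  original motivation; there is no sampling-based approximate census.
- The greedy clustering is quadratic-to-cubic in FNM count and intended
  for the deduplicated FNM scale, not raw occurrence tables.
- Directed motifs, k > 6, identifier mapping, and SBML parsing are out of
  scope; metabolic genes are consumed as a plain list.
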