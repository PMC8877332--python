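# fnmotifs

Functional network motifs (FNMs) in protein interaction networks:
exhaustive graphlet enumeration filtered by genetic-interaction content,
with null models and the downstream analyses that make the motifs
interpretable.

## The problem

Classical network motifs are small graphlets (k = 3–6 nodes) that occur in
a network more often than expected by chance. In a protein–protein
interaction (PPI) network they appear in enormous numbers, and statistical
over-representation alone says nothing about whether any individual
occurrence is functional — which makes the selection of candidates for
follow-up experiments hard.

Genetic interactions (GIs) measure functional relationships directly: a GI
between genes *a* and *b* is a significant deviation of the *ab*Δ
double-deletion fitness from the expectation under the single deletions
(positive = less severe, negative = more severe). This package integrates
the two data types. A PPI graphlet occurrence, enumerated from a source
node with breadth-first layers whose sizes follow an integer composition of
k, is a **functional network motif** when

- GIs are present on at least 50% of all C(k,2) node pairs
  (implemented as `gi_count ≥ ⌈0.5·C(k,2)⌉`), and
- the source node has a direct GI with every node of its most distant
  layer — GIs that span the full graphlet.

Typical users are systems biologists with a PPI edge table (BioGRID-style),
a quantitative GI screen (Costanzo-style scores, top/bottom 5% significant),
complex annotations, gene lists, and an expression compendium, who want a
short, ranked list of candidate feedback and cross-talk circuits.

## What the package does

- `network_io` — read/filter PPI and GI tables (physical-interaction
  filter, score-tail thresholding into a signed GI network, intra-complex
  edge removal, hub removal at degree < d_max, default 50).
- `graphlets` — exhaustive layered DFS census of connected induced
  k-subgraphs from every source node, with canonical graph6 topology
  labels; a brute-force census serves as an independent oracle in tests.
- `fnm_filter` — the FNM decision above, per occurrence and deduplicated
  to node sets.
- `randomization` — degree-preserving edge-switching null models
  (signs ride on edges) and per-topology z-scores over R = 30 replicates.
- `motif_clustering` — greedy max-overlap agglomeration of FNMs and
  cluster statistics.
- `complex_analysis` — complexes merged to joint nodes; consensus GI
  scores (n₊ − n₋)/(n₊ + n₋) per complex pair; PPI/GI edge-overlap
  fractions; betweenness of auxiliary (non-complex) nodes restricted to
  complex-pair shortest paths; FNMs bridging two gene systems (e.g.
  transcription factors ↔ metabolic enzymes).
- `coregulation` — mean pairwise cosine similarity of expression profiles
  per motif, with top-5%/1% flags.
- `stats_enrichment` — Fisher's exact and Wilcoxon–Mann–Whitney tests and
  GI-content-matched control motif sampling.
- `synthetic_fixtures` — seeded generators of the whole input bundle with
  planted, ground-truth FNMs.
- `pipeline` / `cli` — end-to-end orchestration (`fnm run`) plus
  stage-wise subcommands.

## Worked example

Generate a synthetic study (120 genes, 8 planted FNMs among an
Erdős–Rényi background, 8 protein complexes) and run the pipeline:

```sh
fnm synth --out fixture --seed 1
# wrote fixture with 8 planted motifs to fixture

cat > config.yaml <<'YAML'
ppi_path: fixture/ppi.tsv
gi_path: fixture/gi_scores.tsv
complexes_path: fixture/complexes.tsv
essential_path: fixture/essential.txt
tf_path: fixture/tfs.txt
metabolic_path: fixture/metabolic.txt
suppressor_path: fixture/suppressors.tsv
expression_path: fixture/expression.tsv
YAML
fnm --quiet run --config config.yaml --out run1 --seed 1
```

(any field not listed keeps its default: k = 3,4,5,6, d_max = 50, GI tail
fraction 0.05, FNM threshold 0.5, R = 30). `run1/summary.json` then
contains, among others:

```
"n_occurrences_k3": 606,       # per-source PPI graphlet occurrences
"n_fnm_occurrences_k3": 41,    # ... of which pass the FNM filter
"n_fnm_unique_k3": 24,         # deduplicated to node sets
"cluster_clustered_fraction": 0.9625,
"n_bridging_groups": 2,        # TF <-> metabolic connecting FNM groups
"coreg_top5_count": 4
```

The FNM filter is strongly selective (over all k, ~0.5% of occurrences
survive, two orders of magnitude below the raw census), most FNMs
agglomerate into few gene-sharing clusters, and the planted bridging motifs
are found as two
interlinked groups. Per-stage tables (occurrence, FNM, cluster, consensus
GI, betweenness ranking, co-regulation TSVs and the complex network
GraphML) are written next to the summary.

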