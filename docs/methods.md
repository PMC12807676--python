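# Methods

## Problem and model

A *gene* here is a community of genome-mapped transcripts treated as
isoforms or sequence variants of one locus. The pipeline assumes nothing
beyond what a transcript GFF3 carries: exon structure, strand, an SO RNA
type, a source database and a description. It does not look at nucleotide
sequence, expression or homology.

The construction is pairwise-then-global. Candidate pairs are transcripts
on one chromosome whose 5′ start sites lie within a window *w* = 1000 nt
(closed bound; "start site" is strand-aware — the smallest exon start on
`+`, the largest exon end on `-`). A random forest maps each candidate
pair's six features to P(same gene); edges with probability ≥ 0.5 form a
weighted graph whose Louvain communities are the genes. The window is a
hard locality prior: pairs farther than 1 kb apart are never scored, at
training time or build time, so the classifier is only ever asked the
question it was trained on.

### Features

| feature | definition |
|---|---|
| `d_start5` | \|Δ 5′ start\| in nt |
| `d_end5exon` | \|Δ 3′-end coordinate of the 5′-most exon\| |
| `frac_overlap_5exon` | Jaccard (intersection/union, inclusive lengths) of the two 5′-most exons |
| `n_exons_overlap90` | exon pairs with reciprocal overlap strictly >90 % of both exons, matched one-to-one greedily by descending overlap |
| `same_strand` | 1 if strands agree |
| `so_sim` | inner product of the two unit SO-term embedding vectors |

All features are symmetric under argument swap and invariant under genomic
translation. Jaccard was chosen over fraction-of-shorter because the
classifier needs a symmetric measure; reciprocal (both-exon) overlap is the
standard exon-equivalence criterion. An SO type missing from the embedding
degrades to `so_sim = 0` with a warning rather than failing a build.

### Ontology term similarity

The SO is a DAG; term vectors come from node2vec-style random walks
(length 20, 10 per node, window 5, p = q = 1, dimension 64 — standard
defaults, all configurable) treating the DAG as undirected so similarity
flows both up and down is_a links. Rather than training a word2vec model,
the walk co-occurrence counts (plus +1 self-smoothing so no row is empty)
are converted to positive pointwise mutual information and factorized by
SVD — the matrix that skip-gram embeddings implicitly factorize — then the
rows are L2-normalized. This keeps the procedure a pure deterministic
function of (graph, config, seed) with no external dependency; on toy DAGs
the resulting similarity rank-correlates with graph proximity, which is all
the classifier consumes. Embeddings are cached keyed by (ontology hash,
config, seed), and models record the embedding fingerprint they were
trained with; a build with a mismatched embedding is refused.

### Classifier

`SameGenePairClassifier` wraps a 100-tree random forest (unlimited depth,
balanced class weights, fixed seed). Labels come from a reference
annotation whose transcripts carry gene ids; rows are exactly the candidate
pairs, labeled by gene-id equality. Evaluation is stratified 5-fold CV
reporting accuracy, F1, ROC AUC and average precision per fold and
averaged. Feature importances are mean decrease in Gini impurity averaged
across fold models, with the across-fold standard deviation as dispersion.

Note on importances: `d_start5` and `d_end5exon` are strongly correlated,
and Gini importance splits credit between correlated features arbitrarily
(whichever the trees happen to split on absorbs most of it). Statements
about "distance features dominating" are therefore made jointly — the
summed importance of the two distance features plus strand — not feature by
feature.

### Communities and gene records

Louvain (networkx, resolution 1.0) maximizes weighted modularity. A single
seeded pass can land in a local optimum even on 9-node graphs, so
`GeneCommunityClusterer` runs 8 restarts with seeds derived from the
configured seed and keeps the best-modularity partition (ties broken by a
canonical sorted form); runs remain bit-reproducible, and on every ≤10-node
graph in the test suite the result attains the exhaustive-enumeration
modularity maximum. Louvain communities are connected subgraphs, so the
partition always refines connected components.

Communities with ≥ 2 members become genes (matching the minimum observed
gene size); smaller communities go to a retained singleton side channel,
available for inspection and counted as their own clusters when scoring.
Strand is never a pre-filter — a community may be strand-mixed and is then
recorded as strand `mixed`.

## Identity across releases

Accessions: `RNACG<species-prefix><hash11>.<version>`, hash11 = SHA256 of
the UTF-8 string `assembly|chromosome|start|end` read as a big-endian
integer mod 10¹¹, zero-padded (the reduction rule is this package's
documented choice; collision probability between two loci ≈ 10⁻¹¹). The
species prefix is Ensembl-style and empty for human. Versions start at 1.

Release matching pairs old genes and new clusters on the same chromosome
with gene starts (minimum genomic coordinate over member exons —
strand-agnostic, since clusters can be strand-mixed) within 1 kb, resolved
one-to-one greedily by ascending start distance, ties by larger shared
member count then lexicographic old accession. Matched & unchanged genes
keep accession and version; matched & changed (member set or span differs)
keep the accession and increment the version by one; unmatched new clusters
are born via a fresh hash at version 1; unmatched old genes are retired and
logged, their accessions never reused. When an old gene splits into two
nearby clusters the greedy rule keeps the accession on the closer cluster
and births the other — a documented choice, since merge/split semantics are
otherwise underdetermined.

## Annotation voting

Members vote for their SO type and description with their source's weight;
shipped defaults are curated 3, non-curated 1, structural hits 2 (the
ordering is the constraint; magnitudes are package defaults in an editable
TSV). Structural hits vote only when they cover strictly more than 90 % of
the gene's longest member, length measured as summed exon length since the
pipeline never sees sequence. Type ties prefer the deepest (most specific)
ontology term, then lexicographic, with a tie flag; description ties prefer
higher weight, then longer text. Empty descriptions fall back to
`ncRNA gene, <chromosome>:<start>-<end>`. Winners are invariant to
rescaling all weights by a positive constant.

## Synthetic loci

The generator plants genes with a geometric isoform count (1 + Geom(0.2):
mean 6, minimum 2, mirroring the observed corpus summary), 1–5 template
exons of 80–300 nt with 100–500 nt introns, per-isoform TSS jitter of
0–300 nt (upstream extension of the 5′-most exon, so isoforms stay
overlapping), intergenic gaps of 5–50 kb, strand chosen per gene, and an
SO-type palette skewed toward lncRNA/antisense the way the real corpus is.
Source databases and descriptions are sampled so voting has material.

Noise knobs, all fractions of transcripts/genes, defaults 0.1:

* **stragglers** — TSS displaced 300–900 nt: stresses the 1 kb window
  without breaking it;
* **fragments** — isoforms missing their 5′-most exon(s) (or half of a
  single exon): stresses the overlap features; a fragment whose truncated
  start drifts >1 kb from all members becomes a singleton, which is the
  main reason noisy-benchmark ARI sits near 0.98 rather than 1;
* **close genes** — a gene planted with its start 200–2000 nt from its
  neighbor's, 70 % divergent (opposite strand, bodies extending apart, the
  canonical bidirectional-promoter arrangement) and 30 % tandem. This knob
  is what creates cross-gene candidate pairs — the negative class the
  classifier must learn. Without it the stated gap minimum (5 kb > 2×
  window) makes the training table single-class by construction, which the
  code correctly rejects as degenerate.

With all knobs at zero, the planted partition equals the connected
components of the candidate graph by construction, so exact recovery
(ARI = 1) is achievable and asserted. What a green synthetic test does
*not* establish: behavior on loci with dispersed alternative 5′ exons
(XIST-style complex splicing is a known failure mode of 5′-anchored
windows), on piRNA-like biogenesis, or at corpus scale; the generator also
emits no nucleotide sequence, so sequence-similarity confounds are
unmodeled.

## Numerical and degenerate-input choices

Coordinates are 1-based inclusive everywhere; interval length is
`end − start + 1`. The candidate window and the >90 % gates are closed and
strict respectively, as documented at each site. All randomness flows
through explicit integer seeds (numpy PCG64, scikit-learn `random_state`,
networkx Louvain seeds); repeated runs are byte-identical, which the test
suite asserts end to end. Empty inputs produce empty outputs (exit 0);
single-class training tables, cycles in the ontology, cross-assembly
merges, NaN features and fingerprint mismatches are hard errors with
distinct exit codes (2 config/input, 3 contract) rather than warnings.
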