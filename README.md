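# ncgene

Build **gene-level entries from genome-mapped ncRNA transcripts**, and keep
their identifiers stable across annotation releases.

Sequence-centric ncRNA resources store one entry per unique sequence, so a
single locus — an rRNA with thousands of length variants, a lncRNA with many
isoforms — fragments into many records, while biology (and most experiments)
work at the gene level. `ncgene` reconstructs genes from nothing more than
transcript GFF3 annotations, in two steps:

1. **Cluster transcripts into genes.** Every pair of transcripts whose 5′
   start sites lie within 1 kb on the same chromosome is scored by a random
   forest that estimates P(same gene) from six features in three classes —
   *distance* (|Δ 5′ start|, |Δ 3′ end of the 5′-most exon|), *overlap*
   (Jaccard of the 5′-most exons, number of exon pairs with reciprocal >90 %
   overlap) and *similarity* (strand agreement, and the inner product of
   node2vec-style Sequence Ontology term embeddings). The probabilities
   weight a transcript graph; Louvain communities of that graph become genes
   (communities, not connected components, so one sprawling transcript cannot
   chain distinct genes together). piRNAs are excluded up front.
2. **Carry identity across releases.** Genes get accessions
   `RNACG<species-prefix><11-digit hash>.<version>` — the hash is SHA256 of
   `assembly|chromosome|start|end` reduced mod 10¹¹. Between releases, genes
   are matched one-to-one by start-site proximity (≤ 1 kb); a matched gene
   keeps its accession, bumping the version by exactly one when its members
   or span changed. Unmatched clusters are born at version 1; unmatched old
   genes are retired, never reused.

Each gene is annotated by **weighted voting** over its members: curated
sources (HGNC/GENCODE tier) outvote bulk archives, and structural hits
(Rfam/R2DT style) count only when they cover >90 % of the gene's longest
member.

A synthetic locus generator with a planted gene partition (geometric isoform
counts, mean 6, minimum 2; TSS jitter; straggler, fragment and close-gene
noise) makes the whole pipeline testable with no downloads.

## Worked example

```bash
ncgene simulate --n-genes 200 --seed 1 --out sim/
ncgene train   --gff sim/transcripts.gff3 --obo src/ncgene/data/so_rna_mini.obo --seed 1 --out model/
ncgene build   --gff sim/transcripts.gff3 --model model/model.joblib \
               --obo src/ncgene/data/so_rna_mini.obo --seed 1 --out genes/
ncgene merge   --old genes/genes.json --new genes/genes.json --out release/
```

On this benchmark (1294 transcripts, 200 planted genes) the run prints:

```
5-fold CV: AUC 0.9999, AP 1.0000, accuracy 0.9985, F1 0.9992
built 201 genes (21 singleton communities); ARI vs planted truth 0.9807
release self-merge: 201/201 unchanged
```

AUC/AP ≈ 1 say the forest ranks same-gene pairs almost perfectly above
cross-gene pairs inside the 1 kb window; ARI 0.98 says the recovered
partition nearly coincides with the planted genes (the gap is fragment
transcripts whose truncated 5′ ends drift out of the window); the
self-merge line shows release matching is a fixed point, so no accession
or version moves when nothing changed. `model/cv_report.tsv` holds the
per-fold metrics and `model/importances.tsv` the mean decrease in Gini
impurity per feature with across-fold dispersion.

The same pipeline is available as a library:

```python
from ncgene import (LocusSimConfig, generate_locus_set, read_transcripts,
                    build_training_set, cross_validate, train_classifier,
                    build_genes, score_recovery)
```

with the pair model exposed as a scikit-learn estimator
(`SameGenePairClassifier`) and clustering as `GeneCommunityClusterer`.

## Acceptance script

`scripts/acceptance.py` re-runs the complete pipeline from scratch —
generates the standard benchmark, embeds the ontology, trains and
cross-validates the classifier, builds and annotates genes, scores recovery
against the planted truth, and performs a release self-merge — logging the
measured numbers to stderr and writing the results manifest to `--out`:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the model, parameter and simulation details.
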