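"""Synthetic transcript loci with a known planted gene partition.

The generator emulates the shape of a genome-mapped ncRNA corpus: genes
with a geometric number of isoforms (mean 6, minimum 2, matching the
summary statistics of the human gene set), isoforms sharing a 5'
neighborhood (TSS jitter) and an exon template, long intergenic gaps, and
an SO-type palette skewed toward lncRNA the way the real corpus is.

Noise knobs stress specific pipeline stages:

* ``straggler_fraction`` — isoforms whose TSS is displaced 300–900 nt,
  stressing the 1 kb candidate window without breaking it;
* ``fragment_fraction`` — isoforms missing their 5'-most exon(s),
  stressing the overlap features;
* ``close_gene_fraction`` — genes planted 200–2000 nt from their
  neighbor's start (mostly divergent, i.e. opposite strand), which is what
  produces cross-gene candidate pairs: the negative class the pair
  classifier must learn, as in a real genome's divergent-promoter and
  antisense loci.

With every noise knob at 0 the planted partition equals the connected
components of the candidate graph by construction, so noiseless recovery
is exact when the classifier and community detection behave.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .errors import ConfigError, InputError
from .genes import GeneSet

SIM_ASSEMBLY = "ASM_SIM_1"

#: (SO accession, sampling probability): skew mirrors the corpus (lncRNA-dominated).
DEFAULT_SO_PALETTE = (
    ("SO:0001877", 0.55),  # lnc_RNA
    ("SO:0002182", 0.16),  # antisense_lncRNA
    ("SO:0001244", 0.08),  # pre_miRNA
    ("SO:0000275", 0.05),  # snoRNA
    ("SO:0000253", 0.05),  # tRNA
    ("SO:0000650", 0.04),  # small_subunit_rRNA
    ("SO:0000276", 0.04),  # miRNA
    ("SO:0000590", 0.03),  # SRP_RNA
)

CURATED_SOURCES = ("ENSEMBL_GENCODE", "HGNC")
UNCURATED_SOURCES = ("ENA", "NONCODE", "LNCIPEDIA")


@dataclass
class LocusSimConfig:
    n_genes: int = 10
    isoform_geom_p: float = 0.2  # isoforms = 1 + Geometric(p): mean 6, minimum 2
    gap_min: int = 5_000
    gap_max: int = 50_000
    tss_jitter_max: int = 300
    exon_count_min: int = 1
    exon_count_max: int = 5
    exon_len_min: int = 80
    exon_len_max: int = 300
    intron_len_min: int = 100
    intron_len_max: int = 500
    exon_keep_prob: float = 0.8
    strand_flip_prob: float = 0.5
    so_palette: tuple = DEFAULT_SO_PALETTE
    curated_prob: float = 0.3
    empty_description_prob: float = 0.2
    n_chromosomes: int = 4
    candidate_window: int = 1000
    # noise knobs
    straggler_fraction: float = 0.1
    straggler_jitter: tuple[int, int] = (300, 900)
    fragment_fraction: float = 0.1
    close_gene_fraction: float = 0.1
    close_offset: tuple[int, int] = (200, 2000)
    divergent_prob: float = 0.7

    def __post_init__(self):
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.gap_min <= 2 * self.candidate_window:
            raise ConfigError(
                f"intergenic gap minimum ({self.gap_min}) must exceed twice the candidate "
                f"window ({self.candidate_window}); planted genes would not be separable"
            )
        for frac in (self.straggler_fraction, self.fragment_fraction, self.close_gene_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("noise fractions must lie in [0, 1]")
        total = sum(p for _, p in self.so_palette)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"SO palette probabilities must sum to 1, got {total}")

    def noiseless(self) -> "LocusSimConfig":
        """Copy with every noise knob at zero."""
        from dataclasses import replace

        return replace(self, straggler_fraction=0.0, fragment_fraction=0.0, close_gene_fraction=0.0)


@dataclass
class TruthTable:
    """Planted gene membership plus per-gene type and span."""

    assignments: dict[str, str]  # transcript_id -> planted gene id
    gene_types: dict[str, str] = field(default_factory=dict)
    gene_spans: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def to_tsv(self) -> str:
        lines = ["transcript_id\tgene_id\tgene_type"]
        for tid in sorted(self.assignments):
            gid = self.assignments[tid]
            lines.append(f"{tid}\t{gid}\t{self.gene_types.get(gid, '')}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, source: str | Path) -> "TruthTable":
        assignments, gene_types = {}, {}
        for line in Path(source).read_text().splitlines()[1:]:
            tid, gid, gtype = line.split("\t")
            assignments[tid] = gid
            if gtype:
                gene_types[gid] = gtype
        return cls(assignments=assignments, gene_types=gene_types)


def _esc(value: str) -> str:
    return value.replace("%", "%25").replace(";", "%3B").replace("=", "%3D")


def generate_locus_set(config: LocusSimConfig | None = None, seed: int = 0) -> tuple[str, TruthTable]:
    """Generate a GFF3 text plus its truth table; deterministic for a seed."""
    config = config or LocusSimConfig()
    rng = np.random.Generator(np.random.PCG64(seed))
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    cursor = {c: 20_000 for c in chroms}
    prev_gene: dict[str, tuple[int, str]] = {}  # chrom -> (tss, strand)

    buf = io.StringIO()
    buf.write("##gff-version 3\n")
    truth = TruthTable(assignments={})
    type_names = {acc: acc for acc, _ in config.so_palette}
    palette_types = [acc for acc, _ in config.so_palette]
    palette_probs = [p for _, p in config.so_palette]
    tid_counter = 0

    for gi in range(config.n_genes):
        chrom = chroms[gi % len(chroms)]
        gene_id = f"G{gi:05d}"
        so_type = palette_types[rng.choice(len(palette_types), p=palette_probs)]
        strand = "-" if rng.random() < config.strand_flip_prob else "+"
        n_iso = 1 + int(rng.geometric(config.isoform_geom_p))

        n_ex = int(rng.integers(config.exon_count_min, config.exon_count_max + 1))
        exon_lens = rng.integers(config.exon_len_min, config.exon_len_max + 1, size=n_ex)
        intron_lens = rng.integers(config.intron_len_min, config.intron_len_max + 1, size=max(0, n_ex - 1))
        body_len = int(exon_lens.sum() + intron_lens.sum())

        close = gi > 0 and chrom in prev_gene and rng.random() < config.close_gene_fraction
        if close:
            prev_tss, prev_strand = prev_gene[chrom]
            offset = int(rng.integers(config.close_offset[0], config.close_offset[1] + 1))
            if rng.random() < config.divergent_prob:
                # divergent neighbor: opposite strand, body extending away
                strand = "-" if prev_strand == "+" else "+"
                tss = prev_tss - offset if prev_strand == "+" else prev_tss + offset
            else:
                strand = prev_strand
                tss = prev_tss + offset if strand == "+" else prev_tss - offset
            left_anchor = tss if strand == "+" else tss - body_len + 1
            left_anchor = max(left_anchor, 1000)
        else:
            gap = int(rng.integers(config.gap_min, config.gap_max + 1))
            left_anchor = cursor[chrom] + gap
            tss = left_anchor if strand == "+" else left_anchor + body_len - 1

        # physical exon layout, left to right; genome order is 5'->3' on '+',
        # reversed on '-'
        lens_genomic = exon_lens if strand == "+" else exon_lens[::-1]
        introns_genomic = intron_lens if strand == "+" else intron_lens[::-1]
        template: list[tuple[int, int]] = []
        pos = left_anchor
        for i, L in enumerate(lens_genomic):
            template.append((pos, pos + int(L) - 1))
            pos += int(L)
            if i < len(introns_genomic):
                pos += int(introns_genomic[i])

        gene_min, gene_max = template[0][0], template[-1][1]
        truth.gene_types[gene_id] = type_names[so_type]
        truth.gene_spans[gene_id] = (chrom, gene_min, gene_max)

        for _iso in range(n_iso):
            tid = f"URSSYN{tid_counter:08d}"
            tid_counter += 1
            straggler = rng.random() < config.straggler_fraction
            fragment = (not straggler) and rng.random() < config.fragment_fraction
            exons = list(template)
            # drop internal/3' exons, never the 5'-most
            if len(exons) > 1:
                keep = [rng.random() < config.exon_keep_prob for _ in exons]
                if strand == "+":
                    keep[0] = True
                else:
                    keep[-1] = True
                exons = [e for e, k in zip(exons, keep) if k]
            if fragment:
                if len(exons) > 1:
                    k = int(rng.integers(1, len(exons)))
                    exons = exons[k:] if strand == "+" else exons[:-k]
                else:
                    s, e = exons[0]
                    half = (e - s + 1) // 2
                    exons = [(s + half, e)] if strand == "+" else [(s, e - half)]
            else:
                if straggler:
                    jitter = int(rng.integers(config.straggler_jitter[0], config.straggler_jitter[1] + 1))
                else:
                    jitter = int(rng.integers(0, config.tss_jitter_max + 1))
                if strand == "+":
                    s, e = exons[0]
                    exons[0] = (max(1, s - jitter), e)
                else:
                    s, e = exons[-1]
                    exons[-1] = (s, e + jitter)

            if rng.random() < config.curated_prob:
                source_db = CURATED_SOURCES[int(rng.integers(len(CURATED_SOURCES)))]
            else:
                source_db = UNCURATED_SOURCES[int(rng.integers(len(UNCURATED_SOURCES)))]
            if rng.random() < config.empty_description_prob:
                description = ""
            else:
                description = f"synthetic {type_names[so_type]} locus {gene_id}"

            t_start, t_end = exons[0][0], exons[-1][1]
            attrs = (
                f"ID={tid};type={so_type};source_db={source_db};"
                f"description={_esc(description)};gene_id={gene_id};assembly_id={SIM_ASSEMBLY}"
            )
            buf.write(f"{chrom}\tncgene_sim\ttranscript\t{t_start}\t{t_end}\t.\t{strand}\t.\t{attrs}\n")
            for s, e in exons:
                buf.write(f"{chrom}\tncgene_sim\tnoncoding_exon\t{s}\t{e}\t.\t{strand}\t.\tParent={tid}\n")
            truth.assignments[tid] = gene_id

        cursor[chrom] = max(cursor[chrom], gene_max)
        prev_gene[chrom] = (tss, strand)

    return buf.getvalue(), truth


def score_recovery(truth: TruthTable, genes: GeneSet) -> tuple[float, pd.DataFrame]:
    """Adjusted Rand index between planted and recovered partitions.

    Side-channel singleton communities count as their own one-member
    clusters.  Also reports per planted gene the precision/recall of its
    best-matching recovered cluster.
    """
    recovered: dict[str, str] = {}
    for i, g in enumerate(genes.genes):
        label = str(g.accession) if g.accession is not None else f"cluster_{i}"
        for m in g.members:
            recovered[m.transcript_id] = label
    for j, group in enumerate(genes.singletons):
        for tid in group:
            recovered[tid] = f"singleton_{j}"

    if set(recovered) != set(truth.assignments):
        missing = set(truth.assignments) - set(recovered)
        extra = set(recovered) - set(truth.assignments)
        raise InputError(
            f"transcript id sets disagree (missing from recovery: {sorted(missing)[:3]}, "
            f"unexpected: {sorted(extra)[:3]})"
        )

    ids = sorted(truth.assignments)
    ari = float(adjusted_rand_score([truth.assignments[t] for t in ids], [recovered[t] for t in ids]))

    members_of_planted: dict[str, set[str]] = {}
    for tid, gid in truth.assignments.items():
        members_of_planted.setdefault(gid, set()).add(tid)
    members_of_recovered: dict[str, set[str]] = {}
    for tid, label in recovered.items():
        members_of_recovered.setdefault(label, set()).add(tid)

    rows = []
    for gid, planted in sorted(members_of_planted.items()):
        best_label, best_inter = "", 0
        for label in {recovered[t] for t in planted}:
            inter = len(planted & members_of_recovered[label])
            if inter > best_inter:
                best_label, best_inter = label, inter
        rows.append(
            {
                "planted_gene": gid,
                "best_cluster": best_label,
                "precision": best_inter / len(members_of_recovered[best_label]) if best_label else 0.0,
                "recall": best_inter / len(planted),
            }
        )
    return ari, pd.DataFrame(rows)
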