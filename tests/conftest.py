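"""Shared fixtures: the mini ontology, its embedding, and the standard
synthetic benchmark (200 planted genes, default noise, seed 42) reused by
model, clustering and acceptance tests."""

from __future__ import annotations

import io
from importlib import resources

import pytest

from ncgene.features import build_candidate_table
from ncgene.gff_io import ExonInterval, FilterConfig, TranscriptRecord, TranscriptSet, read_transcripts
from ncgene.model import build_training_set, cross_validate, train_classifier
from ncgene.ontology import EmbedConfig, embed_terms, load_ontology
from ncgene.simulate import LocusSimConfig, generate_locus_set

MINI_OBO = str(resources.files("ncgene.data").joinpath("so_rna_mini.obo"))

BENCHMARK_SEED = 42
BENCHMARK_GENES = 200


def make_transcript(
    tid: str,
    exons: list[tuple[int, int]],
    strand: str = "+",
    chromosome: str = "chr1",
    so_type: str = "SO:0001877",
    assembly: str = "ASM_T",
    gene_id: str | None = None,
    source_db: str = "ENA",
    description: str = "",
) -> TranscriptRecord:
    return TranscriptRecord(
        transcript_id=tid,
        chromosome=chromosome,
        assembly_id=assembly,
        strand=strand,
        exons=tuple(ExonInterval(s, e) for s, e in exons),
        so_type=so_type,
        source_db=source_db,
        description=description,
        gene_id=gene_id,
    )


def make_set(transcripts, assembly: str = "ASM_T") -> TranscriptSet:
    return TranscriptSet(assembly_id=assembly, transcripts=list(transcripts))


@pytest.fixture(scope="session")
def mini_onto():
    return load_ontology(MINI_OBO)


@pytest.fixture(scope="session")
def mini_emb(mini_onto):
    return embed_terms(mini_onto, EmbedConfig(), seed=BENCHMARK_SEED)


@pytest.fixture(scope="session")
def benchmark(mini_onto, mini_emb):
    """The standard noisy benchmark plus everything trained on it."""
    config = LocusSimConfig(n_genes=BENCHMARK_GENES)
    gff, truth = generate_locus_set(config, seed=BENCHMARK_SEED)
    ts = read_transcripts(io.StringIO(gff), FilterConfig(ontology=mini_onto))
    table = build_training_set(ts, mini_emb)
    cv = cross_validate(table, k=5, seed=BENCHMARK_SEED)
    model = train_classifier(table, seed=BENCHMARK_SEED, embedding_fingerprint=mini_emb.fingerprint())
    return {
        "config": config,
        "gff": gff,
        "truth": truth,
        "ts": ts,
        "table": table,
        "cv": cv,
        "model": model,
        "pairs": build_candidate_table(ts, mini_emb),
    }
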