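"""Gene-level RNA type and description by weighted voting over members.

Each member transcript votes for its SO type and description with the
weight of its source database; curated resources (HGNC, FlyBase, GENCODE
tier) outweigh bulk archives (ENA tier).  Structural-annotation hits
(Rfam-family / R2DT-template style) vote for their implied type only when
they cover more than 90% of the gene's longest member sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import ConfigError, InputError
from .genes import GeneRecord
from .gff_io import TranscriptRecord
from .ontology import OntologyGraph

DEFAULT_CURATED_WEIGHT = 3.0
DEFAULT_UNCURATED_WEIGHT = 1.0
DEFAULT_STRUCTURAL_WEIGHT = 2.0
DEFAULT_COVERAGE_GATE = 0.9  # "over 90%": strictly greater than


@dataclass
class SourceWeightTable:
    """source_db -> voting weight, plus curated flags and the structural weight."""

    weights: dict[str, float] = field(default_factory=dict)
    curated: frozenset[str] = frozenset()
    structural_weight: float = DEFAULT_STRUCTURAL_WEIGHT
    default_weight: float = DEFAULT_UNCURATED_WEIGHT

    def __post_init__(self):
        bad = {k: w for k, w in self.weights.items() if w <= 0}
        if bad or self.structural_weight <= 0 or self.default_weight <= 0:
            raise ConfigError(f"all voting weights must be positive; offending: {bad}")

    def weight(self, source_db: str) -> float:
        return self.weights.get(source_db, self.default_weight)

    @classmethod
    def from_tsv(cls, source: str | Path, **kwargs) -> "SourceWeightTable":
        weights, curated = {}, set()
        for line in Path(source).read_text().splitlines():
            if line.startswith("#") or not line.strip() or line.startswith("source_db\t"):
                continue
            name, w, flag = line.rstrip("\n").split("\t")
            weights[name] = float(w)
            if flag == "1":
                curated.add(name)
        return cls(weights=weights, curated=frozenset(curated), **kwargs)

    @classmethod
    def default(cls) -> "SourceWeightTable":
        with resources.as_file(resources.files("ncgene.data").joinpath("source_weights.tsv")) as p:
            return cls.from_tsv(p)


@dataclass(frozen=True)
class StructuralHit:
    """One Rfam/R2DT-style hit against a gene's member transcript."""

    transcript_id: str
    family_id: str
    covered_fraction: float
    implied_so_type: str

    def __post_init__(self):
        if not 0.0 <= self.covered_fraction <= 1.0:
            raise ConfigError(f"covered_fraction must lie in [0, 1], got {self.covered_fraction}")


@dataclass
class AnnotationVote:
    winner: str
    tally: dict[str, float]
    tie: bool


def _pick_winner(
    tally: dict[str, float], ontology: OntologyGraph | None
) -> tuple[str, bool]:
    best = max(tally.values())
    leaders = sorted(t for t, w in tally.items() if abs(w - best) < 1e-12)
    if len(leaders) == 1:
        return leaders[0], False
    if ontology is not None:
        # most specific term (greatest depth) wins; lexicographic as last resort
        leaders.sort(key=lambda t: (-ontology.depth(t), t))
    return leaders[0], True


def vote_type(
    cluster: GeneRecord,
    members: list[TranscriptRecord],
    hits: list[StructuralHit] | None = None,
    weights: SourceWeightTable | None = None,
    coverage_gate: float = DEFAULT_COVERAGE_GATE,
    ontology: OntologyGraph | None = None,
) -> AnnotationVote:
    """Weighted vote for the gene's SO type.

    Members contribute their source weight to their SO type; structural
    hits contribute the structural weight iff covered_fraction strictly
    exceeds the gate (coverage measured against the gene's longest member
    by summed exon length).  Ties prefer the most specific ontology term.
    """
    if not members:
        raise InputError("cannot vote on an empty cluster")
    weights = weights or SourceWeightTable.default()
    tally: dict[str, float] = {}
    for m in members:
        if m.so_type:
            tally[m.so_type] = tally.get(m.so_type, 0.0) + weights.weight(m.source_db)
    for h in hits or []:
        if h.covered_fraction > coverage_gate and h.implied_so_type:
            tally[h.implied_so_type] = tally.get(h.implied_so_type, 0.0) + weights.structural_weight
    if not tally:
        return AnnotationVote(winner="", tally={}, tie=False)
    winner, tie = _pick_winner(tally, ontology)
    return AnnotationVote(winner=winner, tally=tally, tie=tie)


def vote_description(
    cluster: GeneRecord,
    members: list[TranscriptRecord],
    weights: SourceWeightTable | None = None,
) -> str:
    """Highest-weight non-empty member description; coordinate fallback.

    Ties go to the longest description, then lexicographic, so the choice
    is deterministic regardless of member order.
    """
    if not members:
        raise InputError("cannot vote on an empty cluster")
    weights = weights or SourceWeightTable.default()
    candidates = [
        (weights.weight(m.source_db), len(m.description), m.description)
        for m in members
        if m.description
    ]
    if not candidates:
        return f"ncRNA gene, {cluster.chromosome}:{cluster.start}-{cluster.end}"
    candidates.sort(key=lambda c: (-c[0], -c[1], c[2]))
    return candidates[0][2]


def annotate_genes(
    geneset,
    transcripts: dict[str, TranscriptRecord],
    hits_by_transcript: dict[str, list[StructuralHit]] | None = None,
    weights: SourceWeightTable | None = None,
    coverage_gate: float = DEFAULT_COVERAGE_GATE,
    ontology: OntologyGraph | None = None,
) -> None:
    """Vote a type and description onto every gene of a GeneSet, in place."""
    weights = weights or SourceWeightTable.default()
    hits_by_transcript = hits_by_transcript or {}
    for gene in geneset.genes:
        members = [transcripts[m.transcript_id] for m in gene.members]
        hits = [h for m in gene.members for h in hits_by_transcript.get(m.transcript_id, [])]
        vote = vote_type(gene, members, hits, weights, coverage_gate, ontology)
        gene.so_type = vote.winner or gene.so_type
        gene.description = vote_description(gene, members, weights)
        gene.vote = {"tally": vote.tally, "tie": vote.tie}
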