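"""GFF3 input/output for transcript models and predicted genes.

The pipeline is GFF-only: everything it consumes is representable as a
transcript feature with exon children (``ID``/``Parent`` linkage), and
everything it produces is written back as ``predicted_gene`` features with
their member transcripts as children.  Coordinates are GFF3-standard
1-based inclusive throughout the package; no other convention appears
anywhere past this module.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Sequence

import gffutils

from .errors import GFFParseError, LinkageError, ValidationError

log = logging.getLogger(__name__)

#: GFF3 column-3 feature types treated as transcript-level records.
TRANSCRIPT_FEATURE_TYPES = frozenset({"transcript", "noncoding_transcript"})
#: Feature types treated as exon children of a transcript.
EXON_FEATURE_TYPES = frozenset({"exon", "noncoding_exon"})
#: Feature type used for gene-level output records.
GENE_FEATURE_TYPE = "predicted_gene"

#: SO accession of piRNA; excluded from gene building by default.
PIRNA_SO = "SO:0001035"


@dataclass(frozen=True, order=True)
class ExonInterval:
    """One exon, 1-based inclusive genomic coordinates."""

    start: int
    end: int

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValidationError(f"invalid exon interval [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap(self, other: "ExonInterval") -> int:
        """Number of shared bases with *other* (0 if disjoint)."""
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass
class TranscriptRecord:
    """One genome-mapped transcript with its exon structure and metadata."""

    transcript_id: str
    chromosome: str
    assembly_id: str
    strand: str
    exons: tuple[ExonInterval, ...]
    so_type: str
    source_db: str = ""
    description: str = ""
    curated_source: bool = False
    gene_id: str | None = None  # reference gene membership, training inputs only

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}")
        exons = tuple(sorted(self.exons))
        if not exons:
            raise ValidationError(f"{self.transcript_id}: transcript has no exons")
        for prev, cur in zip(exons, exons[1:]):
            if cur.start <= prev.end:
                raise ValidationError(
                    f"{self.transcript_id}: exons overlap ([{prev.start},{prev.end}] vs [{cur.start},{cur.end}])"
                )
        self.exons = exons

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def exonic_length(self) -> int:
        """Summed exon length; the proxy for sequence length in a GFF-only pipeline."""
        return sum(e.length for e in self.exons)


@dataclass
class TranscriptSet:
    """All retained transcripts of one assembly, with read provenance."""

    assembly_id: str
    transcripts: list[TranscriptRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        seen: set[str] = set()
        for t in self.transcripts:
            if t.assembly_id != self.assembly_id:
                raise ValidationError(
                    f"{t.transcript_id}: assembly {t.assembly_id!r} != set assembly {self.assembly_id!r}"
                )
            if t.transcript_id in seen:
                raise ValidationError(f"duplicate transcript id {t.transcript_id!r}")
            seen.add(t.transcript_id)

    def __len__(self) -> int:
        return len(self.transcripts)

    def by_id(self) -> dict[str, TranscriptRecord]:
        return {t.transcript_id: t for t in self.transcripts}


@dataclass
class FilterConfig:
    """Which SO types to drop at read time.

    ``excluded_so_types`` are matched literally; when an ontology is supplied
    the exclusion extends to every descendant term, because source databases
    frequently annotate with piRNA subtypes rather than the parent accession.
    """

    excluded_so_types: frozenset[str] = frozenset({PIRNA_SO})
    ontology: "object | None" = None  # ncgene.ontology.OntologyGraph, optional

    def effective_exclusions(self) -> frozenset[str]:
        if self.ontology is None:
            return frozenset(self.excluded_so_types)
        terms: set[str] = set()
        for t in self.excluded_so_types:
            terms.add(t)
            terms.update(self.ontology.descendants(t))
        return frozenset(terms)


def default_curated_sources() -> frozenset[str]:
    """Source databases flagged curated in the shipped weight table."""
    text = resources.files("ncgene.data").joinpath("source_weights.tsv").read_text()
    curated = set()
    for line in text.splitlines():
        if line.startswith("#") or not line.strip() or line.startswith("source_db\t"):
            continue
        name, _weight, flag = line.rstrip("\n").split("\t")
        if flag == "1":
            curated.add(name)
    return frozenset(curated)


def _read_text(source: str | Path | IO[str]) -> str:
    if isinstance(source, (str, Path)):
        return Path(source).read_text()
    return source.read()


def _prevalidate(text: str) -> None:
    """Cheap structural pass so parse errors carry a line number."""
    for i, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise GFFParseError(f"expected 9 tab-separated columns, found {len(cols)}", i)
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError:
            raise GFFParseError(f"coordinates are not integers: {cols[3]!r}, {cols[4]!r}", i) from None
        if start < 1 or end < start:
            raise GFFParseError(f"invalid coordinate range {start}..{end}", i)
        if cols[6] not in ("+", "-", ".", "?"):
            raise GFFParseError(f"invalid strand {cols[6]!r}", i)


def _attr(feature, key: str, default: str = "") -> str:
    vals = feature.attributes.get(key, [])
    return vals[0] if vals else default


def read_transcripts(
    source: str | Path | IO[str],
    filters: FilterConfig | None = None,
    assembly_id: str | None = None,
    curated_sources: Iterable[str] | None = None,
) -> TranscriptSet:
    """Parse transcript + exon features from GFF3 into a :class:`TranscriptSet`.

    Transcript features carry ``ID`` and optionally ``type`` (SO accession),
    ``source_db``, ``description``, ``assembly_id`` and ``gene_id`` attributes;
    exon children carry ``Parent``.  Transcripts without exon children get a
    single exon equal to their own span.  Transcripts whose SO type is in the
    exclusion set (piRNA and, given an ontology, its descendants, by default)
    are dropped and counted in the provenance log.
    """
    filters = filters if filters is not None else FilterConfig()
    curated = frozenset(curated_sources) if curated_sources is not None else default_curated_sources()
    text = _read_text(source)
    _prevalidate(text)
    has_features = any(l.strip() and not l.startswith("#") for l in text.splitlines())

    transcripts_raw: dict[str, gffutils.Feature] = {}
    exon_children: dict[str, list[gffutils.Feature]] = {}
    db_features = (
        gffutils.create_db(
            text, ":memory:", from_string=True, keep_order=True, merge_strategy="create_unique"
        ).all_features()
        if has_features
        else ()
    )
    for feat in db_features:
        if feat.featuretype in TRANSCRIPT_FEATURE_TYPES:
            tid = _attr(feat, "ID") or feat.id
            transcripts_raw[tid] = feat
        elif feat.featuretype in EXON_FEATURE_TYPES:
            parents = feat.attributes.get("Parent", [])
            if not parents:
                raise LinkageError(f"exon at {feat.seqid}:{feat.start}-{feat.end} has no Parent attribute")
            for p in parents:
                exon_children.setdefault(p, []).append(feat)

    for parent_id in exon_children:
        if parent_id not in transcripts_raw:
            raise LinkageError(f"exon Parent {parent_id!r} does not match any transcript ID")

    excluded_terms = filters.effective_exclusions()
    records: list[TranscriptRecord] = []
    excluded = 0
    unplaced = 0
    assemblies: set[str] = set()
    for tid, feat in transcripts_raw.items():
        if feat.seqid in (".", ""):
            unplaced += 1  # cannot be placed on a genome: rejected
            continue
        so_type = _attr(feat, "type")
        if so_type in excluded_terms:
            excluded += 1
            continue
        exon_feats = exon_children.get(tid, [])
        for e in exon_feats:
            if e.seqid != feat.seqid:
                raise ValidationError(
                    f"transcript {tid!r} spans multiple chromosomes ({feat.seqid} vs {e.seqid})"
                )
        if exon_feats:
            exons = tuple(sorted(ExonInterval(e.start, e.end) for e in exon_feats))
        else:
            exons = (ExonInterval(feat.start, feat.end),)
        asm = _attr(feat, "assembly_id") or (assembly_id or "")
        source_db = _attr(feat, "source_db") or feat.source
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                chromosome=feat.seqid,
                assembly_id=asm,
                strand=feat.strand,
                exons=exons,
                so_type=so_type,
                source_db=source_db,
                description=_attr(feat, "description"),
                curated_source=source_db in curated,
                gene_id=_attr(feat, "gene_id") or None,
            )
        )

    if assembly_id is None:
        assemblies = {r.assembly_id for r in records}
        if len(assemblies) > 1:
            raise ValidationError(f"transcripts span multiple assemblies: {sorted(assemblies)}")
        assembly_id = next(iter(assemblies)) if assemblies else ""

    provenance = {
        "source": str(source) if isinstance(source, (str, Path)) else "<stream>",
        "n_read": len(transcripts_raw),
        "n_retained": len(records),
        "n_excluded_by_type": excluded,
        "n_unplaced": unplaced,
        "excluded_so_types": sorted(excluded_terms),
    }
    log.info("read %d transcripts, retained %d (excluded by type: %d)", len(transcripts_raw), len(records), excluded)
    return TranscriptSet(assembly_id=assembly_id, transcripts=records, provenance=provenance)


# -- gene-level output -------------------------------------------------------


def _esc(value: str) -> str:
    return value.replace("%", "%25").replace(";", "%3B").replace("=", "%3D").replace("\t", "%09")


def write_genes_gff(genes, sink: str | Path | IO[str]) -> int:
    """Write a GeneSet as ``predicted_gene`` features with transcript children.

    Returns the number of gene records written.  The output round-trips
    through :func:`read_genes_gff`.
    """
    from .genes import GeneSet  # local import: genes.py imports this module

    assert isinstance(genes, GeneSet)
    buf = io.StringIO()
    buf.write("##gff-version 3\n")
    n = 0
    for gene in genes.genes:
        if gene.accession is None:
            raise ValidationError(f"gene on {gene.chromosome}:{gene.start}-{gene.end} has no accession")
        gid = str(gene.accession)
        attrs = [
            f"ID={_esc(gid)}",
            f"type={_esc(gene.so_type or '')}",
            f"assembly_id={_esc(gene.assembly_id)}",
            f"description={_esc(gene.description or '')}",
        ]
        buf.write(
            f"{gene.chromosome}\tncgene\t{GENE_FEATURE_TYPE}\t{gene.start}\t{gene.end}\t.\t"
            f"{gene.strand if gene.strand in '+-' else '.'}\t.\t{';'.join(attrs)}\n"
        )
        for m in gene.members:
            mattrs = f"ID={_esc(m.transcript_id)};Parent={_esc(gid)};type={_esc(m.so_type)}"
            buf.write(
                f"{gene.chromosome}\tncgene\ttranscript\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t{mattrs}\n"
            )
        n += 1
    text = buf.getvalue()
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text)
    else:
        sink.write(text)
    return n


def read_genes_gff(source: str | Path | IO[str]):
    """Parse ``predicted_gene`` records (the writer's output) back to a GeneSet."""
    from .genes import GeneMember, GeneRecord, GeneSet
    from .identity import GeneAccession

    text = _read_text(source)
    _prevalidate(text)
    genes: dict[str, GeneRecord] = {}
    order: list[str] = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        attrs = {}
        for part in cols[8].split(";"):
            if "=" in part:
                k, v = part.split("=", 1)
                attrs[k] = v.replace("%3B", ";").replace("%3D", "=").replace("%09", "\t").replace("%25", "%")
        if cols[2] == GENE_FEATURE_TYPE:
            gid = attrs["ID"]
            genes[gid] = GeneRecord(
                accession=GeneAccession.parse(gid),
                chromosome=cols[0],
                assembly_id=attrs.get("assembly_id", ""),
                start=int(cols[3]),
                end=int(cols[4]),
                strand=cols[6] if cols[6] in "+-" else "mixed",
                members=[],
                so_type=attrs.get("type", ""),
                description=attrs.get("description", ""),
            )
            order.append(gid)
        elif cols[2] == "transcript" and "Parent" in attrs:
            parent = attrs["Parent"]
            if parent not in genes:
                raise LinkageError(f"transcript Parent {parent!r} does not match any predicted_gene ID")
            genes[parent].members.append(
                GeneMember(
                    transcript_id=attrs["ID"],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand=cols[6],
                    so_type=attrs.get("type", ""),
                )
            )
    recs = [genes[g] for g in order]
    assembly = recs[0].assembly_id if recs else ""
    return GeneSet(assembly_id=assembly, genes=recs)
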