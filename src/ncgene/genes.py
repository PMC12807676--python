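"""Gene-level containers: clusters of transcripts with accession, type and span.

A *gene* here is a community of genome-mapped transcripts treated as
isoforms/variants of one locus.  :class:`GeneRecord` is the versioned,
annotated form; upstream clustering produces bare records (no accession)
which identity assignment then stamps.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import IO

from .errors import ValidationError


@dataclass
class GeneMember:
    """Minimal per-member transcript info a gene record keeps."""

    transcript_id: str
    start: int
    end: int
    strand: str
    so_type: str = ""


@dataclass
class GeneRecord:
    """One gene: member transcripts, span, annotation and (optionally) identity.

    ``start``/``end`` is the genomic span covering all member exons;
    ``start5`` is the minimum genomic coordinate over members' 5' starts and
    is what release matching anchors on (strand-agnostic, since merged
    clusters can be strand-mixed).
    """

    chromosome: str
    assembly_id: str
    start: int
    end: int
    strand: str  # '+', '-' or 'mixed'
    members: list[GeneMember]
    accession: "object | None" = None  # ncgene.identity.GeneAccession
    so_type: str = ""
    description: str = ""
    start5: int | None = None
    vote: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.start5 is None:
            self.start5 = self.start

    @property
    def member_ids(self) -> frozenset[str]:
        return frozenset(m.transcript_id for m in self.members)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class GeneSet:
    """All genes built for one assembly, plus run provenance.

    ``singletons`` is the side channel: communities below the minimum gene
    size are retained for inspection but never emitted as genes.
    """

    assembly_id: str
    genes: list[GeneRecord]
    singletons: list[list[str]] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def by_accession(self) -> dict[str, GeneRecord]:
        out = {}
        for g in self.genes:
            if g.accession is None:
                raise ValidationError("gene set contains unversioned genes")
            out[g.accession.bare] = g
        return out

    # -- JSON serialization --------------------------------------------------

    def to_json(self) -> str:
        def encode(g: GeneRecord) -> dict:
            d = asdict(g)
            d["accession"] = str(g.accession) if g.accession is not None else None
            return d

        payload = {
            "assembly_id": self.assembly_id,
            "genes": [encode(g) for g in self.genes],
            "singletons": self.singletons,
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    def write_json(self, sink: str | Path | IO[str]) -> None:
        text = self.to_json()
        if isinstance(sink, (str, Path)):
            Path(sink).write_text(text)
        else:
            sink.write(text)

    @classmethod
    def from_json(cls, source: str | Path | IO[str]) -> "GeneSet":
        from .identity import GeneAccession

        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            text = Path(source).read_text()
        elif hasattr(source, "read"):
            text = source.read()
        else:
            text = str(source)
        payload = json.loads(text)
        genes = []
        for d in payload["genes"]:
            acc = GeneAccession.parse(d["accession"]) if d.get("accession") else None
            genes.append(
                GeneRecord(
                    chromosome=d["chromosome"],
                    assembly_id=d["assembly_id"],
                    start=d["start"],
                    end=d["end"],
                    strand=d["strand"],
                    members=[GeneMember(**m) for m in d["members"]],
                    accession=acc,
                    so_type=d.get("so_type", ""),
                    description=d.get("description", ""),
                    start5=d.get("start5"),
                    vote=d.get("vote", {}),
                )
            )
        return cls(
            assembly_id=payload["assembly_id"],
            genes=genes,
            singletons=payload.get("singletons", []),
            provenance=payload.get("provenance", {}),
        )
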