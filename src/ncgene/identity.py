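"""Stable gene accessions and cross-release identity.

Accessions render as ``RNACG<species-prefix><11 decimal digits>.<version>``
(no species prefix for *Homo sapiens*).  The 11 digits are the SHA256 of
the gene's coordinates, chromosome and assembly, reduced modulo 10^11.
Once minted, an accession is never recomputed: identity flows across
releases only through start-proximity matching, so a gene whose span
drifts keeps its accession and bumps its version.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field

from .errors import InputError, ValidationError
from .genes import GeneRecord, GeneSet

ACCESSION_RE = re.compile(r"^RNACG(?P<species>[A-Z]*)(?P<hash>[0-9]{11})\.(?P<version>[0-9]+)$")


@dataclass(frozen=True)
class GeneAccession:
    species_prefix: str
    hash11: str
    version: int

    def __post_init__(self):
        if not re.fullmatch(r"[A-Z]*", self.species_prefix):
            raise ValidationError(f"species prefix must be uppercase letters, got {self.species_prefix!r}")
        if not re.fullmatch(r"[0-9]{11}", self.hash11):
            raise ValidationError(f"hash must be 11 zero-padded decimal digits, got {self.hash11!r}")
        if self.version < 1:
            raise ValidationError(f"version must be a positive integer, got {self.version}")

    @property
    def bare(self) -> str:
        """The accession without its version suffix."""
        return f"RNACG{self.species_prefix}{self.hash11}"

    def __str__(self) -> str:
        return f"{self.bare}.{self.version}"

    def bumped(self) -> "GeneAccession":
        return GeneAccession(self.species_prefix, self.hash11, self.version + 1)

    @classmethod
    def parse(cls, text: str) -> "GeneAccession":
        m = ACCESSION_RE.match(text)
        if not m:
            raise ValidationError(f"{text!r} is not a valid gene accession")
        return cls(m.group("species"), m.group("hash"), int(m.group("version")))


def make_accession(cluster: GeneRecord, species_prefix: str = "") -> GeneAccession:
    """Mint a version-1 accession from the cluster's coordinates.

    hash11 = SHA256 of ``assembly_id|chromosome|start|end`` (UTF-8), the
    digest read as a big-endian integer and reduced modulo 10^11, zero-
    padded.  Collision probability between two distinct loci is ~10^-11.
    """
    if not cluster.assembly_id:
        raise ValidationError("cluster has no assembly_id; cannot mint an accession")
    canonical = f"{cluster.assembly_id}|{cluster.chromosome}|{cluster.start}|{cluster.end}"
    digest = int.from_bytes(hashlib.sha256(canonical.encode("utf-8")).digest(), "big")
    return GeneAccession(species_prefix, f"{digest % 10**11:011d}", 1)


@dataclass
class MatchedPair:
    old: GeneRecord
    new: GeneRecord
    changed: bool
    start_distance: int


@dataclass
class ReleaseMapping:
    matched: list[MatchedPair] = field(default_factory=list)
    born: list[GeneRecord] = field(default_factory=list)
    retired: list[GeneRecord] = field(default_factory=list)


def _gene_changed(old: GeneRecord, new: GeneRecord) -> bool:
    return old.member_ids != new.member_ids or old.span != new.span


def match_releases(old: GeneSet, new: list[GeneRecord], window: int = 1000) -> ReleaseMapping:
    """One-to-one correspondence between an old release's genes and new clusters.

    Candidates are same-chromosome pairs whose gene starts (minimum genomic
    coordinate of member exons) lie within *window* nt.  Greedy resolution
    by ascending start distance, ties by larger shared-member count, then by
    lexicographic old accession.  Unmatched news are born; unmatched olds
    retired.  Cross-assembly matching is refused.
    """
    new_assemblies = {g.assembly_id for g in new}
    if new_assemblies and new_assemblies != {old.assembly_id}:
        raise InputError(
            f"cannot match releases across assemblies: {old.assembly_id!r} vs {sorted(new_assemblies)}"
        )
    for g in old.genes:
        if g.accession is None:
            raise InputError("old release contains unversioned genes")

    candidates = []
    for oi, og in enumerate(old.genes):
        for ni, ng in enumerate(new):
            if og.chromosome != ng.chromosome:
                continue
            dist = abs(og.start5 - ng.start5)
            if dist <= window:
                shared = len(og.member_ids & ng.member_ids)
                candidates.append((dist, -shared, str(og.accession), ni, oi))
    candidates.sort()

    used_old: set[int] = set()
    used_new: set[int] = set()
    mapping = ReleaseMapping()
    for dist, _negshared, _acc, ni, oi in candidates:
        if oi in used_old or ni in used_new:
            continue
        used_old.add(oi)
        used_new.add(ni)
        og, ng = old.genes[oi], new[ni]
        mapping.matched.append(MatchedPair(og, ng, _gene_changed(og, ng), dist))
    mapping.retired = [g for i, g in enumerate(old.genes) if i not in used_old]
    mapping.born = [g for i, g in enumerate(new) if i not in used_new]
    return mapping


def assign_versions(
    mapping: ReleaseMapping, assembly_id: str, species_prefix: str = ""
) -> tuple[GeneSet, list[dict]]:
    """Stamp accessions/versions per the mapping and produce the release log.

    Matched & unchanged keep accession and version; matched & changed keep
    the accession and bump the version; born clusters get a freshly minted
    version-1 accession; retired accessions are logged and never reused.
    """
    genes: list[GeneRecord] = []
    log_rows: list[dict] = []
    for m in mapping.matched:
        acc = m.old.accession.bumped() if m.changed else m.old.accession
        g = m.new
        g.accession = acc
        genes.append(g)
        log_rows.append(
            {
                "accession": acc.bare,
                "status": "changed" if m.changed else "unchanged",
                "old_version": m.old.accession.version,
                "new_version": acc.version,
                "start_distance": m.start_distance,
            }
        )
    for g in mapping.born:
        g.accession = make_accession(g, species_prefix)
        genes.append(g)
        log_rows.append(
            {"accession": g.accession.bare, "status": "born", "old_version": "", "new_version": 1, "start_distance": ""}
        )
    for g in mapping.retired:
        log_rows.append(
            {
                "accession": g.accession.bare,
                "status": "retired",
                "old_version": g.accession.version,
                "new_version": "",
                "start_distance": "",
            }
        )
    genes.sort(key=lambda g: (g.chromosome, g.start, g.end))
    log_rows.sort(key=lambda r: (r["accession"], r["status"]))
    return (
        GeneSet(assembly_id=assembly_id, genes=genes, provenance={"release_log": len(log_rows)}),
        log_rows,
    )


def release_log_tsv(rows: list[dict]) -> str:
    lines = ["accession\tstatus\told_version\tnew_version\tstart_distance"]
    for r in rows:
        lines.append(
            f"{r['accession']}\t{r['status']}\t{r['old_version']}\t{r['new_version']}\t{r['start_distance']}"
        )
    return "\n".join(lines) + "\n"
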