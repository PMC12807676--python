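"""Candidate transcript pairing and the six-feature vector of the pair model.

Three classes of measures describe a transcript pair: distance (between the
5' start coordinates and between the 3' ends of the two 5'-most exons),
overlap (Jaccard fraction of the 5'-most exons and the count of exon pairs
with reciprocal >90% overlap), and similarity (strand agreement and the
ontology-embedding similarity of the two SO types).

"Start site" is the biological 5' end throughout, i.e. strand-aware: the
smallest exon start on '+', the largest exon end on '-'.  Candidate pairs
are transcripts on the same chromosome whose 5' starts lie within a 1 kb
window (inclusive); strand is never a pre-filter, only a feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np

from .errors import ConfigError
from .gff_io import TranscriptRecord, TranscriptSet
from .ontology import TermEmbedding, term_similarity

log = logging.getLogger(__name__)

#: Fixed feature order; the trained model's contract.
FEATURE_NAMES = ("d_start5", "d_end5exon", "frac_overlap_5exon", "n_exons_overlap90", "same_strand", "so_sim")

DEFAULT_WINDOW = 1000  # nt; "within 1 kb", closed bound


@dataclass(frozen=True)
class PairFeatures:
    d_start5: float
    d_end5exon: float
    frac_overlap_5exon: float
    n_exons_overlap90: float
    same_strand: float
    so_sim: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)


@dataclass(frozen=True)
class CandidatePair:
    id_a: str
    id_b: str
    features: PairFeatures

    def __post_init__(self):
        if not self.id_a < self.id_b:
            raise ValueError("candidate pair ids must be lexicographically ordered")


def five_prime_anchor(t: TranscriptRecord) -> tuple[int, int]:
    """(5' start coordinate, 3'-end coordinate of the 5'-most exon).

    On '+' the 5'-most exon is the one with the smallest start and its 3'
    end is the exon end; on '-' it is the exon with the largest end and its
    3' end is the exon start.
    """
    if t.strand == "+":
        exon = t.exons[0]
        return exon.start, exon.end
    exon = t.exons[-1]
    return exon.end, exon.start


def _five_prime_exon(t: TranscriptRecord):
    return t.exons[0] if t.strand == "+" else t.exons[-1]


def candidate_pairs(ts: TranscriptSet, window: int = DEFAULT_WINDOW) -> list[tuple[str, str]]:
    """All unordered same-chromosome pairs with 5' starts within *window* nt.

    Per-chromosome sort on the 5' start plus a sliding window gives
    O(n log n + k); each pair appears once, ids in lexicographic order.
    """
    if window < 0:
        raise ConfigError(f"candidate window must be non-negative, got {window}")
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for t in ts.transcripts:
        by_chrom.setdefault(t.chromosome, []).append((five_prime_anchor(t)[0], t.transcript_id))
    pairs: list[tuple[str, str]] = []
    for chrom in sorted(by_chrom):
        entries = sorted(by_chrom[chrom])
        lo = 0
        for i, (start, tid) in enumerate(entries):
            while entries[lo][0] < start - window:
                lo += 1
            for j in range(lo, i):
                other = entries[j][1]
                pairs.append((other, tid) if other < tid else (tid, other))
    pairs.sort()
    return pairs


def exon_overlap_stats(a: TranscriptRecord, b: TranscriptRecord) -> tuple[float, int]:
    """(Jaccard overlap of the two 5'-most exons, #exon pairs with reciprocal >90% overlap).

    The fraction is |intersection| / |union| of the two 5'-most exon
    intervals (interval length = end - start + 1).  The count greedily
    matches exon pairs one-to-one by descending overlap and keeps those
    whose shared length strictly exceeds 90% of BOTH exon lengths.
    """
    ea, eb = _five_prime_exon(a), _five_prime_exon(b)
    inter = ea.overlap(eb)
    union = ea.length + eb.length - inter
    frac = inter / union if union else 0.0

    candidates = []
    for i, xa in enumerate(a.exons):
        for j, xb in enumerate(b.exons):
            ov = xa.overlap(xb)
            if ov > 0.9 * xa.length and ov > 0.9 * xb.length:
                candidates.append((-ov, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    count = 0
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        count += 1
    return frac, count


def compute_features(a: TranscriptRecord, b: TranscriptRecord, emb: TermEmbedding | None) -> PairFeatures:
    """Assemble the six-feature vector for one pair; symmetric in (a, b).

    An SO type absent from the embedding falls back to similarity 0.0 with
    a warning, so a stray source-database type never aborts a build.
    """
    start_a, end5_a = five_prime_anchor(a)
    start_b, end5_b = five_prime_anchor(b)
    frac, n90 = exon_overlap_stats(a, b)
    if emb is not None and a.so_type in emb and b.so_type in emb:
        sim = term_similarity(emb, a.so_type, b.so_type)
    else:
        missing = [t for t in (a.so_type, b.so_type) if emb is None or t not in emb]
        log.warning("SO type(s) %s not in embedding; type similarity falls back to 0.0", missing)
        sim = 0.0
    return PairFeatures(
        d_start5=float(abs(start_a - start_b)),
        d_end5exon=float(abs(end5_a - end5_b)),
        frac_overlap_5exon=frac,
        n_exons_overlap90=float(n90),
        same_strand=1.0 if a.strand == b.strand else 0.0,
        so_sim=sim,
    )


def build_candidate_table(
    ts: TranscriptSet, emb: TermEmbedding | None, window: int = DEFAULT_WINDOW
) -> list[CandidatePair]:
    """Candidate pairs with computed features, ready for scoring."""
    records = ts.by_id()
    return [
        CandidatePair(ia, ib, compute_features(records[ia], records[ib], emb))
        for ia, ib in candidate_pairs(ts, window)
    ]


def features_to_tsv(pairs: list[CandidatePair]) -> str:
    """Audit export: fixed column order (id_a, id_b, then FEATURE_NAMES)."""
    lines = ["id_a\tid_b\t" + "\t".join(FEATURE_NAMES)]
    for p in pairs:
        vals = "\t".join(format(v, "g") for v in p.features.as_array())
        lines.append(f"{p.id_a}\t{p.id_b}\t{vals}")
    return "\n".join(lines) + "\n"
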