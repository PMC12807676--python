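"""From pairwise probabilities to genes: weighted graph + community detection.

Each transcript is a node; each candidate pair whose same-gene probability
clears the edge threshold contributes an edge weighted by that probability.
Communities of the weighted graph become genes — communities rather than
connected components, because a single long transcript can otherwise chain
several distinct genes together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .errors import ConfigError, ContractError
from .features import DEFAULT_WINDOW, CandidatePair, build_candidate_table, five_prime_anchor
from .genes import GeneMember, GeneRecord, GeneSet
from .gff_io import TranscriptSet
from .model import SameGenePairClassifier
from .ontology import TermEmbedding

log = logging.getLogger(__name__)


def build_graph(
    pairs: list[CandidatePair],
    model: SameGenePairClassifier,
    edge_threshold: float = 0.5,
    nodes: list[str] | None = None,
) -> nx.Graph:
    """Score candidate pairs and keep edges with probability >= threshold.

    *nodes*, when given, pre-populates the graph so transcripts without any
    retained edge remain as isolated nodes.
    """
    if not 0.0 <= edge_threshold <= 1.0:
        raise ConfigError(f"edge threshold must lie in [0, 1], got {edge_threshold}")
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(sorted(nodes))
    if pairs:
        X = np.vstack([p.features.as_array() for p in pairs])
        probs = model.same_gene_probability(X)
        for p, w in zip(pairs, probs):
            g.add_nodes_from((p.id_a, p.id_b))
            if w >= edge_threshold and w > 0:
                g.add_edge(p.id_a, p.id_b, weight=float(w))
    return g


class GeneCommunityClusterer(ClusterMixin, BaseEstimator):
    """Weighted-modularity community detection over a transcript graph.

    Louvain on the edge weights, run ``n_restarts`` times with seeds derived
    deterministically from ``seed``; the partition with the highest weighted
    modularity wins (ties broken by a canonical sorted form).  Restarts
    narrow the heuristic gap of single-pass Louvain on small graphs while
    keeping runs bit-reproducible.  Louvain communities are connected, so
    the partition always refines the graph's connected components.

    Fitted attributes: ``communities_`` (list of sorted node lists),
    ``labels_`` (aligned with sorted node order), ``modularity_``.
    """

    def __init__(self, resolution: float = 1.0, seed: int = 0, n_restarts: int = 8):
        self.resolution = resolution
        self.seed = seed
        self.n_restarts = n_restarts

    def fit(self, g: nx.Graph, y=None):
        best: tuple[float, list[list[str]]] | None = None
        if g.number_of_nodes() == 0:
            self.communities_, self.labels_, self.modularity_ = [], np.array([], dtype=int), 0.0
            return self
        for r in range(max(1, self.n_restarts)):
            comms = nx.community.louvain_communities(
                g, weight="weight", resolution=self.resolution, seed=self.seed + r
            )
            canon = sorted((sorted(c) for c in comms), key=lambda c: c[0])
            q = nx.community.modularity(g, comms, weight="weight", resolution=self.resolution) if g.number_of_edges() else 0.0
            if best is None or q > best[0] + 1e-12 or (abs(q - best[0]) <= 1e-12 and canon < best[1]):
                best = (q, canon)
        self.modularity_, self.communities_ = best
        label_of = {}
        for i, comm in enumerate(self.communities_):
            for node in comm:
                label_of[node] = i
        self.labels_ = np.array([label_of[n] for n in sorted(g.nodes)], dtype=int)
        return self

    def fit_predict(self, g: nx.Graph, y=None) -> np.ndarray:
        return self.fit(g).labels_


def detect_communities(g: nx.Graph, resolution: float = 1.0, seed: int = 0) -> list[list[str]]:
    """Partition of the node set into communities (each a sorted id list)."""
    return GeneCommunityClusterer(resolution=resolution, seed=seed).fit(g).communities_


@dataclass
class BuildConfig:
    """End-to-end build parameters; every default is the documented one."""

    window: int = DEFAULT_WINDOW
    edge_threshold: float = 0.5
    min_transcripts: int = 2
    resolution: float = 1.0
    community_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.edge_threshold <= 1.0:
            raise ConfigError(f"edge_threshold must lie in [0, 1], got {self.edge_threshold}")
        if self.min_transcripts < 1:
            raise ConfigError("min_transcripts must be >= 1")


def cluster_to_record(members, ts_index) -> GeneRecord:
    recs = [ts_index[m] for m in sorted(members)]
    strands = {r.strand for r in recs}
    return GeneRecord(
        chromosome=recs[0].chromosome,
        assembly_id=recs[0].assembly_id,
        start=min(r.start for r in recs),
        end=max(r.end for r in recs),
        strand=next(iter(strands)) if len(strands) == 1 else "mixed",
        start5=min(five_prime_anchor(r)[0] for r in recs),
        members=[
            GeneMember(r.transcript_id, r.start, r.end, r.strand, r.so_type) for r in recs
        ],
    )


def build_genes(
    ts: TranscriptSet,
    model: SameGenePairClassifier,
    emb: TermEmbedding | None,
    config: BuildConfig | None = None,
) -> GeneSet:
    """The full first pipeline step: candidates → features → probabilities →
    graph → communities → gene clusters (unversioned).

    Communities smaller than ``min_transcripts`` go to the singleton side
    channel instead of becoming genes.  Refuses to run if the model was
    trained against a different term embedding (fingerprint mismatch).
    """
    config = config or BuildConfig()
    if (
        emb is not None
        and getattr(model, "embedding_fingerprint_", None) is not None
        and model.embedding_fingerprint_ != emb.fingerprint()
    ):
        raise ContractError(
            "model was trained with a different term embedding "
            f"({model.embedding_fingerprint_[:12]}… vs {emb.fingerprint()[:12]}…)"
        )
    index = ts.by_id()
    pairs = build_candidate_table(ts, emb, config.window)
    graph = build_graph(pairs, model, config.edge_threshold, nodes=list(index)) if pairs else nx.Graph()
    if not pairs:
        graph.add_nodes_from(sorted(index))
    communities = detect_communities(graph, config.resolution, config.community_seed)

    genes, side = [], []
    for comm in communities:
        if len(comm) >= config.min_transcripts:
            genes.append(cluster_to_record(comm, index))
        else:
            side.append(sorted(comm))
    genes.sort(key=lambda g: (g.chromosome, g.start, g.end))

    stage_counts = {
        "transcripts": len(ts),
        "candidate_pairs": len(pairs),
        "edges": graph.number_of_edges(),
        "communities": len(communities),
        "genes": len(genes),
        "singleton_communities": len(side),
    }
    log.info("build stages: %s", stage_counts)
    return GeneSet(
        assembly_id=ts.assembly_id,
        genes=genes,
        singletons=side,
        provenance={
            "stage_counts": stage_counts,
            "config": {
                "window": config.window,
                "edge_threshold": config.edge_threshold,
                "min_transcripts": config.min_transcripts,
                "resolution": config.resolution,
                "community_seed": config.community_seed,
            },
            "read": ts.provenance,
        },
    )
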