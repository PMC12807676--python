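"""Sequence Ontology loading and RNA-type similarity via graph embeddings.

The Sequence Ontology (SO) is a directed acyclic graph of feature types.
Two RNA types are compared numerically by embedding the ontology graph
with node2vec-style random walks and taking the inner product of the two
unit-normalized term vectors, so the similarity lies in [-1, 1] and
self-similarity is exactly 1.

Because random-walk skip-gram embeddings implicitly factorize a shifted
pointwise-mutual-information matrix of walk co-occurrences, the embedding
here is computed directly as an SVD of the positive PMI matrix of the
sampled walks: same walk procedure and hyperparameters (walk length,
walks per node, window, p, q), fully deterministic for a fixed seed, and
with no external word2vec dependency.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping

import networkx as nx
import numpy as np

from .errors import ConfigError, OntologyError, TermLookupError

log = logging.getLogger(__name__)


class OntologyGraph:
    """A DAG of ontology terms; edges run child -> parent (is_a/part_of)."""

    def __init__(self, graph: nx.DiGraph, names: Mapping[str, str], dropped_obsolete: list[str] | None = None):
        if graph.number_of_nodes() == 0:
            raise OntologyError("ontology has no terms")
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise OntologyError(f"ontology graph contains a cycle: {cycle}")
        self._g = graph
        self.names = dict(names)
        self.dropped_obsolete = list(dropped_obsolete or [])

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def parents(self, term: str) -> frozenset[str]:
        return frozenset(self._g.successors(term))

    def descendants(self, term: str) -> frozenset[str]:
        """All terms below *term* (transitive children); empty for unknown terms."""
        if term not in self._g:
            return frozenset()
        return frozenset(nx.ancestors(self._g, term))  # child->parent edges: ancestors are children

    def depth(self, term: str) -> int:
        """Longest child->parent path from *term* to any root; specificity proxy."""
        if term not in self._g:
            return 0
        best = 0
        for node in nx.descendants(self._g, term) | {term}:
            if self._g.out_degree(node) == 0:
                for path in (nx.all_simple_paths(self._g, term, node) if node != term else [[term]]):
                    best = max(best, len(path) - 1)
        return best

    def undirected(self) -> nx.Graph:
        return self._g.to_undirected(as_view=False)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for node in sorted(self._g.nodes):
            h.update(node.encode())
        for u, v in sorted(self._g.edges):
            h.update(f"{u}>{v}".encode())
        return h.hexdigest()


def load_ontology(
    source: str | Path | IO[str], keep_relations: Iterable[str] = ("is_a",)
) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 flat file into an :class:`OntologyGraph`.

    Only ``[Term]`` stanzas are read; obsolete terms are dropped (and
    logged); relationship types outside *keep_relations* are ignored.
    """
    keep = set(keep_relations)
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()

    graph = nx.DiGraph()
    names: dict[str, str] = {}
    dropped: list[str] = []
    edges: list[tuple[str, str]] = []

    current: dict | None = None

    def flush(stanza: dict | None):
        if not stanza or "id" not in stanza:
            return
        if stanza.get("obsolete"):
            dropped.append(stanza["id"])
            return
        tid = stanza["id"]
        graph.add_node(tid)
        names[tid] = stanza.get("name", tid)
        for rel, parent in stanza.get("links", []):
            if rel in keep:
                edges.append((tid, parent))

    in_term = False
    for raw in text.splitlines():
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            flush(current if in_term else None)
            in_term = line == "[Term]"
            current = {"links": []} if in_term else None
            continue
        if not in_term or current is None or ":" not in line:
            continue
        key, value = (part.strip() for part in line.split(":", 1))
        if key == "id":
            current["id"] = value
        elif key == "name":
            current["name"] = value
        elif key == "is_obsolete" and value.lower() == "true":
            current["obsolete"] = True
        elif key == "is_a":
            current["links"].append(("is_a", value.strip()))
        elif key == "relationship":
            parts = value.split()
            if len(parts) >= 2:
                current["links"].append((parts[0], parts[1]))
    flush(current if in_term else None)

    obsolete_set = set(dropped)
    for child, parent in edges:
        if parent in obsolete_set or child in obsolete_set:
            continue
        graph.add_node(parent)
        graph.add_edge(child, parent)

    if dropped:
        log.info("dropped %d obsolete ontology terms: %s", len(dropped), dropped[:5])
    return OntologyGraph(graph, names, dropped_obsolete=dropped)


# -- embedding ---------------------------------------------------------------


@dataclass(frozen=True)
class EmbedConfig:
    """node2vec-style hyperparameters; defaults follow common practice
    (dimension 64, walk length 20, 10 walks per node, window 5, p = q = 1)."""

    dimension: int = 64
    walk_length: int = 20
    walks_per_node: int = 10
    window: int = 5
    p: float = 1.0
    q: float = 1.0

    def __post_init__(self):
        if self.dimension <= 0:
            raise ConfigError(f"embedding dimension must be positive, got {self.dimension}")
        if self.walk_length < 2 or self.walks_per_node < 1 or self.window < 1:
            raise ConfigError("walk_length >= 2, walks_per_node >= 1, window >= 1 required")


class TermEmbedding:
    """Unit-norm vectors per ontology term plus the config that produced them."""

    def __init__(self, terms: list[str], matrix: np.ndarray, config: EmbedConfig, seed: int, ontology_hash: str):
        self.terms = list(terms)
        self.matrix = matrix  # (n_terms, dimension), rows unit-norm
        self.config = config
        self.seed = seed
        self.ontology_hash = ontology_hash
        self._index = {t: i for i, t in enumerate(self.terms)}

    @property
    def dimension(self) -> int:
        return self.matrix.shape[1]

    def __contains__(self, term: str) -> bool:
        return term in self._index

    def vector(self, term: str) -> np.ndarray:
        try:
            return self.matrix[self._index[term]]
        except KeyError:
            raise TermLookupError(f"term {term!r} has no embedding") from None

    def fingerprint(self) -> str:
        payload = json.dumps({"ontology": self.ontology_hash, "config": asdict(self.config), "seed": self.seed},
                             sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def _sample_walks(adj: list[np.ndarray], config: EmbedConfig, rng: np.random.Generator) -> list[list[int]]:
    """Second-order biased walks (p: return, q: in-out) over an undirected graph."""
    n = len(adj)
    walks: list[list[int]] = []
    neighbor_sets = [set(a.tolist()) for a in adj]
    uniform = config.p == 1.0 and config.q == 1.0
    for _ in range(config.walks_per_node):
        for start in range(n):
            walk = [start]
            while len(walk) < config.walk_length:
                cur = walk[-1]
                nbrs = adj[cur]
                if nbrs.size == 0:
                    break
                if uniform or len(walk) == 1:
                    nxt = int(nbrs[rng.integers(nbrs.size)])
                else:
                    prev = walk[-2]
                    w = np.ones(nbrs.size)
                    for i, x in enumerate(nbrs):
                        if x == prev:
                            w[i] = 1.0 / config.p
                        elif x in neighbor_sets[prev]:
                            w[i] = 1.0
                        else:
                            w[i] = 1.0 / config.q
                    w /= w.sum()
                    nxt = int(nbrs[rng.choice(nbrs.size, p=w)])
                walk.append(nxt)
            walks.append(walk)
    return walks


def embed_terms(graph: OntologyGraph, config: EmbedConfig | None = None, seed: int = 0) -> TermEmbedding:
    """Embed every ontology term as a unit vector.

    Walks treat the DAG as undirected so similarity flows both up and down
    is_a links.  The walk co-occurrence matrix (symmetric window counts,
    with +1 self-smoothing so no term has an empty context) is converted to
    positive PMI and factorized by SVD; rows are L2-normalized.  The whole
    procedure is a deterministic function of (graph, config, seed).
    """
    config = config or EmbedConfig()
    terms = sorted(graph.terms)
    n = len(terms)
    index = {t: i for i, t in enumerate(terms)}
    und = graph.undirected()
    adj = [np.array(sorted(index[v] for v in und.neighbors(t)), dtype=np.int64) for t in terms]

    rng = np.random.Generator(np.random.PCG64(seed))
    walks = _sample_walks(adj, config, rng)

    counts = np.zeros((n, n))
    for walk in walks:
        L = len(walk)
        for i in range(L):
            for j in range(i + 1, min(i + config.window + 1, L)):
                counts[walk[i], walk[j]] += 1.0
                counts[walk[j], walk[i]] += 1.0
    counts[np.diag_indices(n)] += 1.0  # smoothing: every term co-occurs with itself

    total = counts.sum()
    row = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(counts * total / (row @ row.T))
    ppmi = np.where(np.isfinite(pmi) & (pmi > 0), pmi, 0.0)

    u, s, _ = np.linalg.svd(ppmi, full_matrices=False)
    d = min(config.dimension, n)
    vecs = u[:, :d] * np.sqrt(s[:d])
    if d < config.dimension:
        vecs = np.hstack([vecs, np.zeros((n, config.dimension - d))])

    norms = np.linalg.norm(vecs, axis=1)
    for i in np.where(norms < 1e-12)[0]:
        # degenerate row (term never leaves a trivial context): deterministic fallback
        fallback = np.random.Generator(np.random.PCG64((seed * 1000003 + i) % (2**63))).normal(size=config.dimension)
        vecs[i] = fallback
        norms[i] = np.linalg.norm(fallback)
    vecs = vecs / norms[:, None]
    return TermEmbedding(terms, vecs, config, seed, graph.content_hash())


def term_similarity(embedding: TermEmbedding, a: str, b: str) -> float:
    """Inner product of the two unit term vectors; symmetric, in [-1, 1]."""
    sim = float(np.dot(embedding.vector(a), embedding.vector(b)))
    return max(-1.0, min(1.0, sim))


# -- embedding cache ---------------------------------------------------------


def save_embedding(emb: TermEmbedding, path: str | Path) -> None:
    """Serialize as a TSV (term, vector) table with a JSON config header line."""
    header = json.dumps(
        {"format": "ncgene-embedding/1", "config": asdict(emb.config), "seed": emb.seed,
         "ontology_hash": emb.ontology_hash, "dimension": emb.dimension},
        sort_keys=True,
    )
    lines = [f"#{header}"]
    for term, vec in zip(emb.terms, emb.matrix):
        lines.append(term + "\t" + "\t".join(repr(float(x)) for x in vec))
    Path(path).write_text("\n".join(lines) + "\n")


def load_embedding(path: str | Path) -> TermEmbedding:
    lines = Path(path).read_text().splitlines()
    meta = json.loads(lines[0][1:])
    terms, rows = [], []
    for line in lines[1:]:
        parts = line.split("\t")
        terms.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    return TermEmbedding(terms, np.array(rows), EmbedConfig(**meta["config"]), meta["seed"], meta["ontology_hash"])


def embed_terms_cached(
    graph: OntologyGraph, config: EmbedConfig | None = None, seed: int = 0, cache_dir: str | Path | None = None
) -> TermEmbedding:
    """Like :func:`embed_terms` but cached by (ontology hash, config, seed)."""
    config = config or EmbedConfig()
    if cache_dir is None:
        return embed_terms(graph, config, seed)
    key = hashlib.sha256(
        json.dumps({"o": graph.content_hash(), "c": asdict(config), "s": seed}, sort_keys=True).encode()
    ).hexdigest()[:24]
    path = Path(cache_dir) / f"embedding-{key}.tsv"
    if path.exists():
        return load_embedding(path)
    emb = embed_terms(graph, config, seed)
    path.parent.mkdir(parents=True, exist_ok=True)
    save_embedding(emb, path)
    return emb
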