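"""Redundancy removal and seed-anchored graph clustering.

Two stages connect the homology screen to the motif-grammar filter:

1. Greedy incremental identity clustering (the cd-hit algorithm at a
   90% identity cut-off, word length 5): sequences are visited longest
   first and join the first existing cluster whose representative they
   match at or above the threshold, where identity is identical aligned
   positions over the shorter sequence's length.  A shared-word
   prefilter only skips pairs that share no k-mer at all — it can never
   change the partition relative to the unfiltered algorithm.

2. Markov clustering (MCL, inflation 1.4) of the bit-score similarity
   graph, after which only the cluster containing the seed (query)
   sequence is retained — discarding well-scoring but seed-dissimilar
   sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from upomine.homology import ScoringScheme, identity_fraction, local_score
from upomine.io_formats import ProteinRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterSet:
    """A partition of record ids with one representative per cluster."""

    clusters: tuple[tuple[str, ...], ...]
    representatives: tuple[str, ...]
    method: str  # greedy | mcl
    converged: bool = True

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cluster, rep in zip(self.clusters, self.representatives):
            if not cluster:
                raise ValueError("empty cluster")
            if rep not in cluster:
                raise ValueError(f"representative {rep!r} not a member")
            overlap = seen & set(cluster)
            if overlap:
                raise ValueError(f"ids in multiple clusters: {sorted(overlap)}")
            seen |= set(cluster)

    @property
    def ids(self) -> frozenset:
        return frozenset(i for c in self.clusters for i in c)

    def cluster_of(self, record_id: str) -> tuple[str, ...]:
        for c in self.clusters:
            if record_id in c:
                return c
        raise KeyError(record_id)


@dataclass
class SimilarityGraph:
    """Weighted undirected similarity graph over record ids."""

    nodes: tuple[str, ...]
    edges: dict  # frozenset({u, v}) -> weight >= 0

    @classmethod
    def from_records(
        cls,
        records: list[ProteinRecord],
        scheme: ScoringScheme | None = None,
        weight: str = "bit",
    ) -> "SimilarityGraph":
        """All-pairs similarity graph weighted by bit score (default).

        ``weight="raw"`` uses raw Smith–Waterman scores instead.
        """
        from upomine.homology import bit_score

        scheme = (scheme or ScoringScheme()).with_stats()
        nodes = tuple(r.id for r in records)
        edges: dict = {}
        for i, a in enumerate(records):
            for b in records[i + 1 :]:
                s = local_score(a.residues, b.residues, scheme)
                if s <= 0:
                    continue
                w = bit_score(s, scheme) if weight == "bit" else s
                if w > 0:
                    edges[frozenset((a.id, b.id))] = w
        return cls(nodes, edges)


def _word_set(residues: str, k: int) -> frozenset:
    return frozenset(residues[i : i + k] for i in range(len(residues) - k + 1))


def greedy_identity_cluster(
    records: list[ProteinRecord],
    identity_threshold: float = 0.90,
    word_length: int = 5,
    scheme: ScoringScheme | None = None,
) -> ClusterSet:
    """Greedy incremental clustering at an identity cut-off.

    Records are sorted by length descending (ties by id); each record
    joins the first existing cluster whose representative it matches at
    ``>= identity_threshold``, else it founds a new cluster.  With
    ``word_length > 0`` pairs sharing no word are skipped without
    alignment.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError(f"identity threshold {identity_threshold} outside (0, 1]")
    scheme = (scheme or ScoringScheme()).with_stats()
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    reps: list[ProteinRecord] = []
    rep_words: list[frozenset] = []
    members: list[list[str]] = []
    for rec in ordered:
        words = _word_set(rec.residues, word_length) if word_length else None
        placed = False
        for k, rep in enumerate(reps):
            if words is not None and not (words & rep_words[k]):
                continue  # zero shared words: identity cannot reach threshold
            if identity_fraction(rep, rec, scheme) >= identity_threshold:
                members[k].append(rec.id)
                placed = True
                break
        if not placed:
            reps.append(rec)
            rep_words.append(words if words is not None else frozenset())
            members.append([rec.id])
    return ClusterSet(
        clusters=tuple(tuple(m) for m in members),
        representatives=tuple(r.id for r in reps),
        method="greedy",
    )


def mcl_cluster(
    graph: SimilarityGraph,
    inflation: float = 1.4,
    max_iter: int = 100,
    tol: float = 1e-6,
    prune: float = 1e-8,
) -> ClusterSet:
    """Markov clustering of a similarity graph.

    Self-loops are added (weight = the node's maximum incident edge
    weight, or 1 for isolated nodes), columns are normalized to a
    stochastic matrix, and expansion (matrix squaring) alternates with
    inflation (elementwise power, renormalize) until the matrix changes
    by less than ``tol`` or ``max_iter`` is reached.  Clusters are the
    weakly connected components of the attractor interpretation: node j
    joins attractor i whenever the converged entry (i, j) is positive.

    Node order never matters: the matrix is built over sorted ids.
    """
    if not graph.nodes:
        raise ValueError("empty graph")
    ids = sorted(graph.nodes)
    index = {v: i for i, v in enumerate(ids)}
    n = len(ids)
    M = np.zeros((n, n))
    for edge, w in graph.edges.items():
        if w < 0:
            raise ValueError(f"negative edge weight on {sorted(edge)}")
        pair = sorted(edge)
        if len(pair) == 1:
            continue  # explicit self-loop in input; replaced below
        u, v = (index[x] for x in pair)
        M[u, v] = M[v, u] = w
    incident_max = M.max(axis=0)
    for i in range(n):
        M[i, i] = incident_max[i] if incident_max[i] > 0 else 1.0

    def normalize(A: np.ndarray) -> np.ndarray:
        return A / A.sum(axis=0, keepdims=True)

    M = normalize(M)
    converged = False
    for _ in range(max_iter):
        prev = M
        M = M @ M                      # expansion
        M = normalize(M ** inflation)  # inflation
        M[M < prune] = 0.0
        M = normalize(M)
        if np.max(np.abs(M - prev)) < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge within %d iterations", max_iter)

    g = nx.Graph()
    g.add_nodes_from(range(n))
    rows, cols = np.nonzero(M)
    g.add_edges_from(zip(rows.tolist(), cols.tolist()))
    clusters = []
    representatives = []
    for comp in nx.connected_components(g):
        names = sorted(ids[i] for i in comp)
        clusters.append(tuple(names))
        representatives.append(names[0])
    order = np.argsort([c[0] for c in clusters])
    return ClusterSet(
        clusters=tuple(clusters[i] for i in order),
        representatives=tuple(representatives[i] for i in order),
        method="mcl",
        converged=converged,
    )


def retain_seed_cluster(clusters: ClusterSet, seed_id: str) -> tuple[str, ...]:
    """Members of the cluster containing the seed sequence."""
    try:
        return clusters.cluster_of(seed_id)
    except KeyError:
        raise KeyError(f"seed {seed_id!r} not among the clustered ids") from None
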