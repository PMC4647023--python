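"""Weighted undirected PPI graph and exact shortest paths with deterministic ties.

The network transforms STRING confidence scores into distances with
``w(e) = 1000 - score``, so high-confidence interactions (score near 999)
become short edges (weight near 1) and minimum-weight paths chain together
strong interactions.  All weights are positive integers in [1, 850], which
satisfies Dijkstra's preconditions by construction.

Many distinct paths can share the minimum total weight.  To make output
independent of edge insertion order, the default tie-break returns, among all
minimum-weight paths, the one whose node sequence is lexicographically
smallest.  This is computed by a greedy descent on the distance field: from the
source, repeatedly step to the smallest-ID neighbour that stays on some
shortest path (an edge (u, v) does iff ``w(u, v) + d(v, t) == d(u, t)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _sp_dijkstra

from .string_io import SCORE_MAX, SCORE_MIN, ScoredInteraction

WEIGHT_MIN = 1000 - SCORE_MAX  # 1
WEIGHT_MAX = 1000 - SCORE_MIN  # 850

TieBreak = Literal["lexicographic", "first-found"]

_ORACLE_NODE_LIMIT = 200


@dataclass(frozen=True)
class SeedPairPath:
    """One minimum-weight path between a seed pair.

    ``nodes`` runs from ``source`` to ``target``; ``total_weight`` is the sum
    of edge weights along it.  ``edge_weights`` (len(nodes) - 1 entries) is
    carried when the path was produced by mining, so edge tables can be written
    without re-querying the network.
    """

    source: str
    target: str
    nodes: tuple[str, ...]
    total_weight: int
    edge_weights: tuple[int, ...] | None = None

    def __len__(self) -> int:
        return len(self.nodes)

    def edges(self) -> Iterator[tuple[str, str, int]]:
        if self.edge_weights is None:
            raise ValueError("path carries no per-edge weights")
        for i, w in enumerate(self.edge_weights):
            yield self.nodes[i], self.nodes[i + 1], w


class PPINetwork:
    """Undirected weighted protein network.

    Nodes are protein IDs; each edge carries the original ``score`` and its
    distance ``weight = 1000 - score``.  A sorted-node CSR adjacency matrix is
    cached lazily for bulk shortest-path queries; node order in the CSR is
    lexicographic, which is what makes the greedy tie-break walk emit the
    lexicographically smallest path.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()
        self._nodes: list[str] | None = None
        self._index: dict[str, int] | None = None
        self._csr: csr_matrix | None = None

    # -- container-ish surface -------------------------------------------------
    def __contains__(self, node: object) -> bool:
        return node in self.graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        """All node IDs in lexicographic order."""
        self._ensure_index()
        return list(self._nodes)  # type: ignore[arg-type]

    def weight(self, u: str, v: str) -> int:
        return int(self.graph[u][v]["weight"])

    def degree(self, node: str) -> int:
        return self.graph.degree(node)

    # -- internal CSR view -----------------------------------------------------
    def _ensure_index(self) -> None:
        if self._csr is not None:
            return
        self._nodes = sorted(self.graph.nodes)
        self._index = {n: i for i, n in enumerate(self._nodes)}
        n = len(self._nodes)
        rows, cols, vals = [], [], []
        for u, v, data in self.graph.edges(data=True):
            iu, iv = self._index[u], self._index[v]
            w = data["weight"]
            rows.extend((iu, iv))
            cols.extend((iv, iu))
            vals.extend((w, w))
        self._csr = csr_matrix(
            (np.asarray(vals, dtype=np.float64), (rows, cols)), shape=(n, n)
        )
        self._csr.sort_indices()

    def csr(self) -> tuple[list[str], dict[str, int], csr_matrix]:
        self._ensure_index()
        return self._nodes, self._index, self._csr  # type: ignore[return-value]

    def distances_from(self, sources: Iterable[str]) -> np.ndarray:
        """Single-source Dijkstra distances from each source to every node.

        Returns an array of shape (len(sources), n_nodes) indexed by the
        lexicographic node order; unreachable entries are ``inf``.  Distances
        are integer-valued floats (weights are integers well below 2**53, so
        float64 arithmetic is exact and equality tests are safe).
        """
        nodes, index, csr = self.csr()
        idx = [index[s] for s in sources]
        if not idx:
            return np.empty((0, len(nodes)))
        return _sp_dijkstra(csr, directed=False, indices=idx)


def build_network(interactions: Iterable[ScoredInteraction]) -> PPINetwork:
    """Build the weighted network: one node per protein, ``w = 1000 - score``.

    Interactions are expected deduplicated (the parser's contract); a repeated
    pair keeps the maximum score, matching parser semantics.  A score outside
    [150, 999] raises ``ValueError`` naming the offending pair.
    """
    g = nx.Graph()
    for it in interactions:
        if not (SCORE_MIN <= it.score <= SCORE_MAX):
            raise ValueError(
                f"score {it.score} for pair ({it.protein_a}, {it.protein_b}) "
                f"outside [{SCORE_MIN}, {SCORE_MAX}]"
            )
        a, b = it.protein_a, it.protein_b
        if g.has_edge(a, b) and g[a][b]["score"] >= it.score:
            continue
        g.add_edge(a, b, score=it.score, weight=1000 - it.score)
    net = PPINetwork(g)
    return net


def _greedy_walk(
    start: int,
    goal: int,
    dist_to_goal: np.ndarray,
    csr: csr_matrix,
) -> list[int]:
    """Lexicographically smallest shortest path start -> goal, as node indices.

    At each node u, steps to the smallest-index neighbour v satisfying
    ``w(u, v) + d(v, goal) == d(u, goal)``.  CSR column indices are sorted, so
    the first hit is the smallest; node indices follow lexicographic ID order.
    """
    indptr, indices, data = csr.indptr, csr.indices, csr.data
    path = [start]
    u = start
    n = csr.shape[0]
    while u != goal:
        lo, hi = indptr[u], indptr[u + 1]
        nbrs = indices[lo:hi]
        ok = np.nonzero(data[lo:hi] + dist_to_goal[nbrs] == dist_to_goal[u])[0]
        if ok.size == 0:  # pragma: no cover - cannot happen on a finite distance
            raise RuntimeError("greedy walk left the shortest-path DAG")
        u = int(nbrs[ok[0]])
        path.append(u)
        if len(path) > n:  # pragma: no cover
            raise RuntimeError("greedy walk cycled")
    return path


def _materialise(
    network: PPINetwork, node_idx: list[int], total: int
) -> SeedPairPath:
    nodes, _, _ = network.csr()
    names = tuple(nodes[i] for i in node_idx)
    weights = tuple(
        network.weight(names[i], names[i + 1]) for i in range(len(names) - 1)
    )
    return SeedPairPath(
        source=names[0],
        target=names[-1],
        nodes=names,
        total_weight=total,
        edge_weights=weights,
    )


def shortest_path(
    network: PPINetwork,
    source: str,
    target: str,
    tie_break: TieBreak = "lexicographic",
) -> SeedPairPath | None:
    """Exactly one minimum-weight path from source to target, or None.

    Under the default ``lexicographic`` policy the returned path has the
    lexicographically smallest node sequence among all co-optimal paths,
    independent of edge insertion order.  ``first-found`` defers to networkx's
    Dijkstra and is order-dependent among ties.  Returns ``None`` when the
    target is unreachable; ``source == target`` yields the zero-length path.
    """
    for name, node in (("source", source), ("target", target)):
        if node not in network:
            raise KeyError(f"{name} node {node!r} not in network")
    if source == target:
        return SeedPairPath(source, target, (source,), 0, ())

    if tie_break == "first-found":
        try:
            length, nodes = nx.single_source_dijkstra(
                network.graph, source, target, weight="weight"
            )
        except nx.NetworkXNoPath:
            return None
        weights = tuple(
            network.weight(nodes[i], nodes[i + 1]) for i in range(len(nodes) - 1)
        )
        return SeedPairPath(source, target, tuple(nodes), int(length), weights)

    if tie_break != "lexicographic":
        raise ValueError(f"unknown tie_break policy {tie_break!r}")

    _, index, csr = network.csr()
    dist = network.distances_from([target])[0]
    s, t = index[source], index[target]
    if not np.isfinite(dist[s]):
        return None
    walk = _greedy_walk(s, t, dist, csr)
    return _materialise(network, walk, int(dist[s]))


def all_pairs_oracle(network: PPINetwork) -> dict[tuple[str, str], float]:
    """Exact all-pairs distances by Floyd–Warshall dynamic programming.

    An intentionally simple, algorithmically independent cross-check for the
    Dijkstra-based paths; guarded to small graphs (<= 200 nodes) and meant for
    tests.  Disconnected pairs map to ``math.inf``.
    """
    if network.n_nodes > _ORACLE_NODE_LIMIT:
        raise ValueError(
            f"oracle guard: {network.n_nodes} nodes exceeds {_ORACLE_NODE_LIMIT}"
        )
    nodes = network.nodes()
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v, data in network.graph.edges(data=True):
        i, j = nodes.index(u), nodes.index(v)
        w = float(data["weight"])
        if w < dist[i, j]:
            dist[i, j] = dist[j, i] = w
    for k in range(n):
        np.minimum(dist, dist[:, k, None] + dist[None, k, :], out=dist)
    return {
        (nodes[i], nodes[j]): float(dist[i, j])
        for i in range(n)
        for j in range(n)
    }


def export_graphml(network: PPINetwork, path) -> None:
    """Write the network as GraphML (nodes, score and weight attributes)."""
    nx.write_graphml(network.graph, path)


def write_edge_list(network: PPINetwork, path) -> None:
    """Write the full network as a weighted edge-list TSV."""
    rows = []
    for u, v, data in network.graph.edges(data=True):
        a, b = (u, v) if u < v else (v, u)
        rows.append((a, b, data["score"], data["weight"]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_a\tprotein_b\tscore\tweight\n")
        for a, b, s, w in sorted(rows):
            fh.write(f"{a}\t{b}\t{s}\t{w}\n")
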