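"""Heterogeneous knowledge-graph container and typed neighbor queries.

A knowledge graph is modeled as an undirected simple graph whose nodes carry
a single semantic type (drug, disease, protein, ...): a node set ``V``, a
total type map ``phi: V -> A`` and an edge set of unordered node pairs.
Typed neighbor queries — "the neighbors of node *u* whose type is *T*" — are
the primitive every meta-path operation is built on.  They can be answered
directly from the edge list, or from a precomputed per-node, per-type
adjacency index; the two backends are interchangeable and return identical
results.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

from .errors import GraphValidationError, UnknownNodeError

logger = logging.getLogger(__name__)

__all__ = [
    "TypedGraph",
    "AdjacencyIndex",
    "build_graph",
    "precompute_adjacency",
    "neighbors_of_type",
    "typed_degree",
]


def _canonical_edge(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class TypedGraph:
    """An undirected, simple, node-typed graph.

    Parameters
    ----------
    type_of
        Total map node id -> type label.  Every node of the graph appears
        here, including degree-0 nodes.
    edges
        Canonicalized unordered pairs ``(min(u,v), max(u,v))``; no
        self-loops, no duplicates.
    n_self_loops_dropped, n_duplicates_dropped
        Bookkeeping from construction (see :func:`build_graph`).
    """

    type_of: Mapping[str, str]
    edges: frozenset[tuple[str, str]]
    n_self_loops_dropped: int = 0
    n_duplicates_dropped: int = 0

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.type_of)

    @property
    def n_nodes(self) -> int:
        return len(self.type_of)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def node_types(self) -> frozenset[str]:
        return frozenset(self.type_of.values())

    def has_node(self, node: str) -> bool:
        return node in self.type_of

    def has_edge(self, u: str, v: str) -> bool:
        return _canonical_edge(u, v) in self.edges

    def sorted_edges(self) -> list[tuple[str, str]]:
        """Edges in lexicographic order — the deterministic serialization order."""
        return sorted(self.edges)

    def fingerprint(self) -> str:
        """Content hash of (nodes, types, edges); stable across sessions."""
        h = hashlib.sha256()
        for node in sorted(self.type_of):
            h.update(f"N\t{node}\t{self.type_of[node]}\n".encode())
        for u, v in self.sorted_edges():
            h.update(f"E\t{u}\t{v}\n".encode())
        return h.hexdigest()


@dataclass(frozen=True)
class AdjacencyIndex:
    """Per-node, per-type sorted neighbor lists plus the source-graph type map.

    ``index[u][T]`` is the lexicographically sorted, duplicate-free list of
    neighbors of ``u`` whose type is ``T``.  The index is symmetric by
    construction: ``v in index[u][T]`` iff ``u in index[v][type_of(u)]``.
    """

    index: Mapping[str, Mapping[str, tuple[str, ...]]]
    type_of: Mapping[str, str]
    source_graph_fingerprint: str = ""

    def has_node(self, node: str) -> bool:
        return node in self.index

    def type_of_node(self, node: str) -> str:
        try:
            return self.type_of[node]
        except KeyError:
            raise UnknownNodeError(node) from None

    def neighbors(self, node: str, node_type: str) -> tuple[str, ...]:
        """Sorted neighbors of ``node`` with type ``node_type`` (empty if none)."""
        try:
            by_type = self.index[node]
        except KeyError:
            raise UnknownNodeError(node) from None
        return by_type.get(node_type, ())


def build_graph(
    edge_rows: Iterable[tuple[str, str]],
    type_rows: Iterable[tuple[str, str]],
) -> TypedGraph:
    """Validate and assemble a :class:`TypedGraph` from raw rows.

    Node ids and type labels are stripped of surrounding whitespace; type
    labels are then compared case-sensitively.  Self-loops and duplicate
    edges are dropped with a logged count.  Nodes present in ``type_rows``
    but in no edge are retained as degree-0 nodes.

    Raises
    ------
    GraphValidationError
        If the edge list is empty, an edge endpoint is untyped, or a node id
        is assigned two different types.
    """
    type_of: dict[str, str] = {}
    for raw_node, raw_type in type_rows:
        node, label = str(raw_node).strip(), str(raw_type).strip()
        if not node or not label:
            raise GraphValidationError(f"blank node id or type label in row ({raw_node!r}, {raw_type!r})")
        if node in type_of and type_of[node] != label:
            raise GraphValidationError(
                f"conflicting types for node {node!r}: {type_of[node]!r} vs {label!r}"
            )
        type_of[node] = label

    edges: set[tuple[str, str]] = set()
    n_self, n_dup = 0, 0
    n_rows = 0
    for raw_u, raw_v in edge_rows:
        n_rows += 1
        u, v = str(raw_u).strip(), str(raw_v).strip()
        for endpoint in (u, v):
            if endpoint not in type_of:
                raise GraphValidationError(f"edge endpoint {endpoint!r} has no type assignment")
        if u == v:
            n_self += 1
            continue
        e = _canonical_edge(u, v)
        if e in edges:
            n_dup += 1
        else:
            edges.add(e)
    if n_rows == 0:
        raise GraphValidationError("empty edge list")
    if n_self or n_dup:
        logger.info("dropped %d self-loop(s) and %d duplicate edge(s)", n_self, n_dup)

    return TypedGraph(
        type_of=dict(type_of),
        edges=frozenset(edges),
        n_self_loops_dropped=n_self,
        n_duplicates_dropped=n_dup,
    )


def precompute_adjacency(graph: TypedGraph) -> AdjacencyIndex:
    """Build the per-node, per-type adjacency index from a graph's edge list.

    Every node of the graph appears in the index; degree-0 nodes map to an
    empty type dict.  Total neighbor-slot count equals ``2 * n_edges``.
    """
    tmp: dict[str, dict[str, list[str]]] = {node: {} for node in graph.type_of}
    for u, v in graph.edges:
        tmp[u].setdefault(graph.type_of[v], []).append(v)
        tmp[v].setdefault(graph.type_of[u], []).append(u)
    index = {
        node: {t: tuple(sorted(nbrs)) for t, nbrs in by_type.items()}
        for node, by_type in tmp.items()
    }
    return AdjacencyIndex(
        index=index,
        type_of=dict(graph.type_of),
        source_graph_fingerprint=graph.fingerprint(),
    )


GraphOrIndex = Union[TypedGraph, AdjacencyIndex]


def neighbors_of_type(source: GraphOrIndex, node: str, node_type: str) -> list[str]:
    """Sorted neighbors of ``node`` whose type is ``node_type``.

    Works against either backend: an :class:`AdjacencyIndex` (O(1) lookup)
    or a :class:`TypedGraph` (edge-list scan).  An unknown type label yields
    an empty list; an unknown node id raises :class:`UnknownNodeError`.
    """
    if isinstance(source, AdjacencyIndex):
        return list(source.neighbors(node, node_type))
    if not source.has_node(node):
        raise UnknownNodeError(node)
    out = [
        w
        for u, v in source.edges
        if (w := (v if u == node else u if v == node else None)) is not None
        and source.type_of[w] == node_type
    ]
    return sorted(out)


def typed_degree(source: GraphOrIndex, node: str, node_type: str) -> int:
    """Number of neighbors of ``node`` with type ``node_type``."""
    return len(neighbors_of_type(source, node, node_type))
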