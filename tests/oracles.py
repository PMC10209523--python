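"""Independent reference implementations used to cross-check hetpaths.

These deliberately avoid the package's traversal code: walk counts come
from products of scipy.sparse biadjacency matrices, repeat-free paths from
networkx's simple-path search, and metric formulas are evaluated directly
over the oracle-enumerated paths with degrees counted off the raw edge
list.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from scipy import sparse

from hetpaths.graph import TypedGraph
from hetpaths.traversal import MetaPath


def walk_count_matrix(graph: TypedGraph, metapath: MetaPath) -> tuple[np.ndarray, list[str], list[str]]:
    """Walk counts as the product of per-step typed biadjacency matrices.

    Returns (matrix, origin node order, destination node order); entry
    (i, j) is the number of typed walks from origin i to destination j.
    """
    by_type: dict[str, list[str]] = {}
    for node in sorted(graph.type_of):
        by_type.setdefault(graph.type_of[node], []).append(node)
    pos = {t: {n: i for i, n in enumerate(nodes)} for t, nodes in by_type.items()}

    product = None
    for ta, tb in zip(metapath.types, metapath.types[1:]):
        rows_t, cols_t = by_type.get(ta, []), by_type.get(tb, [])
        step = sparse.lil_matrix((len(rows_t), len(cols_t)), dtype=np.int64)
        for u, v in graph.edges:
            tu, tv = graph.type_of[u], graph.type_of[v]
            if tu == ta and tv == tb:
                step[pos[ta][u], pos[tb][v]] = 1
            if tv == ta and tu == tb:
                step[pos[ta][v], pos[tb][u]] = 1
        step = step.tocsr()
        product = step if product is None else product @ step
    dense = np.asarray(product.todense())
    return dense, by_type.get(metapath.types[0], []), by_type.get(metapath.types[-1], [])


def walk_count(graph: TypedGraph, u: str, v: str, metapath: MetaPath) -> int:
    mat, rows, cols = walk_count_matrix(graph, metapath)
    return int(mat[rows.index(u), cols.index(v)])


def _to_nx(graph: TypedGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(graph.type_of)
    g.add_edges_from(graph.edges)
    return g


def simple_paths(graph: TypedGraph, origin: str, destination: str, metapath: MetaPath) -> set[tuple[str, ...]]:
    """Repeat-free conforming paths via networkx's simple-path DFS.

    Round trips (origin == destination) are handled by searching to a
    duplicate of the origin attached to the same neighbors.
    """
    g = _to_nx(graph)
    length = metapath.n_edges
    target = destination
    if origin == destination:
        target = "__origin_copy__"
        g.add_node(target)
        g.add_edges_from((target, nbr) for nbr in list(g.neighbors(origin)))

    found = set()
    for p in nx.all_simple_paths(g, origin, target, cutoff=length):
        if len(p) != length + 1:
            continue
        p = tuple(origin if n == "__origin_copy__" else n for n in p)
        if all(graph.type_of[n] == t for n, t in zip(p, metapath.types)):
            found.add(p)
    return found


def typed_degree_from_edges(graph: TypedGraph, node: str, node_type: str) -> int:
    return sum(
        1
        for u, v in graph.edges
        if (u == node and graph.type_of[v] == node_type)
        or (v == node and graph.type_of[u] == node_type)
    )


def brute_pc(graph: TypedGraph, u: str, v: str, metapath: MetaPath) -> int:
    return len(simple_paths(graph, u, v, metapath))


def brute_npc(graph: TypedGraph, u: str, v: str, metapath: MetaPath) -> float:
    dests = sorted(n for n, t in graph.type_of.items() if t == metapath.types[-1])
    origs = sorted(n for n, t in graph.type_of.items() if t == metapath.types[0])
    out_u = sum(brute_pc(graph, u, d, metapath) for d in dests)
    into_v = sum(brute_pc(graph, o, v, metapath) for o in origs)
    pc = brute_pc(graph, u, v, metapath)
    return 0.0 if out_u + into_v == 0 else 2.0 * pc / (out_u + into_v)


def brute_dwpc(graph: TypedGraph, u: str, v: str, metapath: MetaPath, w: float) -> float:
    total = 0.0
    for p in simple_paths(graph, u, v, metapath):
        pdp = 1.0
        for i in range(len(p) - 1):
            d1 = typed_degree_from_edges(graph, p[i], metapath.types[i + 1])
            d2 = typed_degree_from_edges(graph, p[i + 1], metapath.types[i])
            pdp *= (d1 * d2) ** (-w)
        total += pdp
    return total


def brute_pathsim(graph: TypedGraph, u: str, v: str, metapath: MetaPath) -> float:
    mat, rows, cols = walk_count_matrix(graph, metapath)
    iu, iv = rows.index(u), rows.index(v)
    denom = mat[iu, cols.index(u)] + mat[iv, cols.index(v)]
    return 0.0 if denom == 0 else 2.0 * mat[iu, cols.index(v)] / denom
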