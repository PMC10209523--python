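"""Seeded synthetic knowledge graphs with a biomedical-style schema.

The generator emulates the shape of open biomedical KGs such as ogbl-biokg:
five node types (disease, drug, protein, function, side-effect) connected
by cross-type relations.  Topology is Erdos-Renyi per type pair — each
admissible node pair carries an edge independently with a per-type-pair
probability — which gives controllable density and exact expected edge
counts but NOT the heavy-tailed degree distributions of real biomedical
graphs (see docs/methods.md for what that implies for the tests built on
it).

Also provides FIX1, the small hand-built fixture every worked example and
regression test refers to, and a scaling harness that runs a fixed query
battery on graphs of increasing size.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .graph import TypedGraph, build_graph, precompute_adjacency
from .traversal import DEFAULT_WILDCARD_MAX_PATHS, MetaPath, count_paths

__all__ = [
    "SchemaSpec",
    "DEFAULT_TYPE_COUNTS",
    "DEFAULT_EDGE_DENSITY",
    "default_schema",
    "generate_kg",
    "fixture_fix1",
    "RDPF",
    "RDR",
    "scaling_harness",
]

#: Desk-scale defaults: five biokg-like types, dense enough for nontrivial
#: multi-step path structure yet small enough for exhaustive oracles.
DEFAULT_TYPE_COUNTS: dict[str, int] = {
    "disease": 50,
    "drug": 50,
    "protein": 50,
    "function": 50,
    "side-effect": 50,
}

DEFAULT_EDGE_DENSITY: dict[tuple[str, str], float] = {
    ("disease", "drug"): 0.05,
    ("disease", "protein"): 0.05,
    ("function", "protein"): 0.05,
    ("drug", "protein"): 0.03,
    ("drug", "side-effect"): 0.03,
    ("protein", "protein"): 0.02,
}

#: The canonical drug–disease–protein–function meta-path.
RDPF = MetaPath(("drug", "disease", "protein", "function"))
#: Palindromic drug–disease–drug meta-path (PathSim-compatible).
RDR = MetaPath(("drug", "disease", "drug"))


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class SchemaSpec:
    """Generator configuration: nodes per type, edge probability per type
    pair, and a seed.  Same spec => byte-identical graph."""

    type_counts: Mapping[str, int]
    edge_density: Mapping[tuple[str, str], float]
    seed: int = 0

    def __post_init__(self):
        for t, n in self.type_counts.items():
            if n < 0:
                raise ValueError(f"negative node count for type {t!r}")
        norm = {}
        for pair, p in self.edge_density.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"edge density for {pair} must be in [0,1], got {p}")
            norm[_pair_key(*pair)] = p
        object.__setattr__(self, "type_counts", dict(self.type_counts))
        object.__setattr__(self, "edge_density", norm)


def default_schema(seed: int = 0, scale: float = 1.0) -> SchemaSpec:
    """The default biokg-like schema, optionally scaled in node count."""
    counts = {t: max(1, int(round(n * scale))) for t, n in DEFAULT_TYPE_COUNTS.items()}
    return SchemaSpec(type_counts=counts, edge_density=DEFAULT_EDGE_DENSITY, seed=seed)


def generate_kg(spec: SchemaSpec) -> TypedGraph:
    """Sample a typed graph from the schema.

    Node ids are ``<type><index>`` (e.g. ``drug7``).  Type pairs are
    processed in sorted order and sampling is vectorized from a single
    ``numpy`` generator seeded by ``spec.seed``, so the output is fully
    deterministic.  Same-type pairs (if given a density) sample each
    unordered pair once.
    """
    rng = np.random.default_rng(spec.seed)
    ids = {
        t: [f"{t}{i}" for i in range(n)]
        for t, n in sorted(spec.type_counts.items())
    }
    type_rows = [(node, t) for t, nodes in ids.items() for node in nodes]

    edge_rows: list[tuple[str, str]] = []
    for (ta, tb) in sorted(spec.edge_density):
        p = spec.edge_density[(ta, tb)]
        if p == 0.0 or ta not in ids or tb not in ids:
            continue
        na, nb = len(ids[ta]), len(ids[tb])
        if na == 0 or nb == 0:
            continue
        draw = rng.random((na, nb))
        if ta == tb:
            ii, jj = np.nonzero(np.triu(draw < p, k=1))
        else:
            ii, jj = np.nonzero(draw < p)
        edge_rows.extend((ids[ta][i], ids[tb][j]) for i, j in zip(ii, jj))

    if not edge_rows:
        # degenerate but legal: an edgeless typed node set
        return TypedGraph(type_of=dict(type_rows), edges=frozenset())
    return build_graph(edge_rows, type_rows)


def fixture_fix1() -> TypedGraph:
    """The 7-node, 7-edge reference fixture used throughout the test-suite.

    Two drugs (r1, r2) share one disease (d1) which touches two proteins
    (p1, p2), both annotated to one function (f1); r2 additionally has one
    side-effect (s1).  Mirrors the motif of a drug connected to a pathway
    through disease-associated proteins.
    """
    types = [
        ("r1", "drug"), ("r2", "drug"),
        ("d1", "disease"),
        ("p1", "protein"), ("p2", "protein"),
        ("f1", "function"),
        ("s1", "side-effect"),
    ]
    edges = [
        ("r1", "d1"), ("r2", "d1"),
        ("d1", "p1"), ("d1", "p2"),
        ("p1", "f1"), ("p2", "f1"),
        ("r2", "s1"),
    ]
    return build_graph(edges, types)


def scaling_harness(
    sizes: Sequence[int],
    template: Optional[SchemaSpec] = None,
    metapath: MetaPath = RDPF,
    repetitions: int = 1,
    seed: int = 0,
    n_origins: int = 10,
) -> pd.DataFrame:
    """Run a fixed query battery on synthetic graphs of increasing size.

    For each total node count in ``sizes`` (stratified evenly across the
    schema's types) and each repetition, a graph is generated, indexed, and
    the first ``n_origins`` origin nodes are queried with wildcard
    ``count_paths`` along ``metapath``.  Returns one row per (size,
    repetition) with node/edge counts, total paths found, and wall time.
    Timings are informational only.
    """
    if list(sizes) != sorted(sizes):
        raise ValueError("sizes must be increasing")
    template = template if template is not None else default_schema()
    ntypes = len(template.type_counts)
    rows = []
    for size in sizes:
        per_type = max(1, size // ntypes)
        for rep in range(repetitions):
            spec = SchemaSpec(
                type_counts={t: per_type for t in template.type_counts},
                edge_density=template.edge_density,
                seed=seed + 1000 * rep + size,
            )
            t0 = time.perf_counter()
            graph = generate_kg(spec)
            index = precompute_adjacency(graph)
            origin_type = metapath.types[0]
            origins = sorted(n for n, t in graph.type_of.items() if t == origin_type)
            counts = [
                count_paths(index, o, "any", metapath) for o in origins[:n_origins]
            ]
            elapsed = time.perf_counter() - t0
            rows.append(
                {
                    "size": size,
                    "repetition": rep,
                    "nodes": graph.n_nodes,
                    "edges": graph.n_edges,
                    "total_paths": int(sum(counts)),
                    "truncated": any(c >= DEFAULT_WILDCARD_MAX_PATHS for c in counts),
                    "seconds": elapsed,
                }
            )
    return pd.DataFrame(rows)
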