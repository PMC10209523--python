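"""Reduce OGB-biokg-style entity triples to the node-typed edge form.

Open-graph-benchmark biomedical KGs store edges as (head entity, relation,
tail entity) with per-namespace integer indices: a drug and a protein may
share index 7.  This loader discards the relation (edge-typed meta-paths
are out of scope), prefixes each index with its entity-type namespace so
node ids are globally unique, and emits the combined 4-column typed-edge
rows that :func:`hetpaths.io.read_typed_edges` / :func:`build_graph`
consume.  Directed input relations are symmetrized implicitly because the
graph is undirected (reciprocal triples collapse to one edge).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence, Union

from .graph import TypedGraph, build_graph

__all__ = ["triples_to_typed_edges", "read_triples_tsv", "graph_from_triples"]

#: (head_type, head_index, relation, tail_type, tail_index)
Triple = tuple[str, Union[int, str], str, str, Union[int, str]]


def _node_id(entity_type: str, index) -> str:
    return f"{entity_type}:{index}"


def triples_to_typed_edges(
    triples: Iterable[Triple],
) -> list[tuple[str, str, str, str]]:
    """Convert triples to 4-column rows (source, source_type, target, target_type)."""
    rows = []
    for head_type, head_idx, _relation, tail_type, tail_idx in triples:
        rows.append(
            (_node_id(head_type, head_idx), head_type,
             _node_id(tail_type, tail_idx), tail_type)
        )
    return rows


def read_triples_tsv(path: Union[str, Path], delimiter: str = "\t") -> list[Triple]:
    """Read 5-column triple rows: head_type, head_index, relation, tail_type, tail_index."""
    triples: list[Triple] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter=delimiter):
            if not row or all(not c.strip() for c in row):
                continue
            ht, hi, rel, tt, ti = (c.strip() for c in row[:5])
            triples.append((ht, hi, rel, tt, ti))
    return triples


def graph_from_triples(triples: Iterable[Triple]) -> TypedGraph:
    """Build an undirected node-typed graph from entity triples."""
    edge_rows, type_rows = [], []
    for s, st, t, tt in triples_to_typed_edges(triples):
        edge_rows.append((s, t))
        type_rows.append((s, st))
        type_rows.append((t, tt))
    return build_graph(edge_rows, type_rows)
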