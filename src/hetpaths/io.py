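"""Reading and writing the delimited-text graph formats, meta-path parsing,
and the portable adjacency-index cache.

Formats (TSV by default, any single-character delimiter supported):

* edge list — two columns: source, target
* node types — two columns: node, type
* combined typed edges — four columns: source, source_type, target, target_type
* index cache — JSON with the source-graph fingerprint, so a stale cache is
  detectable
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from .errors import GraphValidationError, MetaPathError
from .graph import AdjacencyIndex, TypedGraph, build_graph
from .traversal import MetaPath

__all__ = [
    "read_edge_list",
    "read_type_table",
    "read_typed_edges",
    "write_edge_list",
    "write_type_table",
    "load_graph",
    "save_index",
    "load_index",
    "parse_metapath",
]

PathLike = Union[str, Path]


def _read_rows(path: PathLike, n_cols: int, delimiter: str, header: bool) -> list[tuple]:
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for lineno, row in enumerate(reader, start=1):
            if header and lineno == 1:
                continue
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < n_cols:
                raise GraphValidationError(
                    f"{path}:{lineno}: expected {n_cols} columns, got {len(row)}"
                )
            rows.append(tuple(c.strip() for c in row[:n_cols]))
    return rows


def read_edge_list(path: PathLike, delimiter: str = "\t", header: bool = False) -> list[tuple[str, str]]:
    return _read_rows(path, 2, delimiter, header)


def read_type_table(path: PathLike, delimiter: str = "\t", header: bool = False) -> list[tuple[str, str]]:
    return _read_rows(path, 2, delimiter, header)


def read_typed_edges(
    path: PathLike, delimiter: str = "\t", header: bool = False
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Read the combined 4-column form; returns (edge_rows, type_rows)."""
    edge_rows, type_rows = [], []
    for s, st, t, tt in _read_rows(path, 4, delimiter, header):
        edge_rows.append((s, t))
        type_rows.append((s, st))
        type_rows.append((t, tt))
    return edge_rows, type_rows


def write_edge_list(graph: TypedGraph, path: PathLike, delimiter: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["source", "target"])
        writer.writerows(graph.sorted_edges())


def write_type_table(graph: TypedGraph, path: PathLike, delimiter: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["node", "type"])
        writer.writerows((n, graph.type_of[n]) for n in sorted(graph.type_of))


def load_graph(
    edges: Optional[PathLike] = None,
    types: Optional[PathLike] = None,
    typed_edges: Optional[PathLike] = None,
    delimiter: str = "\t",
    header: bool = False,
) -> TypedGraph:
    """Load a graph from (edges + types) files or one combined typed-edges file."""
    if typed_edges is not None:
        if edges is not None or types is not None:
            raise GraphValidationError("pass either typed_edges or edges+types, not both")
        edge_rows, type_rows = read_typed_edges(typed_edges, delimiter, header)
    else:
        if edges is None or types is None:
            raise GraphValidationError("both an edge list and a type table are required")
        edge_rows = read_edge_list(edges, delimiter, header)
        type_rows = read_type_table(types, delimiter, header)
    return build_graph(edge_rows, type_rows)


def save_index(index: AdjacencyIndex, path: PathLike) -> None:
    """Serialize an adjacency index to portable JSON."""
    payload = {
        "fingerprint": index.source_graph_fingerprint,
        "type_of": dict(index.type_of),
        "index": {
            node: {t: list(nbrs) for t, nbrs in by_type.items()}
            for node, by_type in index.index.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=0, sort_keys=True)


def load_index(path: PathLike, expect_fingerprint: Optional[str] = None) -> AdjacencyIndex:
    with open(path) as fh:
        payload = json.load(fh)
    if expect_fingerprint is not None and payload["fingerprint"] != expect_fingerprint:
        raise GraphValidationError(
            f"index cache {path} was built from a different graph "
            f"(fingerprint mismatch)"
        )
    return AdjacencyIndex(
        index={
            node: {t: tuple(nbrs) for t, nbrs in by_type.items()}
            for node, by_type in payload["index"].items()
        },
        type_of=payload["type_of"],
        source_graph_fingerprint=payload["fingerprint"],
    )


def parse_metapath(text: str, aliases: Optional[Mapping[str, str]] = None) -> MetaPath:
    """Parse a comma-separated type sequence, e.g. ``drug,disease,protein``.

    With an alias table (e.g. ``{"R": "drug"}``), single-character tokens
    are resolved through it; an unresolvable single-character token is an
    error, longer tokens are taken literally.
    """
    tokens = [t.strip() for t in text.split(",") if t.strip()]
    if len(tokens) < 2:
        raise MetaPathError(
            f"a meta-path needs at least 2 comma-separated types, got {text!r}"
        )
    resolved = []
    for tok in tokens:
        if aliases is not None and tok in aliases:
            resolved.append(aliases[tok])
        elif aliases is not None and len(tok) == 1:
            raise MetaPathError(f"unknown meta-path alias {tok!r}")
        else:
            resolved.append(tok)
    return MetaPath(tuple(resolved))
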