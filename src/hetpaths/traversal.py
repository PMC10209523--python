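"""Meta-path definition and typed path enumeration.

A meta-path is an ordered sequence of node types (e.g. drug–disease–
protein–function) prescribing which walks through the graph are admissible.
Enumeration expands the type sequence step by step from the origin using
typed neighbor lookups, keeping only sequences whose final node matches the
requested destination.

Two path semantics are exposed:

* default (``allow_repeats=False``): *paths* — no node id may occur twice,
  except that the first and last node may coincide (round trips, needed for
  self-counts of palindromic meta-paths);
* ``allow_repeats=True``: *walks* — no repetition restriction.  Walk counts
  equal entries of the product of per-step typed biadjacency matrices,
  which is the independent oracle used in the test-suite.

Enumeration is iterative (explicit stack), so meta-path length is not
limited by Python's recursion depth, and results are emitted in
lexicographic order of the node sequences because neighbor lists are
sorted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence, Union

from .errors import MetaPathError, UnknownNodeError
from .graph import AdjacencyIndex

__all__ = [
    "ANY",
    "MetaPath",
    "PathSet",
    "enumerate_paths",
    "enumerate_from",
    "count_paths",
    "DEFAULT_WILDCARD_MAX_PATHS",
]

#: Wildcard endpoint marker accepted by :func:`count_paths`.
ANY = "any"

#: Per-origin enumeration cap for wildcard queries (never silent: results
#: carry a ``truncated`` flag).  Pair queries are uncapped by default.
DEFAULT_WILDCARD_MAX_PATHS = 10**6

PathInstance = tuple[str, ...]


@dataclass(frozen=True)
class MetaPath:
    """An ordered sequence of node-type labels; L+1 types describe L edges."""

    types: tuple[str, ...]

    def __post_init__(self):
        if len(self.types) < 2:
            raise MetaPathError(
                f"a meta-path needs at least 2 node types, got {list(self.types)!r}"
            )
        if any(not t for t in self.types):
            raise MetaPathError(f"empty type label in meta-path {list(self.types)!r}")
        object.__setattr__(self, "types", tuple(self.types))

    @classmethod
    def of(cls, *types: str) -> "MetaPath":
        return cls(tuple(types))

    @property
    def n_edges(self) -> int:
        return len(self.types) - 1

    @property
    def is_symmetric(self) -> bool:
        """True for palindromic meta-paths (equal to their own reversal)."""
        return self.types == self.types[::-1]

    def reverse(self) -> "MetaPath":
        return MetaPath(self.types[::-1])

    def __str__(self) -> str:
        return ",".join(self.types)

    def __len__(self) -> int:
        return len(self.types)


@dataclass(frozen=True)
class PathSet:
    """Enumerated path instances plus a truncation flag.

    Behaves as a sequence of node-id tuples.  ``truncated`` is True when a
    ``max_paths`` cap stopped enumeration early — never silently.
    """

    paths: tuple[PathInstance, ...]
    truncated: bool = False

    def __iter__(self) -> Iterator[PathInstance]:
        return iter(self.paths)

    def __len__(self) -> int:
        return len(self.paths)

    def __getitem__(self, i):
        return self.paths[i]


def _check_endpoint(index: AdjacencyIndex, node: str, expected_type: str, role: str) -> None:
    actual = index.type_of_node(node)  # raises UnknownNodeError
    if actual != expected_type:
        raise MetaPathError(
            f"{role} node {node!r} has type {actual!r} but the meta-path "
            f"requires {expected_type!r}"
        )


def _walk(
    index: AdjacencyIndex,
    origin: str,
    metapath: MetaPath,
    destination: Optional[str],
    allow_repeats: bool,
    max_paths: Optional[int],
    collect: bool,
) -> tuple[list[PathInstance], int, bool]:
    """Core DFS over the type sequence.

    Returns (collected paths, count, truncated).  With ``collect=False``
    paths are not materialized (pure counting).  ``destination=None`` keeps
    every completed sequence (wildcard).
    """
    types = metapath.types
    last = len(types) - 1
    path: list[str] = [origin]
    iters: list[Iterator[str]] = [iter(index.neighbors(origin, types[1]))]
    found: list[PathInstance] = []
    count = 0
    truncated = False

    while iters:
        step = next(iters[-1], None)
        if step is None:
            iters.pop()
            path.pop()
            continue
        depth = len(iters)  # position `step` would occupy
        if not allow_repeats and step in path:
            # repetition is legal only as a round trip: final node == origin
            if not (depth == last and step == origin):
                continue
        if depth == last:
            if destination is None or step == destination:
                count += 1
                if collect:
                    found.append(tuple(path) + (step,))
                if max_paths is not None and count >= max_paths:
                    truncated = True
                    break
            continue
        path.append(step)
        iters.append(iter(index.neighbors(step, types[depth + 1])))

    return found, count, truncated


def enumerate_paths(
    index: AdjacencyIndex,
    origin: str,
    destination: str,
    metapath: MetaPath,
    allow_repeats: bool = False,
    max_paths: Optional[int] = None,
) -> PathSet:
    """All path instances from ``origin`` to ``destination`` conforming to
    ``metapath``, in lexicographic order of their node sequences.

    Raises :class:`MetaPathError` if either endpoint's type does not match
    the corresponding end of the meta-path, :class:`UnknownNodeError` for
    missing nodes.
    """
    _check_endpoint(index, origin, metapath.types[0], "origin")
    _check_endpoint(index, destination, metapath.types[-1], "destination")
    found, _, truncated = _walk(
        index, origin, metapath, destination, allow_repeats, max_paths, collect=True
    )
    return PathSet(tuple(found), truncated)


def enumerate_from(
    index: AdjacencyIndex,
    origin: str,
    metapath: MetaPath,
    allow_repeats: bool = False,
    max_paths: Optional[int] = DEFAULT_WILDCARD_MAX_PATHS,
) -> dict[str, PathSet]:
    """Conforming paths from ``origin`` to every reachable destination,
    grouped by destination node."""
    _check_endpoint(index, origin, metapath.types[0], "origin")
    found, _, truncated = _walk(
        index, origin, metapath, None, allow_repeats, max_paths, collect=True
    )
    grouped: dict[str, list[PathInstance]] = {}
    for p in found:
        grouped.setdefault(p[-1], []).append(p)
    return {dest: PathSet(tuple(ps), truncated) for dest, ps in grouped.items()}


def count_paths(
    index: AdjacencyIndex,
    origin: str,
    destination: str,
    metapath: MetaPath,
    allow_repeats: bool = False,
    max_paths: Optional[int] = None,
) -> int:
    """Number of conforming path instances, without materializing them.

    Either endpoint may be the wildcard ``"any"`` (or ``None``): a wildcard
    destination counts all paths leaving ``origin`` along the meta-path; a
    wildcard origin counts all paths reaching ``destination``, computed by
    traversing the reversed meta-path from ``destination``.
    """
    origin_any = origin in (ANY, None)
    dest_any = destination in (ANY, None)
    if origin_any and dest_any:
        raise MetaPathError("at most one endpoint of a count query may be the wildcard")
    if origin_any:
        return count_paths(
            index, destination, ANY, metapath.reverse(), allow_repeats, max_paths
        )
    _check_endpoint(index, origin, metapath.types[0], "origin")
    if dest_any:
        if max_paths is None:
            max_paths = DEFAULT_WILDCARD_MAX_PATHS
        target = None
    else:
        _check_endpoint(index, destination, metapath.types[-1], "destination")
        target = destination
    _, count, _ = _walk(
        index, origin, metapath, target, allow_repeats, max_paths, collect=False
    )
    return count
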