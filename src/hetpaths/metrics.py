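"""Meta-path similarity metrics for node pairs.

Built-in metrics over one meta-path M between nodes u, v:

* ``pc``  — Path Count: PC(u,v|M), the number of conforming path instances
  (repeat-free semantics).
* ``npc`` — Normalized Path Count:
  ``2*PC(u,v|M) / (PC(u,*|M) + PC(*,v|M))``, where PC(u,*) counts all paths
  leaving u along M and PC(*,v) all paths reaching v along M (equivalently
  leaving v along reversed M).  0/0 -> 0.  Always in [0,1] because the
  numerator paths are contained in both marginals.
* ``dwpc`` — Degree-Weighted Path Count: sum over conforming paths of the
  path-degree product ``PDP(p) = prod over edges (n_i, n_{i+1}) of
  [d_{T_{i+1}}(n_i) * d_{T_i}(n_{i+1})]**(-w)`` with ``d_T(n)`` the typed
  degree of n toward type T; the damping exponent ``w`` (default 0.4)
  discounts paths through high-degree hubs.  ``w=0`` reduces exactly to PC.
* ``pathsim`` — ``2*PC(u,v|M) / (PC(u,u|M) + PC(v,v|M))`` for palindromic
  (symmetric) M, a peer-similarity in [0,1].  PathSim counts walk-semantics
  path instances (node repetition allowed), the semantics under which the
  Gram-matrix argument guarantees the [0,1] bound; see docs/methods.md.

NPC and DWPC follow the normalization and degree-damping scheme of the
hetnet edge-prediction literature (Himmelstein & Baranzini 2015); PathSim
follows Sun et al. 2011.  Each formula lives in its own scorer function so
an alternative convention is a one-line change.

Custom metrics are registered by name next to the built-ins and receive the
enumerated paths plus a :class:`MetricContext` able to answer typed-degree
and wildcard-count queries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

from .errors import MetaPathError, MetricError
from .graph import AdjacencyIndex
from .traversal import ANY, MetaPath, PathSet, count_paths, enumerate_paths

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityResult",
    "MetricSpec",
    "MetricContext",
    "MetricRegistry",
    "default_registry",
    "register_metric",
    "path_count",
    "normalized_path_count",
    "dwpc",
    "pathsim",
    "score_pair",
    "DEFAULT_DWPC_EXPONENT",
]

DEFAULT_DWPC_EXPONENT = 0.4


@dataclass(frozen=True)
class SimilarityResult:
    """A scored node pair: metric score plus the supporting path count."""

    origin: str
    destination: str
    metapath: MetaPath
    metric: str
    score: float
    path_count: int
    truncated: bool = False


class MetricContext:
    """Shared traversal context for metric evaluation.

    Caches pair enumerations and wildcard counts so that scoring several
    metrics on the same (u, v, M) triple traverses the graph once, and
    exposes the typed-degree and count queries custom metrics may need.
    """

    def __init__(self, index: AdjacencyIndex, max_paths: Optional[int] = None):
        self.index = index
        self.max_paths = max_paths
        self._path_cache: dict = {}
        self._count_cache: dict = {}

    def paths(self, u: str, v: str, metapath: MetaPath, allow_repeats: bool = False) -> PathSet:
        key = (u, v, metapath.types, allow_repeats)
        if key not in self._path_cache:
            self._path_cache[key] = enumerate_paths(
                self.index, u, v, metapath,
                allow_repeats=allow_repeats, max_paths=self.max_paths,
            )
        return self._path_cache[key]

    def count(self, u: str, v: str, metapath: MetaPath, allow_repeats: bool = False) -> int:
        """PC(u,v|M); either endpoint may be the wildcard ``"any"``."""
        key = (u, v, metapath.types, allow_repeats)
        if key not in self._count_cache:
            if u not in (ANY, None) and v not in (ANY, None):
                self._count_cache[key] = len(self.paths(u, v, metapath, allow_repeats))
            else:
                self._count_cache[key] = count_paths(
                    self.index, u, v, metapath, allow_repeats=allow_repeats
                )
        return self._count_cache[key]

    def typed_degree(self, node: str, node_type: str) -> int:
        return len(self.index.neighbors(node, node_type))


#: Scorer contract: (ctx, u, v, metapath, paths, **params) -> non-negative score.
Scorer = Callable[..., float]


@dataclass(frozen=True)
class MetricSpec:
    name: str
    scorer: Scorer
    requires_symmetric_metapath: bool = False
    #: enumerate supporting paths as walks (repetition allowed) — PathSim only
    walk_semantics: bool = False


class MetricRegistry:
    """Name -> :class:`MetricSpec` mapping with collision checking."""

    def __init__(self):
        self._specs: dict[str, MetricSpec] = {}

    def register(self, spec: MetricSpec) -> "MetricRegistry":
        if spec.name in self._specs:
            raise MetricError(f"metric name {spec.name!r} is already registered")
        self._specs[spec.name] = spec
        return self

    def get(self, name: str) -> MetricSpec:
        try:
            return self._specs[name]
        except KeyError:
            raise MetricError(
                f"unknown metric {name!r}; registered metrics: "
                f"{{{', '.join(sorted(self._specs))}}}"
            ) from None

    def names(self) -> list[str]:
        return sorted(self._specs)

    def __contains__(self, name: str) -> bool:
        return name in self._specs


def _score_pc(ctx: MetricContext, u: str, v: str, metapath: MetaPath, paths: PathSet) -> float:
    return float(len(paths))


def _score_npc(ctx: MetricContext, u: str, v: str, metapath: MetaPath, paths: PathSet) -> float:
    pc = len(paths)
    out_u = ctx.count(u, ANY, metapath)
    into_v = ctx.count(ANY, v, metapath)
    denom = out_u + into_v
    return 0.0 if denom == 0 else 2.0 * pc / denom


def _score_dwpc(
    ctx: MetricContext, u: str, v: str, metapath: MetaPath, paths: PathSet,
    w: float = DEFAULT_DWPC_EXPONENT,
) -> float:
    if not 0.0 <= w <= 1.0:
        raise MetricError(f"DWPC damping exponent must lie in [0, 1], got {w}")
    types = metapath.types
    total = 0.0
    for p in paths:
        pdp = 1.0
        for i in range(len(p) - 1):
            # typed degrees along the step: each endpoint's degree toward
            # the other endpoint's step type (not total degree)
            d_fwd = ctx.typed_degree(p[i], types[i + 1])
            d_back = ctx.typed_degree(p[i + 1], types[i])
            pdp *= (d_fwd * d_back) ** (-w)
        total += pdp
    return total


def _score_pathsim(
    ctx: MetricContext, u: str, v: str, metapath: MetaPath, paths: PathSet,
    force: bool = False,
) -> float:
    m = metapath
    if not m.is_symmetric:
        if not force:
            raise MetaPathError(
                f"PathSim requires a symmetric (palindromic) meta-path; "
                f"{m} reversed is {m.reverse()} — pass force=True to use the "
                f"round trip M + reverse(M) instead"
            )
        m = MetaPath(m.types + m.reverse().types[1:])
    # walk semantics: repetition allowed (keeps the score in [0,1])
    pc_uv = ctx.count(u, v, m, allow_repeats=True)
    pc_uu = ctx.count(u, u, m, allow_repeats=True)
    pc_vv = ctx.count(v, v, m, allow_repeats=True)
    denom = pc_uu + pc_vv
    return 0.0 if denom == 0 else 2.0 * pc_uv / denom


def default_registry() -> MetricRegistry:
    """Registry pre-loaded with the built-in metrics pc, npc, dwpc, pathsim."""
    reg = MetricRegistry()
    reg.register(MetricSpec("pc", _score_pc))
    reg.register(MetricSpec("npc", _score_npc))
    reg.register(MetricSpec("dwpc", _score_dwpc))
    reg.register(
        MetricSpec(
            "pathsim", _score_pathsim,
            requires_symmetric_metapath=True, walk_semantics=True,
        )
    )
    return reg


def register_metric(registry: MetricRegistry, spec: MetricSpec) -> MetricRegistry:
    """Add a custom metric; duplicate names are an error."""
    return registry.register(spec)


def score_pair(
    ctx: MetricContext,
    u: str,
    v: str,
    metapath: MetaPath,
    metric: str = "pc",
    registry: Optional[MetricRegistry] = None,
    **params,
) -> SimilarityResult:
    """Dispatch one metric by name on a node pair.

    The context's caches ensure that scoring several metrics on the same
    pair shares a single traversal.
    """
    registry = registry if registry is not None else default_registry()
    spec = registry.get(metric)
    effective = metapath
    if spec.requires_symmetric_metapath and not metapath.is_symmetric:
        if not params.get("force"):
            raise MetaPathError(
                f"metric {metric!r} requires a symmetric (palindromic) meta-path; "
                f"{metapath} reversed is {metapath.reverse()} — pass force=True "
                f"to use the round trip M + reverse(M) instead"
            )
        effective = MetaPath(metapath.types + metapath.reverse().types[1:])
    pset = ctx.paths(u, v, effective, allow_repeats=spec.walk_semantics)
    score = spec.scorer(ctx, u, v, effective, pset, **params)
    return SimilarityResult(
        origin=u, destination=v, metapath=metapath, metric=metric,
        score=float(score), path_count=len(pset), truncated=pset.truncated,
    )


# ------------------------------------------------------------------ direct
# named entry points mirroring the registry, convenient for library use

def path_count(ctx: MetricContext, u: str, v: str, metapath: MetaPath) -> SimilarityResult:
    return score_pair(ctx, u, v, metapath, "pc")


def normalized_path_count(ctx: MetricContext, u: str, v: str, metapath: MetaPath) -> SimilarityResult:
    return score_pair(ctx, u, v, metapath, "npc")


def dwpc(
    ctx: MetricContext, u: str, v: str, metapath: MetaPath,
    w: float = DEFAULT_DWPC_EXPONENT,
) -> SimilarityResult:
    return score_pair(ctx, u, v, metapath, "dwpc", w=w)


def pathsim(
    ctx: MetricContext, u: str, v: str, metapath: MetaPath, force: bool = False
) -> SimilarityResult:
    return score_pair(ctx, u, v, metapath, "pathsim", force=force)
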