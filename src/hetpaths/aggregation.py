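"""Set-level similarity: aggregate pairwise metric scores over two node sets.

Given node sets A and B whose members match the two ends of a meta-path,
the full |A| x |B| matrix of pairwise scores is computed and reduced with
an order-statistic aggregator (mean by default).  The pair matrix is always
returned so callers can apply their own reduction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import MetaPathError
from .metrics import MetricContext, MetricRegistry, score_pair
from .traversal import MetaPath

logger = logging.getLogger(__name__)

__all__ = ["AGGREGATORS", "SetSimilarityResult", "set_similarity"]

AGGREGATORS = {
    "mean": np.mean,
    "median": np.median,
    "max": np.max,
    "min": np.min,
}


@dataclass(frozen=True)
class SetSimilarityResult:
    set_a: tuple[str, ...]
    set_b: tuple[str, ...]
    metapath: MetaPath
    metric: str
    aggregator: str
    score: float
    #: rows indexed by set_a, columns by set_b; entry (i, j) = score(a_i, b_j)
    pair_matrix: pd.DataFrame


def _prepare_set(nodes: Sequence[str], label: str) -> list[str]:
    if not nodes:
        raise MetaPathError(f"node set {label} is empty")
    seen: list[str] = []
    for n in nodes:
        if n in seen:
            logger.warning("duplicate node %r in set %s dropped", n, label)
        else:
            seen.append(n)
    return seen


def set_similarity(
    ctx: MetricContext,
    set_a: Sequence[str],
    set_b: Sequence[str],
    metapath: MetaPath,
    metric: str = "pc",
    aggregator: str = "mean",
    registry: Optional[MetricRegistry] = None,
    **params,
) -> SetSimilarityResult:
    """Aggregate pairwise similarity between two node sets.

    Every node in ``set_a`` must carry the meta-path's first type and every
    node in ``set_b`` its last type (checked pairwise by the metric calls,
    which name the offending node).  Duplicates within a set are dropped
    with a warning so no pair is silently double-weighted.
    """
    if aggregator not in AGGREGATORS:
        raise MetaPathError(
            f"unknown aggregator {aggregator!r}; choose from {sorted(AGGREGATORS)}"
        )
    a = _prepare_set(set_a, "A")
    b = _prepare_set(set_b, "B")
    scores = np.empty((len(a), len(b)), dtype=float)
    for i, u in enumerate(a):
        for j, v in enumerate(b):
            scores[i, j] = score_pair(
                ctx, u, v, metapath, metric, registry=registry, **params
            ).score
    matrix = pd.DataFrame(scores, index=a, columns=b)
    return SetSimilarityResult(
        set_a=tuple(a),
        set_b=tuple(b),
        metapath=metapath,
        metric=metric,
        aggregator=aggregator,
        score=float(AGGREGATORS[aggregator](scores)),
        pair_matrix=matrix,
    )
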