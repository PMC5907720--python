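"""Collective feature selection: top-k% per ranker, unioned across rankers.

The central idea: no single feature-selection algorithm is specialised for
every genetic architecture, so instead of betting on one method, take the
union of the top user-defined percentage of features from several
heterogeneous methods.  By set inclusion the union's sensitivity can never
fall below the best single method's — the cost is extra false positives,
bounded by (number of methods) x k.
"""

from __future__ import annotations

import math
from typing import Sequence

from .dataio import FeatureRanking, SelectionResult

__all__ = ["top_fraction", "collective_union"]


def top_k(percentage: float, n_features: int) -> int:
    """Selection size: round-half-up of p% of n, floored at 1."""
    if not 0 < percentage <= 100:
        raise ValueError(f"percentage must be in (0, 100], got {percentage}")
    return max(1, int(math.floor(percentage / 100.0 * n_features + 0.5)))


def top_fraction(ranking: FeatureRanking, percentage: float) -> tuple[str, ...]:
    """The top p% features of a ranking, in rank order."""
    k = top_k(percentage, ranking.n_features)
    return ranking.order[:k]


def collective_union(
    rankings: Sequence[FeatureRanking], percentage: float
) -> SelectionResult:
    """Per-method top-p% sets with their union and intersection."""
    if not rankings:
        raise ValueError("need at least one ranking")
    universe = set(rankings[0].order)
    for r in rankings[1:]:
        if set(r.order) != universe:
            raise ValueError(
                f"ranking {r.method!r} covers a different feature universe"
            )
    per_method: dict[str, frozenset[str]] = {}
    for r in rankings:
        if r.method in per_method:
            raise ValueError(f"duplicate method name {r.method!r}")
        per_method[r.method] = frozenset(top_fraction(r, percentage))
    union: frozenset[str] = frozenset().union(*per_method.values())
    intersection = frozenset(
        set.intersection(*(set(s) for s in per_method.values()))
    )
    provenance = {
        f: frozenset(m for m, s in per_method.items() if f in s) for f in union
    }
    return SelectionResult(
        percentage=float(percentage),
        per_method=per_method,
        union_set=union,
        intersection_set=intersection,
        provenance=provenance,
    )
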