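"""Relief-family scorers: MultiSURF* and the recursive TuRF wrapper.

MultiSURF* extends SURF* with per-instance distance thresholds: for each
target instance the mean distance ``T_i`` to all other instances defines a
threshold, and a dead band of half-width ``sigma_i / 2`` (the standard
deviation of those distances) excludes ambiguous neighbours.  Instances
closer than the band are *near*, farther are *far*, and attribute weights
update with the conventional sign for near pairs (hits down, misses up)
and the inverted sign for far pairs (hits up, misses down) — the far-pair
inversion is what lets the scorer reward attributes whose values agree
between dissimilar same-class instances.

Attribute differences are range-normalised (|a - b| / 2 for 0/1/2
genotypes), instance distance is the mean attribute difference, and final
scores are divided by the number of instances.

TuRF (tuned Relief) wraps any ranker: it repeatedly re-scores the
surviving features and discards a fixed fraction of the weakest, so noise
attributes stop diluting the Relief distance metric as iterations proceed.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Callable

import numpy as np

from ..dataio import FeatureRanking, SimulatedDataset

__all__ = ["multisurf_star_rank", "turf_wrap"]

_ABSDIFF = np.abs(np.arange(3)[:, None] - np.arange(3)[None, :]).astype(float)


def _one_hot_f32(values: np.ndarray) -> np.ndarray:
    n, p = values.shape
    out = np.zeros((n, 3, p), dtype=np.float32)
    out[np.arange(n)[:, None], values, np.arange(p)[None, :]] = 1.0
    return out


def multisurf_star_rank(dataset: SimulatedDataset) -> FeatureRanking:
    """MultiSURF* attribute weights, vectorised over instance pairs."""
    X = dataset.genotypes.values
    y = dataset.phenotype.labels
    n, p = X.shape
    if n < 3:
        raise ValueError("MultiSURF* needs at least 3 instances")
    onehot = _one_hot_f32(X)  # (n, 3, p)
    flat = onehot.reshape(n, 3 * p)
    # pairwise mean attribute difference via genotype-pair counts:
    # d(i,j) = sum_{g,h} |g-h|/2 * #{a : x_ia=g, x_ja=h} / p
    D = np.zeros((n, n), dtype=np.float32)
    for g in range(3):
        for h in range(3):
            if _ABSDIFF[g, h]:
                D += (_ABSDIFF[g, h] / 2.0) * (onehot[:, g, :] @ onehot[:, h, :].T)
    D /= p
    np.fill_diagonal(D, 0.0)
    # per-target threshold and dead band over the n-1 off-diagonal distances
    row_sum = D.sum(axis=1)
    T = row_sum / (n - 1)
    sq = (D * D).sum(axis=1)
    var = sq / (n - 1) - T * T
    sigma = np.sqrt(np.maximum(var, 0.0))
    near = D < (T - sigma / 2.0)[:, None]
    far = D > (T + sigma / 2.0)[:, None]
    np.fill_diagonal(near, False)
    # pair sign: +1 near-miss / far-hit, -1 near-hit / far-miss, 0 ignored
    miss = (y[:, None] != y[None, :]).astype(np.float32) * 2.0 - 1.0
    C = miss * (near.astype(np.float32) - far.astype(np.float32))
    # score_a = sum_{i,j} C_ij * |x_ia - x_ja| / 2, accumulated per genotype pair
    CS = C @ flat  # (n, 3p) : CS[i, (g,a)] = sum_j C_ij 1[x_ja = g]
    CS = CS.reshape(n, 3, p)
    scores = np.zeros(p, dtype=np.float64)
    for g in range(3):
        for h in range(3):
            if _ABSDIFF[g, h]:
                scores += (_ABSDIFF[g, h] / 2.0) * np.einsum(
                    "ia,ia->a", onehot[:, g, :], CS[:, h, :], dtype=np.float64
                )
    scores /= n
    return FeatureRanking.from_scores(
        "multisurf_star", dataset.genotypes.feature_ids, scores
    )


def turf_wrap(
    base_ranker: Callable[[SimulatedDataset], FeatureRanking],
    dataset: SimulatedDataset,
    drop_fraction: float = 0.10,
    min_features: int = 10,
    method_name: str | None = None,
) -> FeatureRanking:
    """Recursive feature elimination around ``base_ranker``.

    Each pass re-ranks the survivors and removes ``floor(drop_fraction *
    current)`` (at least 1) of the lowest-scoring features until at most
    ``min_features`` remain.  The final order lists survivors by their
    last-pass scores, then removed features in reverse order of removal.
    Scores in the returned ranking are ordinal (n-1 .. 0) because raw
    scores from different passes are not comparable.
    """
    if not 0 < drop_fraction < 1:
        raise ValueError("drop_fraction must be in (0, 1)")
    if min_features < 1:
        raise ValueError("min_features must be >= 1")
    fids = list(dataset.genotypes.feature_ids)
    index_of = {fid: i for i, fid in enumerate(fids)}
    surviving = list(range(len(fids)))
    removed_stack: list[list[int]] = []  # batches, earliest removal first
    last_ranking: FeatureRanking | None = None
    while len(surviving) > min_features:
        sub = replace(
            dataset, genotypes=dataset.genotypes.subset_features(surviving), truth=None
        )
        last_ranking = base_ranker(sub)
        n_rm = max(1, int(np.floor(drop_fraction * len(surviving))))
        worst = [index_of[fid] for fid in last_ranking.order[-n_rm:]]
        removed_stack.append(worst)
        surviving = [i for i in surviving if i not in set(worst)]
    if last_ranking is not None and surviving:
        keep = set(fids[i] for i in surviving)
        head = [index_of[fid] for fid in last_ranking.order if fid in keep]
    else:  # nothing ever removed: rank once and use it whole
        last_ranking = base_ranker(dataset)
        head = [index_of[fid] for fid in last_ranking.order]
        removed_stack = []
    order_idx = head + [i for batch in reversed(removed_stack) for i in batch]
    n = len(fids)
    scores = np.empty(n)
    for rank_pos, i in enumerate(order_idx):
        scores[i] = float(n - 1 - rank_pos)
    name = method_name or f"turf:{getattr(last_ranking, 'method', 'base')}"
    return FeatureRanking.from_scores(name, fids, scores)
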