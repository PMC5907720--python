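"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the vectorised code paths of the package: MDR is
recounted cell by cell with dictionaries, and MultiSURF* follows the
pairwise pseudocode literally, instance by instance.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def mdr_oracle(X: np.ndarray, y: np.ndarray, max_order: int = 2) -> dict:
    """Balanced accuracy of every 1- and 2-locus MDR model, by brute force.

    Returns {loci_tuple (column indices): balanced_accuracy}.
    """
    n, p = X.shape
    n_case = int((y == 1).sum())
    n_ctrl = int((y == 0).sum())
    overall = n_case / n_ctrl
    out = {}
    loci_sets = [(j,) for j in range(p)]
    if max_order >= 2:
        loci_sets += list(combinations(range(p), 2))
    for loci in loci_sets:
        cells: dict[tuple, list[int]] = {}
        for i in range(n):
            key = tuple(int(X[i, j]) for j in loci)
            cells.setdefault(key, [0, 0])[int(y[i])] += 1
        tp = tn = 0
        for (ctrl_count, case_count) in cells.values():
            # high-risk iff case:control ratio strictly exceeds the overall
            # ratio; empty-control cells with cases are high; ties are low
            if ctrl_count == 0:
                high = case_count > 0
            else:
                high = case_count / ctrl_count > overall
            if high:
                tp += case_count
            else:
                tn += ctrl_count
        out[loci] = 0.5 * (tp / n_case + tn / n_ctrl)
    return out


def multisurf_star_oracle(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Literal pairwise MultiSURF* scoring, without vectorisation."""
    n, p = X.shape
    scores = np.zeros(p)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                dist[i, j] = sum(
                    abs(float(X[i, a]) - float(X[j, a])) / 2.0 for a in range(p)
                ) / p
    for i in range(n):
        others = [dist[i, j] for j in range(n) if j != i]
        T = sum(others) / len(others)
        sigma = float(np.std(others))  # population sd
        for j in range(n):
            if j == i:
                continue
            d = dist[i, j]
            if d < T - sigma / 2.0:
                zone = "near"
            elif d > T + sigma / 2.0:
                zone = "far"
            else:
                continue
            same = y[i] == y[j]
            for a in range(p):
                diff = abs(float(X[i, a]) - float(X[j, a])) / 2.0
                if zone == "near":
                    scores[a] += -diff if same else diff
                else:
                    scores[a] += diff if same else -diff
    return scores / n
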