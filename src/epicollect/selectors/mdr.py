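"""Multifactor dimensionality reduction (MDR) as an exhaustive filter.

Every one-locus and two-locus genotype-cell model is evaluated on the
training data without cross-validation: a cell is labelled high-risk when
its case:control ratio strictly exceeds the dataset-wide ratio (ties and
empty cells are low-risk), and the model is scored by training balanced
accuracy.  A feature's rank score is the best balanced accuracy over all
models that contain it.

The implementation counts all C(p,2) joint genotype tables with one
one-hot matrix product, so the exhaustive scan stays fast even at
thousands of pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..dataio import FeatureRanking, SimulatedDataset

__all__ = ["MDRModel", "mdr_rank"]


@dataclass(frozen=True)
class MDRModel:
    """One evaluated MDR model: its loci, cell labels, and training BA."""

    loci: tuple[str, ...]
    cell_labels: dict[tuple[int, ...], str]
    balanced_accuracy: float


def _one_hot(values: np.ndarray) -> np.ndarray:
    """(n, p) genotypes -> (n, 3p) float one-hot, feature-major blocks."""
    n, p = values.shape
    out = np.zeros((n, 3 * p), dtype=np.float64)
    cols = 3 * np.arange(p)[None, :] + values
    out[np.arange(n)[:, None], cols] = 1.0
    return out


def mdr_rank(
    dataset: SimulatedDataset, max_order: int = 2, collect_models: bool = True
) -> tuple[FeatureRanking, list[MDRModel]]:
    """Rank features by their best MDR training balanced accuracy.

    Returns the ranking and (unless ``collect_models=False``) all
    evaluated models sorted by balanced accuracy, best first.
    """
    if max_order not in (1, 2):
        raise ValueError("max_order must be 1 or 2")
    X = dataset.genotypes.values
    y = dataset.phenotype.labels
    n, p = X.shape
    n_case = int(y.sum())
    n_ctrl = n - n_case
    onehot = _one_hot(X)
    case_counts = onehot[y == 1].sum(axis=0).reshape(p, 3)
    ctrl_counts = onehot[y == 0].sum(axis=0).reshape(p, 3)

    def ba_from_counts(ca: np.ndarray, co: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Balanced accuracy over the trailing cell axes; returns (ba, high)."""
        high = ca * n_ctrl > co * n_case  # strict ratio rule; empty cells low
        axes = tuple(range(ca.ndim - 2, ca.ndim)) if ca.ndim > 2 else -1
        tpr = (ca * high).sum(axis=axes) / n_case
        tnr = (co * ~high).sum(axis=axes) / n_ctrl
        return (tpr + tnr) / 2.0, high

    ba1, high1 = ba_from_counts(case_counts, ctrl_counts)
    best = ba1.copy()

    ba2 = high2 = None
    if max_order == 2 and p >= 2:
        case_joint = (onehot[y == 1].T @ onehot[y == 1]).reshape(p, 3, p, 3)
        ctrl_joint = (onehot[y == 0].T @ onehot[y == 0]).reshape(p, 3, p, 3)
        ca = case_joint.transpose(0, 2, 1, 3)  # (p, p, 3, 3)
        co = ctrl_joint.transpose(0, 2, 1, 3)
        ba2, high2 = ba_from_counts(ca, co)
        iu = np.triu_indices(p, k=1)
        pair_best = np.full(p, -np.inf)
        vals = ba2[iu]
        np.maximum.at(pair_best, iu[0], vals)
        np.maximum.at(pair_best, iu[1], vals)
        best = np.maximum(best, pair_best)

    fids = dataset.genotypes.feature_ids
    ranking = FeatureRanking.from_scores("mdr", fids, best)

    models: list[MDRModel] = []
    if collect_models:
        for j in range(p):
            labels = {(g,): ("high" if high1[j, g] else "low") for g in range(3)}
            models.append(MDRModel((fids[j],), labels, float(ba1[j])))
        if ba2 is not None:
            for j in range(p):
                for k in range(j + 1, p):
                    labels = {
                        (g1, g2): ("high" if high2[j, k, g1, g2] else "low")
                        for g1 in range(3)
                        for g2 in range(3)
                    }
                    models.append(MDRModel((fids[j], fids[k]), labels, float(ba2[j, k])))
        models.sort(key=lambda m: -m.balanced_accuracy)
    return ranking, models
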