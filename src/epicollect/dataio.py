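"""Core data containers and plain-text readers/writers.

Genotypes are held as additively coded integer matrices (0/1/2 copies of
the minor allele), phenotypes as 0/1 case-control labels.  Two on-disk
dialects are supported: the tab-delimited layout written by GAMETES-style
simulators (feature columns followed by a literal ``Class`` column) and the
PLINK ``.raw`` additive-dosage export.  Truth manifests — which SNPs carry
simulated signal, and in which effect units — travel as JSON sidecars so
that truth-free real data flows through the same reader.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GenotypeMatrix",
    "PhenotypeVector",
    "TruthManifest",
    "SimulatedDataset",
    "FeatureRanking",
    "SelectionResult",
    "read_dataset",
    "write_dataset",
    "read_ranking",
    "write_ranking",
    "read_truth",
    "write_truth",
    "truth_sidecar_path",
]


class FormatError(ValueError):
    """A file or in-memory object violates the genotype-data contracts."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise FormatError(f"duplicate {what} id: {dup!r}")


@dataclass(frozen=True, eq=False)
class GenotypeMatrix:
    """Samples x SNPs matrix with additive coding (AA=0, Aa=1, aa=2)."""

    values: np.ndarray
    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise FormatError("genotype matrix must be 2-dimensional")
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(values == np.floor(values)):
                raise FormatError("genotype values must be integers")
            values = values.astype(np.int8)
        bad = (values < 0) | (values > 2)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise FormatError(
                f"genotype value {values[r, c]} outside {{0,1,2}} at sample "
                f"{self.sample_ids[r]!r} (row {r}), feature "
                f"{self.feature_ids[c]!r} (column {c})"
            )
        object.__setattr__(self, "values", np.ascontiguousarray(values, dtype=np.int8))
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        n, p = self.values.shape
        if len(self.feature_ids) != p:
            raise FormatError(f"{len(self.feature_ids)} feature ids for {p} columns")
        if len(self.sample_ids) != n:
            raise FormatError(f"{len(self.sample_ids)} sample ids for {n} rows")
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_features(self, keep: Sequence[int]) -> "GenotypeMatrix":
        """New matrix restricted to the feature columns at ``keep`` (in order)."""
        keep = list(keep)
        return GenotypeMatrix(
            values=self.values[:, keep],
            feature_ids=tuple(self.feature_ids[i] for i in keep),
            sample_ids=self.sample_ids,
        )


@dataclass(frozen=True, eq=False)
class PhenotypeVector:
    """Binary case/control labels: 0 = control, 1 = case."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 1:
            raise FormatError("phenotype must be a vector")
        if not np.isin(labels, (0, 1)).all():
            bad = labels[~np.isin(labels, (0, 1))][0]
            raise FormatError(f"phenotype value {bad} outside {{0,1}}")
        labels = labels.astype(np.int8)
        if labels.min(initial=1) != 0 or labels.max(initial=0) != 1:
            raise FormatError("phenotype must contain at least one case and one control")
        object.__setattr__(self, "labels", np.ascontiguousarray(labels))

    @property
    def n_samples(self) -> int:
        return self.labels.shape[0]

    @property
    def n_cases(self) -> int:
        return int(self.labels.sum())

    @property
    def n_controls(self) -> int:
        return int(self.n_samples - self.labels.sum())


@dataclass(frozen=True)
class TruthManifest:
    """Which features carry simulated signal, grouped into effect units.

    ``effect_structure`` lists the causal units: 1-tuples for main effects
    and 2-tuples for interacting pairs, each tagged ``case`` or ``control``
    according to the group whose genotype distribution is enriched.
    """

    causal_ids: frozenset[str]
    model_name: str
    effect_structure: tuple[tuple[tuple[str, ...], str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "causal_ids", frozenset(self.causal_ids))
        structure = tuple((tuple(ids), str(tag)) for ids, tag in self.effect_structure)
        object.__setattr__(self, "effect_structure", structure)
        flat = {fid for ids, _ in structure for fid in ids}
        if flat != self.causal_ids:
            raise FormatError("causal_ids must equal the union of effect_structure units")
        for _, tag in structure:
            if tag not in ("case", "control"):
                raise FormatError(f"effect unit tag must be 'case' or 'control', got {tag!r}")


@dataclass(frozen=True, eq=False)
class SimulatedDataset:
    """A genotype matrix with phenotype, optional truth, and provenance."""

    genotypes: GenotypeMatrix
    phenotype: PhenotypeVector
    truth: TruthManifest | None = None
    seed: int | None = None
    replicate: int = 0
    generator: str = "unknown"

    def __post_init__(self) -> None:
        if self.phenotype.n_samples != self.genotypes.n_samples:
            raise FormatError(
                f"phenotype length {self.phenotype.n_samples} != "
                f"{self.genotypes.n_samples} genotype rows"
            )
        if self.truth is not None:
            missing = self.truth.causal_ids - set(self.genotypes.feature_ids)
            if missing:
                raise FormatError(f"truth features absent from matrix: {sorted(missing)}")

    def with_truth(self, truth: TruthManifest) -> "SimulatedDataset":
        return replace(self, truth=truth)


def ranking_order(feature_ids: Sequence[str], scores: Sequence[float]) -> tuple[str, ...]:
    """Descending-score order with ties broken by ascending column index."""
    scores = np.asarray(scores, dtype=float)
    idx = np.argsort(-scores, kind="stable")
    return tuple(feature_ids[i] for i in idx)


@dataclass(frozen=True)
class FeatureRanking:
    """Per-feature importance scores plus the induced total order.

    Higher scores rank first; tied scores fall back to the order of the
    columns in the genotype matrix, so rankings are reproducible even when
    a method returns many identical scores (e.g. a fully shrunk lasso).
    """

    method: str
    scores: Mapping[str, float]
    order: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", dict(self.scores))
        if not self.order:
            ids = list(self.scores)
            object.__setattr__(
                self, "order", ranking_order(ids, [self.scores[i] for i in ids])
            )
        if set(self.order) != set(self.scores) or len(self.order) != len(self.scores):
            raise FormatError("ranking order must be a permutation of the scored features")

    @classmethod
    def from_scores(
        cls, method: str, feature_ids: Sequence[str], scores: Sequence[float]
    ) -> "FeatureRanking":
        scores = np.asarray(scores, dtype=float)
        return cls(
            method=method,
            scores={fid: float(s) for fid, s in zip(feature_ids, scores)},
            order=ranking_order(feature_ids, scores),
        )

    @property
    def n_features(self) -> int:
        return len(self.order)


@dataclass(frozen=True)
class SelectionResult:
    """Top-p% selections per method plus their union and intersection."""

    percentage: float
    per_method: dict[str, frozenset[str]]
    union_set: frozenset[str]
    intersection_set: frozenset[str]
    provenance: dict[str, frozenset[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "percentage": self.percentage,
            "per_method": {m: sorted(s) for m, s in self.per_method.items()},
            "union": sorted(self.union_set),
            "intersection": sorted(self.intersection_set),
            "provenance": {f: sorted(m) for f, m in self.provenance.items()},
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# dataset I/O

_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def truth_sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".truth.json")


def _validate_genotype_frame(frame: pd.DataFrame, path: Path) -> np.ndarray:
    arr = frame.to_numpy()
    if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
        raise FormatError(f"{path}: non-numeric genotype entries")
    bad = (arr < 0) | (arr > 2) | (arr != np.floor(arr))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: genotype value {arr[r, c]} outside {{0,1,2}} at data row "
            f"{r + 1}, column {frame.columns[c]!r}"
        )
    return arr.astype(np.int8)


def read_dataset(path: str | Path, dialect: str = "gametes_tsv") -> SimulatedDataset:
    """Read a case/control genotype file; attaches a truth sidecar if present."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "gametes_tsv":
        table = pd.read_csv(path, sep="\t")
        if "Class" not in table.columns:
            raise FormatError(f"{path}: missing 'Class' column")
        labels = table.pop("Class").to_numpy()
        feature_ids = [str(c) for c in table.columns]
        sample_ids = [f"S{i + 1}" for i in range(len(table))]
    elif dialect == "plink_raw":
        table = pd.read_csv(path, sep=r"\s+")
        missing = [c for c in _PLINK_META if c not in table.columns]
        if missing:
            raise FormatError(f"{path}: missing PLINK .raw columns {missing}")
        sample_ids = [str(i) for i in table["IID"]]
        pheno = table["PHENOTYPE"].to_numpy()
        if not np.isin(pheno, (1, 2)).all():
            raise FormatError(f"{path}: PLINK PHENOTYPE must be 1 (control) or 2 (case)")
        labels = (pheno == 2).astype(np.int8)
        table = table.drop(columns=_PLINK_META)
        feature_ids = [str(c) for c in table.columns]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    _check_unique(feature_ids, "feature")
    values = _validate_genotype_frame(table, path)
    dataset = SimulatedDataset(
        genotypes=GenotypeMatrix(values, tuple(feature_ids), tuple(sample_ids)),
        phenotype=PhenotypeVector(np.asarray(labels)),
        generator="file",
    )
    sidecar = truth_sidecar_path(path)
    if sidecar.exists():
        truth, seed, replicate = read_truth(sidecar)
        dataset = replace(dataset, truth=truth, seed=seed, replicate=replicate)
    return dataset


def write_dataset(
    dataset: SimulatedDataset, path: str | Path, dialect: str = "gametes_tsv"
) -> None:
    """Write a dataset in the requested dialect plus a truth sidecar if known."""
    path = Path(path)
    g = dataset.genotypes
    if dialect == "gametes_tsv":
        frame = pd.DataFrame(g.values, columns=list(g.feature_ids))
        frame["Class"] = dataset.phenotype.labels
        frame.to_csv(path, sep="\t", index=False)
    elif dialect == "plink_raw":
        frame = pd.DataFrame(
            {
                "FID": g.sample_ids,
                "IID": g.sample_ids,
                "PAT": 0,
                "MAT": 0,
                "SEX": 0,
                "PHENOTYPE": dataset.phenotype.labels + 1,
            }
        )
        for j, fid in enumerate(g.feature_ids):
            frame[fid] = g.values[:, j]
        frame.to_csv(path, sep=" ", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if dataset.truth is not None:
        write_truth(
            dataset.truth, truth_sidecar_path(path), seed=dataset.seed,
            replicate=dataset.replicate,
        )


def write_truth(
    truth: TruthManifest, path: str | Path, seed: int | None = None, replicate: int = 0
) -> None:
    payload = {
        "model_name": truth.model_name,
        "causal_ids": sorted(truth.causal_ids),
        "effect_structure": [
            {"features": list(ids), "enriched_in": tag}
            for ids, tag in truth.effect_structure
        ],
        "seed": seed,
        "replicate": replicate,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_truth(path: str | Path) -> tuple[TruthManifest, int | None, int]:
    payload = json.loads(Path(path).read_text())
    truth = TruthManifest(
        causal_ids=frozenset(payload["causal_ids"]),
        model_name=payload["model_name"],
        effect_structure=tuple(
            (tuple(u["features"]), u["enriched_in"])
            for u in payload["effect_structure"]
        ),
    )
    return truth, payload.get("seed"), payload.get("replicate", 0)


# ---------------------------------------------------------------------------
# ranking I/O

def write_ranking(ranking: FeatureRanking, path: str | Path) -> None:
    rows = [
        {"feature_id": fid, "score": repr(ranking.scores[fid]), "rank": r + 1}
        for r, fid in enumerate(ranking.order)
    ]
    frame = pd.DataFrame(rows, columns=["feature_id", "score", "rank"])
    frame.to_csv(path, sep="\t", index=False)


def read_ranking(path: str | Path, method: str | None = None) -> FeatureRanking:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    for col in ("feature_id", "score", "rank"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing ranking column {col!r}")
    frame = frame.sort_values("rank", kind="stable")
    ids = [str(f) for f in frame["feature_id"]]
    scores = frame["score"].astype(float).to_numpy()
    if list(frame["rank"]) != list(range(1, len(frame) + 1)):
        raise FormatError(f"{path}: rank column is not 1..n")
    # ranks must agree with descending score under the stable-index tie rule,
    # where "index" is the order features appear at rank 1..n after a stable
    # re-sort by score; equivalently scores must be non-increasing by rank.
    if np.any(np.diff(scores) > 0):
        k = int(np.flatnonzero(np.diff(scores) > 0)[0]) + 1
        raise FormatError(
            f"{path}: rank column inconsistent with scores near rank {k + 1}"
        )
    return FeatureRanking(
        method=method or path.stem,
        scores={fid: float(s) for fid, s in zip(ids, scores)},
        order=tuple(ids),
    )
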