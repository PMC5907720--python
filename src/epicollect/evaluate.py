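"""Truth-based scoring and the end-to-end simulation benchmark.

Sensitivity is the fraction of simulated causal features present in a
selected set; true/false-positive counts partition the selection.  The
benchmark runner reproduces the simulation study at configurable scale:
simulate replicate datasets over a parameter grid, rank with each method,
form per-method and union selections at each percentage, score against the
truth manifests, and aggregate — including the pooled true-positive counts
per architecture obtained by merging the heritability levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .collective import collective_union
from .dataio import SelectionResult, SimulatedDataset, TruthManifest
from .selectors import SelectorConfig, get_ranker
from .sim_freq import build_effect_tables, simulate_freq_dataset
from .sim_gametes import sample_architecture_models, simulate_gametes_dataset

__all__ = [
    "sensitivity",
    "aggregate_replicates",
    "overlap_counts",
    "BenchmarkConfig",
    "BenchmarkResult",
    "run_benchmark",
]

UNION = "union"


def sensitivity(
    selected: Iterable[str], truth: TruthManifest
) -> tuple[float, int, int]:
    """(sensitivity, tp_count, fp_count) of a selection against the truth."""
    if not truth.causal_ids:
        raise ValueError("sensitivity undefined for an empty truth manifest")
    selected = set(selected)
    tp = len(selected & truth.causal_ids)
    fp = len(selected) - tp
    return tp / len(truth.causal_ids), tp, fp


def aggregate_replicates(rows: pd.DataFrame) -> pd.DataFrame:
    """Mean sensitivity/tp/fp over replicates per (model, method, percentage)."""
    keys = ["model", "method", "percentage"]
    agg = (
        rows.groupby(keys, as_index=False)
        .agg(
            sensitivity=("sensitivity", "mean"),
            tp_count=("tp_count", "mean"),
            fp_count=("fp_count", "mean"),
            n=("replicate", "size"),
        )
        .assign(replicate="mean")
    )
    return agg


def overlap_counts(
    per_method: Mapping[str, Iterable[str]]
) -> dict[frozenset[str], int]:
    """Venn-partition counts: features selected by exactly each method subset."""
    methods = list(per_method)
    if not 2 <= len(methods) <= 4:
        raise ValueError(
            "overlap partition supports 2-4 methods; use the long-format "
            "selection table for more"
        )
    sets = {m: set(per_method[m]) for m in methods}
    counts: dict[frozenset[str], int] = {}
    for r in range(1, len(methods) + 1):
        for subset in combinations(methods, r):
            inside = set.intersection(*(sets[m] for m in subset))
            outside = set.union(
                *(sets[m] for m in methods if m not in subset), set()
            )
            counts[frozenset(subset)] = len(inside - outside)
    return counts


# ---------------------------------------------------------------------------
# benchmark


def _derive_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass(frozen=True)
class BenchmarkConfig:
    """Grid definition for one simulation experiment.

    ``experiment`` is ``freq`` (frequency-shift models over signal
    strengths) or ``gametes`` (penetrance architectures over heritability
    levels).  Unused grid fields for the other experiment are ignored.
    """

    experiment: str
    methods: tuple[str, ...] = ("mdr", "rf", "gbm", "turf:multisurf_star")
    percentages: tuple[float, ...] = (10.0,)
    replicates: int = 10
    seed: int = 0
    n_snps: int = 100
    # frequency-shift grid
    freq_models: tuple[str, ...] = ("1SNP", "case1_control0")
    signals: tuple[float, ...] = (0.1, 0.5, 0.9)
    freq_maf: float = 0.4
    freq_cases: int = 2000
    freq_controls: int = 2000
    # penetrance grid
    h2_levels: tuple[float, ...] = (0.1, 0.2, 0.4)
    architectures: tuple[str, ...] = ("hard", "easy")
    gametes_maf: float = 0.2
    gametes_cases: int = 1000
    gametes_controls: int = 1000
    prevalence: float = 0.3
    main_share: float = 1 / 3
    n_candidates: int = 10_000
    # selector settings
    selector_preset: str = "interaction"
    selector_overrides: Mapping[str, object] = field(default_factory=dict)
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.experiment not in ("freq", "gametes"):
            raise ValueError("experiment must be 'freq' or 'gametes'")
        object.__setattr__(self, "selector_overrides", dict(self.selector_overrides))

    @classmethod
    def from_dict(cls, payload: Mapping[str, object]) -> "BenchmarkConfig":
        kwargs = dict(payload)
        for key in (
            "methods", "percentages", "freq_models", "signals", "h2_levels",
            "architectures",
        ):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class BenchmarkResult:
    """Long-format scores plus selection artifacts and pooled summaries."""

    results: pd.DataFrame
    selections: dict[tuple[str, int, float], SelectionResult]
    failures: list[dict[str, object]]
    pooled: pd.DataFrame | None = None

    def aggregated(self) -> pd.DataFrame:
        return aggregate_replicates(self.results)


def _score_rows(
    model_key: str,
    selection: SelectionResult,
    truth: TruthManifest,
    replicate: int,
    extra: Mapping[str, object],
) -> list[dict[str, object]]:
    rows = []
    named = dict(selection.per_method)
    named[UNION] = selection.union_set
    for method, sel in named.items():
        sens, tp, fp = sensitivity(sel, truth)
        rows.append(
            {
                "model": model_key,
                "method": method,
                "percentage": selection.percentage,
                "replicate": replicate,
                "sensitivity": sens,
                "tp_count": tp,
                "fp_count": fp,
                "n_selected": tp + fp,
                **extra,
            }
        )
    return rows


def _run_cell(
    config: BenchmarkConfig,
    cell_index: int,
    model_key: str,
    extra: Mapping[str, object],
    simulate,  # (replicate, seed) -> SimulatedDataset
) -> tuple[list[dict], dict[tuple[str, int, float], SelectionResult], list[dict]]:
    rows: list[dict] = []
    selections: dict[tuple[str, int, float], SelectionResult] = {}
    failures: list[dict] = []
    for rep in range(config.replicates):
        seed = _derive_seed(config.seed, cell_index, rep)
        try:
            dataset = simulate(rep, seed)
            cfg = SelectorConfig.preset(
                config.selector_preset,
                n_snps=config.n_snps,
                seed=_derive_seed(config.seed, cell_index, rep, 7),
                **config.selector_overrides,
            )
            rankings = [get_ranker(m)(dataset, cfg) for m in config.methods]
            for pct in config.percentages:
                selection = collective_union(rankings, pct)
                selections[(model_key, rep, pct)] = selection
                rows.extend(
                    _score_rows(model_key, selection, dataset.truth, rep, extra)
                )
        except Exception as exc:  # record and continue with other cells
            failures.append(
                {"model": model_key, "replicate": rep, "error": repr(exc)}
            )
    return rows, selections, failures


def _pooled_recovery(
    results_cells: Sequence[tuple[str, Mapping[str, object]]],
    selections: Mapping[tuple[str, int, float], SelectionResult],
    truths: Mapping[str, TruthManifest],
    config: BenchmarkConfig,
) -> pd.DataFrame:
    """Distinct (heritability, causal feature) units recovered per architecture.

    Replicates of one grid cell are merged by consensus: a unit counts as
    recovered by a method (or the union) when the feature is selected in
    at least half of the cell's replicates.  Counts are pooled over the
    heritability levels within one architecture, so the maximum is
    (number of h2 levels) x (causal features per dataset).
    """
    rows = []
    for pct in config.percentages:
        for arch in config.architectures:
            recovered: dict[str, int] = {}
            total = 0
            for model_key, extra in results_cells:
                if extra.get("architecture") != arch:
                    continue
                truth = truths[model_key]
                total += len(truth.causal_ids)
                reps = [
                    selections.get((model_key, rep, pct))
                    for rep in range(config.replicates)
                ]
                reps = [s for s in reps if s is not None]
                if not reps:
                    continue
                quorum = (len(reps) + 1) // 2
                names = list(reps[0].per_method) + [UNION]
                for name in names:
                    hits = 0
                    for fid in truth.causal_ids:
                        votes = sum(
                            fid in (s.union_set if name == UNION else s.per_method[name])
                            for s in reps
                        )
                        hits += votes >= quorum
                    recovered[name] = recovered.get(name, 0) + hits
            for name, count in recovered.items():
                rows.append(
                    {
                        "architecture": arch,
                        "percentage": pct,
                        "method": name,
                        "pooled_tp": count,
                        "pooled_tp_max": total,
                    }
                )
    return pd.DataFrame(rows)


def run_benchmark(config: BenchmarkConfig) -> BenchmarkResult:
    """Run the full grid: simulate, rank, select, score, aggregate."""
    cells: list[tuple[str, Mapping[str, object]]] = []
    simulators = {}
    truths: dict[str, TruthManifest] = {}

    if config.experiment == "freq":
        for model in config.freq_models:
            for s in config.signals:
                key = f"{model}_s{s:g}"
                spec = build_effect_tables(model, s, config.freq_maf)
                cells.append((key, {"signal": s, "freq_model": model}))

                def simulate(rep, seed, spec=spec):
                    return simulate_freq_dataset(
                        spec,
                        n_snps=config.n_snps,
                        n_cases=config.freq_cases,
                        n_controls=config.freq_controls,
                        seed=seed,
                        replicate=rep,
                    )

                simulators[key] = simulate
                truths[key] = spec.truth()
    else:
        for i_h2, h2 in enumerate(config.h2_levels):
            models = sample_architecture_models(
                q=config.gametes_maf,
                h2=h2,
                K=config.prevalence,
                main_share=config.main_share,
                n_candidates=config.n_candidates,
                seed=_derive_seed(config.seed, 9000 + i_h2),
            )
            for arch in config.architectures:
                key = f"{arch}_h2_{h2:g}"
                cells.append((key, {"architecture": arch, "h2": h2}))
                model = models[arch]

                def simulate(rep, seed, model=model, arch=arch, h2=h2):
                    return simulate_gametes_dataset(
                        model,
                        n_snps=config.n_snps,
                        n_cases=config.gametes_cases,
                        n_controls=config.gametes_controls,
                        seed=seed,
                        replicate=rep,
                        model_name=f"{arch}_h2_{h2:g}",
                    )

                simulators[key] = simulate
                truths[key] = TruthManifest(
                    causal_ids=frozenset({"G1", "G2", "G3"}),
                    model_name=key,
                    effect_structure=((("G1", "G2"), "case"), (("G3",), "case")),
                )

    jobs = (
        delayed(_run_cell)(config, i, key, extra, simulators[key])
        for i, (key, extra) in enumerate(cells)
    )
    outputs = Parallel(n_jobs=config.n_jobs)(jobs)

    rows: list[dict] = []
    selections: dict[tuple[str, int, float], SelectionResult] = {}
    failures: list[dict] = []
    for cell_rows, cell_sel, cell_fail in outputs:
        rows.extend(cell_rows)
        selections.update(cell_sel)
        failures.extend(cell_fail)
    results = pd.DataFrame(rows)
    pooled = None
    if config.experiment == "gametes" and not results.empty:
        pooled = _pooled_recovery(cells, selections, truths, config)
    return BenchmarkResult(
        results=results, selections=selections, failures=failures, pooled=pooled
    )
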