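"""Frequency-shift case/control simulator (experiment 1).

Balanced case/control datasets in which causal SNPs — singletons or
interacting pairs — have different (joint) genotype frequencies in cases
versus controls.  Every non-causal SNP is drawn from Hardy–Weinberg
proportions at a common minor-allele frequency in both groups, so the only
signal is the frequency shift on the causal units.

The enrichment is a mixture with strength ``s`` (the effect-size /
"penetrance" label of the eight named models):

* a main-effect unit enriched in group X gets
  ``P_X(g) = (1 - s) * P_HWE(g) + s * 1[g = 2]`` (mass moved onto the
  minor homozygote, configurable to another genotype profile);
* an interaction unit enriched in group X gets the joint table
  ``P_X(g1, g2) = (1 - s) * P_HWE(g1) P_HWE(g2) + s * Diag(g1, g2)`` with
  ``Diag`` uniform over the concordant cells {(0,0), (1,1), (2,2)} — the
  "diagonal" architecture.  The other group keeps the independent
  Hardy–Weinberg product.

Genotypes are sampled with replacement using the tables as probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataio import (
    GenotypeMatrix,
    PhenotypeVector,
    SimulatedDataset,
    TruthManifest,
)

__all__ = [
    "FREQ_MODELS",
    "FreqEffectSpec",
    "EffectUnit",
    "hwe_probs",
    "build_effect_tables",
    "simulate_freq_dataset",
]

#: Named models: (main-effect case units, case-enriched pairs, control-enriched pairs)
#: expressed in 1-based feature positions; feature ids are "G<position>".
FREQ_MODELS: dict[str, tuple[tuple[int, ...], tuple[tuple[int, int], ...], tuple[tuple[int, int], ...]]] = {
    "1SNP": ((1,), (), ()),
    "2SNP": ((1, 2), (), ()),
    "3SNP": ((1, 2, 3), (), ()),
    "4SNP": ((1, 2, 3, 4), (), ()),
    "case1_control0": ((), ((1, 2),), ()),
    "case1_control1": ((), ((1, 2),), ((99, 100),)),
    "case2_control0": ((), ((1, 2), (3, 4)), ()),
    "case2_control2": ((), ((1, 2), (3, 4)), ((97, 98), (99, 100))),
}

_DIAGONAL = np.eye(3) / 3.0


def hwe_probs(q: float) -> np.ndarray:
    """Hardy–Weinberg genotype probabilities ((1-q)^2, 2q(1-q), q^2)."""
    if not 0 < q <= 0.5:
        raise ValueError(f"minor-allele frequency must be in (0, 0.5], got {q}")
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])


@dataclass(frozen=True, eq=False)
class EffectUnit:
    """One causal unit: a single SNP or an interacting pair.

    ``case_table`` / ``control_table`` are length-3 genotype-frequency
    vectors for main effects and 3x3 joint tables for pairs.
    """

    feature_ids: tuple[str, ...]
    enriched_in: str  # "case" | "control"
    case_table: np.ndarray
    control_table: np.ndarray

    def __post_init__(self) -> None:
        for name in ("case_table", "control_table"):
            t = np.asarray(getattr(self, name), dtype=float)
            if t.min() < 0 or abs(t.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} must be a probability table summing to 1")
            object.__setattr__(self, name, t)
        expected = (3,) if len(self.feature_ids) == 1 else (3, 3)
        if self.case_table.shape != expected:
            raise ValueError(f"table shape {self.case_table.shape} != {expected}")


@dataclass(frozen=True, eq=False)
class FreqEffectSpec:
    """Fully materialised frequency tables for one named model."""

    model_name: str
    signal: float
    maf: float
    units: tuple[EffectUnit, ...]
    main_profile: tuple[float, float, float] = (0.0, 0.0, 1.0)

    @property
    def causal_positions(self) -> tuple[int, ...]:
        return tuple(
            int(fid[1:]) for unit in self.units for fid in unit.feature_ids
        )

    def truth(self) -> TruthManifest:
        return TruthManifest(
            causal_ids=frozenset(
                fid for unit in self.units for fid in unit.feature_ids
            ),
            model_name=self.model_name,
            effect_structure=tuple(
                (unit.feature_ids, unit.enriched_in) for unit in self.units
            ),
        )


def build_effect_tables(
    model_name: str,
    signal: float,
    maf: float = 0.4,
    main_profile: Sequence[float] = (0.0, 0.0, 1.0),
) -> FreqEffectSpec:
    """Materialise the case/control frequency tables for a named model.

    ``main_profile`` is the genotype profile that main-effect enrichment
    mixes toward; the default puts all enrichment mass on the minor
    homozygote (g = 2).
    """
    if model_name not in FREQ_MODELS:
        raise ValueError(
            f"unknown model {model_name!r}; choose one of {sorted(FREQ_MODELS)}"
        )
    if not 0 <= signal < 1:
        raise ValueError(f"signal strength must be in [0, 1), got {signal}")
    p_hwe = hwe_probs(maf)
    profile = np.asarray(main_profile, dtype=float)
    if profile.shape != (3,) or profile.min() < 0 or abs(profile.sum() - 1) > 1e-12:
        raise ValueError("main_profile must be a length-3 probability vector")
    joint_hwe = np.outer(p_hwe, p_hwe)
    mains, case_pairs, control_pairs = FREQ_MODELS[model_name]
    units: list[EffectUnit] = []
    for pos in mains:
        units.append(
            EffectUnit(
                feature_ids=(f"G{pos}",),
                enriched_in="case",
                case_table=(1 - signal) * p_hwe + signal * profile,
                control_table=p_hwe,
            )
        )
    enriched_joint = (1 - signal) * joint_hwe + signal * _DIAGONAL
    for group, pairs in (("case", case_pairs), ("control", control_pairs)):
        for a, b in pairs:
            units.append(
                EffectUnit(
                    feature_ids=(f"G{a}", f"G{b}"),
                    enriched_in=group,
                    case_table=enriched_joint if group == "case" else joint_hwe,
                    control_table=joint_hwe if group == "case" else enriched_joint,
                )
            )
    return FreqEffectSpec(
        model_name=model_name,
        signal=signal,
        maf=maf,
        units=tuple(units),
        main_profile=tuple(profile),
    )


def _sample_unit(
    unit: EffectUnit, n_cases: int, n_controls: int, rng: np.random.Generator
) -> np.ndarray:
    """Genotype columns for one causal unit; cases stacked above controls."""
    cols = np.empty((n_cases + n_controls, len(unit.feature_ids)), dtype=np.int8)
    for table, sl in (
        (unit.case_table, slice(0, n_cases)),
        (unit.control_table, slice(n_cases, n_cases + n_controls)),
    ):
        n = sl.stop - sl.start
        if len(unit.feature_ids) == 1:
            cols[sl, 0] = rng.choice(3, size=n, p=table)
        else:
            cells = rng.choice(9, size=n, p=table.ravel())
            cols[sl, 0] = cells // 3
            cols[sl, 1] = cells % 3
    return cols


def simulate_freq_dataset(
    spec: FreqEffectSpec,
    n_snps: int = 100,
    n_cases: int = 2000,
    n_controls: int = 2000,
    seed: int = 0,
    replicate: int = 0,
) -> SimulatedDataset:
    """Sample one balanced dataset: cases first, then controls.

    Causal columns are drawn per sample from the group-appropriate table;
    every other column is Hardy–Weinberg noise at the spec's MAF,
    identically distributed in both groups.
    """
    positions = spec.causal_positions
    if positions and n_snps < max(positions):
        raise ValueError(
            f"model {spec.model_name!r} places causal SNPs up to position "
            f"{max(positions)}, but n_snps={n_snps}"
        )
    if n_cases < 1 or n_controls < 1:
        raise ValueError("need at least one case and one control")
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    values = np.empty((n, n_snps), dtype=np.int8)
    causal_cols = set()
    for unit in spec.units:
        cols = _sample_unit(unit, n_cases, n_controls, rng)
        for k, fid in enumerate(unit.feature_ids):
            j = int(fid[1:]) - 1
            values[:, j] = cols[:, k]
            causal_cols.add(j)
    noise_cols = [j for j in range(n_snps) if j not in causal_cols]
    if noise_cols:
        values[:, noise_cols] = rng.choice(
            3, size=(n, len(noise_cols)), p=hwe_probs(spec.maf)
        )
    labels = np.concatenate(
        [np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    )
    return SimulatedDataset(
        genotypes=GenotypeMatrix(
            values,
            feature_ids=tuple(f"G{j + 1}" for j in range(n_snps)),
            sample_ids=tuple(f"S{i + 1}" for i in range(n)),
        ),
        phenotype=PhenotypeVector(labels),
        truth=spec.truth(),
        seed=seed,
        replicate=replicate,
        generator="freq",
    )
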