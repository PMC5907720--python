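"""Penetrance-model case/control simulator (experiment 2).

Random *pure-strict* two-locus epistasis models — penetrance tables whose
single-locus marginal penetrances all equal the prevalence, so signal
exists only in the pair — are drawn at a fixed minor-allele frequency and
an exact heritability, stratified into easy/hard architectures by a
detectability score, combined with a one-locus main-effect model on a
third SNP, and sampled into balanced case/control datasets by rejection
sampling.

Notation: ``w(g)`` are Hardy–Weinberg genotype weights, ``K`` the disease
prevalence, ``f`` a penetrance table.  Heritability is the standard
penetrance-variance definition

    h2 = sum_g w(g) (f(g) - K)^2 / (K (1 - K)).

The detectability score is the analytic Bayes-optimal two-locus balanced
accuracy

    BA* = 1/2 + 1/4 * sum_cells | P(cell | case) - P(cell | control) |,

monotone in how separable the class-conditional genotype distributions
are; population minima/maxima over many random models at the same
(MAF, h2, K) give the hard/easy architectures.

Sampling pure-strict tables works direction-first: a random direction in
the 4-dimensional null space of the zero-marginal constraints is drawn,
the largest scale keeping all penetrances in [0, 1] is computed, the
direction is rejected if the target heritability is unreachable, and
otherwise the deviation is scaled so the heritability is exact.  (Scaling
an isotropic draw and rejecting out-of-range tables finds essentially no
models at high heritability, because the feasible set is a thin cone.)

Combining models is a convex mixture of penetrance tables,

    f(g1, g2, g3) = c_e * f_epi(g1, g2) + c_m * f_main(g3),  c_e + c_m = 1,

which shares the components' prevalence and stays in [0, 1] by
construction.  Mixing necessarily attenuates each component: the pair
contributes ``c_e^2 * h2_epi`` and the main effect ``c_m^2 * h2_main`` to
the combined table's heritability (the deviations are orthogonal under
independent-locus HWE weights).  A combined table in which the pair keeps
its full generated heritability alongside a non-degenerate main effect
does not exist at low MAF — the pair's penetrances already touch 0 and 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import null_space

from .dataio import (
    GenotypeMatrix,
    PhenotypeVector,
    SimulatedDataset,
    TruthManifest,
)
from .sim_freq import hwe_probs

__all__ = [
    "PenetranceModel",
    "CombinedModel",
    "InfeasibleModelError",
    "compute_heritability",
    "edm_proxy",
    "random_pure_epistasis_model",
    "select_edm_extremes",
    "main_effect_deviation",
    "combine_with_main_effect",
    "sample_architecture_models",
    "simulate_gametes_dataset",
    "draw_candidates",
]


class InfeasibleModelError(RuntimeError):
    """No valid penetrance table exists for the requested parameters."""


def _pair_weights(q: float) -> np.ndarray:
    w = hwe_probs(q)
    return np.outer(w, w)


@dataclass(frozen=True, eq=False)
class PenetranceModel:
    """Two-locus penetrance table with its population parameters."""

    f: np.ndarray
    maf: float
    K: float
    h2: float
    edm_score: float
    kind: str = "pure_pair"

    def __post_init__(self) -> None:
        f = np.asarray(self.f, dtype=float)
        if f.shape != (3, 3):
            raise ValueError("penetrance table must be 3x3")
        if f.min() < -1e-12 or f.max() > 1 + 1e-12:
            raise ValueError("penetrances must lie in [0, 1]")
        object.__setattr__(self, "f", np.clip(f, 0.0, 1.0))
        W = _pair_weights(self.maf)
        K = float((W * self.f).sum())
        if abs(K - self.K) > 1e-9:
            raise ValueError(f"stored prevalence {self.K} != table prevalence {K}")
        h2 = compute_heritability_table(self.f, self.maf, self.K)
        if abs(h2 - self.h2) > 1e-9:
            raise ValueError(f"stored heritability {self.h2} != table value {h2}")

    def marginal_penetrances(self) -> tuple[np.ndarray, np.ndarray]:
        """Row- and column-marginal penetrances under HWE weights."""
        w = hwe_probs(self.maf)
        return self.f @ w, self.f.T @ w


def compute_heritability_table(f: np.ndarray, q: float, K: float) -> float:
    if K <= 0 or K >= 1:
        raise ValueError("heritability undefined for prevalence 0 or 1")
    W = _pair_weights(q)
    return float((W * (np.asarray(f, dtype=float) - K) ** 2).sum() / (K * (1 - K)))


def compute_heritability(model: PenetranceModel) -> float:
    """Penetrance-variance heritability of a two-locus model."""
    return compute_heritability_table(model.f, model.maf, model.K)


def edm_proxy(model: PenetranceModel) -> float:
    """Detectability score: Bayes-optimal two-locus balanced accuracy.

    0.5 for a constant table (classes indistinguishable), 1.0 when the
    class-conditional genotype-cell distributions have disjoint support.
    """
    W = _pair_weights(model.maf)
    K = model.K
    p_case = W * model.f / K
    p_ctrl = W * (1 - model.f) / (1 - K)
    return float(0.5 + 0.25 * np.abs(p_case - p_ctrl).sum())


def _marginal_nullspace(q: float) -> np.ndarray:
    """Basis (9 x 4) of deviation tables with zero HWE row/col marginals."""
    w = hwe_probs(q)
    A = np.zeros((6, 9))
    for g1 in range(3):
        for g2 in range(3):
            A[g1, 3 * g1 + g2] = w[g2]
            A[3 + g2, 3 * g1 + g2] = w[g1]
    return null_space(A)


def _draw_pure_tables(
    q: float,
    h2_target: float,
    K: float,
    rng: np.random.Generator,
    n_models: int,
    max_draws: int,
    batch: int = 4096,
) -> list[np.ndarray]:
    """Up to ``n_models`` valid pure-strict tables at exactly ``h2_target``."""
    basis = _marginal_nullspace(q)
    W = _pair_weights(q).ravel()
    target_ss = h2_target * K * (1 - K)  # required weighted sum of squares
    out: list[np.ndarray] = []
    drawn = 0
    while len(out) < n_models and drawn < max_draws:
        b = min(batch, max_draws - drawn)
        drawn += b
        U = rng.standard_normal((b, basis.shape[1])) @ basis.T  # (b, 9)
        with np.errstate(divide="ignore", invalid="ignore"):
            up = np.where(U > 1e-12, (1 - K) / U, np.inf)
            dn = np.where(U < -1e-12, K / (-U), np.inf)
        cmax = np.minimum(up.min(axis=1), dn.min(axis=1))
        ss = (W[None, :] * U * U).sum(axis=1)
        ok = (ss > 0) & (cmax ** 2 * ss >= target_ss)
        for row in U[ok]:
            scale = np.sqrt(target_ss / float((W * row * row).sum()))
            out.append(K + (scale * row).reshape(3, 3))
            if len(out) == n_models:
                break
    return out


def random_pure_epistasis_model(
    q: float,
    h2_target: float,
    K: float = 0.3,
    seed: int = 0,
    max_retries: int = 200_000,
) -> PenetranceModel:
    """Draw one random pure-strict model at exactly the target heritability."""
    if not 0 < q <= 0.5:
        raise ValueError("MAF must be in (0, 0.5]")
    if not 0 < h2_target < 1:
        raise ValueError("heritability target must be in (0, 1)")
    if not 0 < K < 1:
        raise ValueError("prevalence must be in (0, 1)")
    rng = np.random.default_rng(seed)
    tables = _draw_pure_tables(q, h2_target, K, rng, 1, max_retries)
    if not tables:
        raise InfeasibleModelError(
            f"no pure-strict model with h2={h2_target} at MAF={q}, K={K} "
            f"after {max_retries} draws"
        )
    f = tables[0]
    probe = PenetranceModel(f=f, maf=q, K=K, h2=h2_target, edm_score=0.5)
    return PenetranceModel(
        f=f, maf=q, K=K, h2=h2_target, edm_score=edm_proxy(probe), kind="pure_pair"
    )


def select_edm_extremes(
    population: Sequence[PenetranceModel],
) -> tuple[PenetranceModel, PenetranceModel]:
    """(hardest, easiest) models by detectability; ties keep the earliest."""
    if not population:
        raise ValueError("empty model population")
    scores = [m.edm_score for m in population]
    return population[int(np.argmin(scores))], population[int(np.argmax(scores))]


def main_effect_deviation(
    q: float, h2: float, K: float, profile: str = "dominant"
) -> np.ndarray:
    """Zero-HWE-mean one-locus deviation ``d(g)`` scaled to heritability h2.

    ``profile`` is ``additive`` (d proportional to the centred allele count
    g - 2q) or ``dominant`` (d proportional to the centred carrier
    indicator 1[g >= 1]); the dominant profile spreads the deviation far
    more evenly across genotypes at low MAF, so it supports much higher
    heritabilities before a penetrance leaves [0, 1].
    """
    w = hwe_probs(q)
    g = np.arange(3, dtype=float)
    if profile == "additive":
        unit = g - 2 * q
    elif profile == "dominant":
        unit = (g >= 1).astype(float) - (1 - (1 - q) ** 2)
    else:
        raise ValueError("profile must be 'additive' or 'dominant'")
    v = float(w @ unit ** 2)
    d = np.sqrt(h2 * K * (1 - K) / v) * unit
    if K + d.min() < -1e-12 or K + d.max() > 1 + 1e-12:
        raise InfeasibleModelError(
            f"one-locus {profile} model with h2={h2} at MAF={q}, K={K} "
            "requires penetrances outside [0, 1]"
        )
    return d


@dataclass(frozen=True, eq=False)
class CombinedModel:
    """Convex mixture of a pure pair and a one-locus main effect.

    ``f(g1,g2,g3) = K + c_e (f_epi(g1,g2) - K) + c_m d_main(g3)`` with
    ``c_e + c_m <= 1``, so the table stays in [0, 1] whenever both
    components are valid.  ``h2_total`` is the heritability of the mixed
    27-cell table: ``c_e^2 h2_epi + c_m^2 h2_main`` by orthogonality of
    independent-locus deviations.
    """

    epi: PenetranceModel
    d_main: np.ndarray
    c_e: float
    c_m: float
    K: float
    h2_total: float

    def __post_init__(self) -> None:
        d = np.asarray(self.d_main, dtype=float)
        if d.shape != (3,):
            raise ValueError("main-effect deviation must have length 3")
        w = hwe_probs(self.epi.maf)
        if abs(float(w @ d)) > 1e-9:
            raise ValueError("main-effect deviation must have zero HWE mean")
        object.__setattr__(self, "d_main", d)
        table = self.table()
        if table.min() < -1e-12 or table.max() > 1 + 1e-12:
            raise ValueError("combined penetrances leave [0, 1]")
        if abs(self.heritability() - self.h2_total) > 1e-9:
            raise ValueError("stored h2_total inconsistent with the 27-cell table")

    @property
    def maf(self) -> float:
        return self.epi.maf

    def table(self) -> np.ndarray:
        """Full 3x3x3 penetrance table, axes (g1, g2, g3)."""
        epi_dev = self.c_e * (self.epi.f - self.epi.K)
        return self.K + epi_dev[:, :, None] + self.c_m * self.d_main[None, None, :]

    def heritability(self) -> float:
        """Total heritability recomputed from the 27-cell table."""
        w = hwe_probs(self.maf)
        W3 = w[:, None, None] * w[None, :, None] * w[None, None, :]
        f = self.table()
        return float((W3 * (f - self.K) ** 2).sum() / (self.K * (1 - self.K)))


def combine_with_main_effect(
    epi: PenetranceModel,
    main_share: float = 1 / 3,
    main_h2: float | None = None,
    main_profile: str = "dominant",
    h2_total: float | None = None,
) -> CombinedModel:
    """Mix a pure pair with a main-effect locus at a given variance share.

    ``main_share`` is the fraction of the combined table's heritability
    contributed by the main effect; ``main_h2`` (default: the pair's
    heritability) only sets the main component's deviation *shape scale*
    before the joint rescaling.  With ``h2_total`` given, the joint
    deviation is scaled so the combined table's heritability equals it
    exactly; an :class:`InfeasibleModelError` is raised when that pushes a
    penetrance out of [0, 1].  With ``h2_total=None`` the convex mixture
    ``c_e + c_m = 1`` is used, which is always valid but attenuates the
    total to ``(1-s)^2 h2_epi + s^2-weighted`` contributions — the
    strongest combination that is feasible for *every* pair model.
    ``main_share = 0`` degenerates to the pure pair.
    """
    if not 0 <= main_share < 1:
        raise ValueError("main-effect share must be in [0, 1)")
    K, q = epi.K, epi.maf
    h2_m = epi.h2 if main_h2 is None else main_h2
    if main_share == 0:
        c_e, c_m = 1.0, 0.0
        d_main = np.zeros(3)
        base_total = epi.h2
    else:
        d_main = main_effect_deviation(q, h2_m, K, main_profile)
        # shares: c_m^2 h2_m / (c_e^2 h2_e + c_m^2 h2_m) = main_share
        ratio = np.sqrt(main_share * epi.h2 / ((1 - main_share) * h2_m))  # c_m / c_e
        c_e = 1.0 / (1.0 + ratio)
        c_m = ratio * c_e
        base_total = c_e ** 2 * epi.h2 + c_m ** 2 * h2_m
    if h2_total is not None:
        gamma = float(np.sqrt(h2_total / base_total))
        c_e *= gamma
        c_m *= gamma
        base_total = h2_total
    try:
        return CombinedModel(
            epi=epi, d_main=d_main, c_e=float(c_e), c_m=float(c_m), K=K,
            h2_total=float(base_total),
        )
    except ValueError as exc:
        raise InfeasibleModelError(
            f"combined table cannot reach h2_total={h2_total}: {exc}"
        ) from exc


def sample_architecture_models(
    q: float = 0.2,
    h2: float = 0.1,
    K: float = 0.3,
    main_share: float = 1 / 3,
    main_profile: str = "dominant",
    n_candidates: int = 10_000,
    seed: int = 0,
    max_draws: int = 50_000_000,
) -> dict[str, CombinedModel]:
    """Candidate population at (q, h2, K) -> {'hard': ..., 'easy': ...}.

    ``h2`` names the level: it is both the heritability of the generated
    two-locus component and the target heritability of the combined
    27-cell table.  Candidates whose combined table cannot reach the
    target are discarded; if *no* candidate can (the penetrance
    constraints cap the combined total well below the pair's own
    heritability at high levels), every candidate falls back to the
    always-feasible convex mixture and the models carry the capped
    ``h2_total``.  Detectability extremes over the surviving population
    define the hard (EDM minimum) and easy (EDM maximum) architectures.
    """
    rng = np.random.default_rng(seed)
    tables = _draw_pure_tables(q, h2, K, rng, n_candidates, max_draws)
    if not tables:
        raise InfeasibleModelError(
            f"no pure-strict candidates at h2={h2}, MAF={q}, K={K}"
        )
    combined: list[CombinedModel] = []
    for f in tables:
        probe = PenetranceModel(f=f, maf=q, K=K, h2=h2, edm_score=0.5)
        epi = PenetranceModel(f=f, maf=q, K=K, h2=h2, edm_score=edm_proxy(probe))
        try:
            combined.append(
                combine_with_main_effect(
                    epi, main_share, main_profile=main_profile, h2_total=h2
                )
            )
        except InfeasibleModelError:
            continue
    if not combined:  # target total unreachable: maximal always-valid mixture
        for f in tables:
            probe = PenetranceModel(f=f, maf=q, K=K, h2=h2, edm_score=0.5)
            epi = PenetranceModel(f=f, maf=q, K=K, h2=h2, edm_score=edm_proxy(probe))
            combined.append(
                combine_with_main_effect(epi, main_share, main_profile=main_profile)
            )
    scores = [m.epi.edm_score for m in combined]
    return {
        "hard": combined[int(np.argmin(scores))],
        "easy": combined[int(np.argmax(scores))],
    }


def draw_candidates(
    model: CombinedModel, n: int, rng: np.random.Generator, n_snps: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` individuals: genotypes i.i.d. HWE, case status ~ penetrance.

    All ``n_snps`` loci (predictive ones in columns 0-2) are sampled at the
    model's MAF; status is Bernoulli with probability ``f(g1, g2, g3)``.
    """
    geno = rng.choice(3, size=(n, n_snps), p=hwe_probs(model.maf)).astype(np.int8)
    f = model.table()
    risk = f[geno[:, 0], geno[:, 1], geno[:, 2]]
    status = (rng.random(n) < risk).astype(np.int8)
    return geno, status


def simulate_gametes_dataset(
    model: CombinedModel,
    n_snps: int = 100,
    n_cases: int = 1000,
    n_controls: int = 1000,
    seed: int = 0,
    replicate: int = 0,
    model_name: str = "gametes",
    shuffle: bool = False,
) -> SimulatedDataset:
    """Rejection-sample a balanced dataset from a combined penetrance model.

    Candidate individuals are drawn until both case and control quotas are
    full; candidates arriving after their quota filled are discarded.  The
    three predictive loci occupy the first three columns unless
    ``shuffle=True`` permutes all columns (truth ids follow the features).
    """
    if n_snps < 3:
        raise ValueError("need at least 3 SNPs for the predictive loci")
    rng = np.random.default_rng(seed)
    case_rows: list[np.ndarray] = []
    ctrl_rows: list[np.ndarray] = []
    need_cases, need_ctrls = n_cases, n_controls
    K = model.K
    while need_cases > 0 or need_ctrls > 0:
        n_draw = int(
            max(
                need_cases / max(K, 1e-6),
                need_ctrls / max(1 - K, 1e-6),
                64,
            )
            * 1.2
        )
        geno, status = draw_candidates(model, n_draw, rng, n_snps)
        if need_cases > 0:
            take = geno[status == 1][:need_cases]
            case_rows.append(take)
            need_cases -= len(take)
        if need_ctrls > 0:
            take = geno[status == 0][:need_ctrls]
            ctrl_rows.append(take)
            need_ctrls -= len(take)
    values = np.vstack(case_rows + ctrl_rows)
    feature_ids = [f"G{j + 1}" for j in range(n_snps)]
    if shuffle:
        perm = rng.permutation(n_snps)
        values = values[:, perm]
        predictive = tuple(
            feature_ids[int(np.flatnonzero(perm == j)[0])] for j in range(3)
        )
    else:
        predictive = ("G1", "G2", "G3")
    labels = np.concatenate(
        [np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    )
    truth = TruthManifest(
        causal_ids=frozenset(predictive),
        model_name=model_name,
        effect_structure=(
            ((predictive[0], predictive[1]), "case"),
            ((predictive[2],), "case"),
        ),
    )
    return SimulatedDataset(
        genotypes=GenotypeMatrix(
            values,
            feature_ids=tuple(feature_ids),
            sample_ids=tuple(f"S{i + 1}" for i in range(n_cases + n_controls)),
        ),
        phenotype=PhenotypeVector(labels),
        truth=truth,
        seed=seed,
        replicate=replicate,
        generator="gametes",
    )
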