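import numpy as np
import pytest

from epicollect.sim_freq import hwe_probs
from epicollect.sim_gametes import (
    CombinedModel,
    InfeasibleModelError,
    PenetranceModel,
    combine_with_main_effect,
    compute_heritability,
    draw_candidates,
    edm_proxy,
    main_effect_deviation,
    random_pure_epistasis_model,
    sample_architecture_models,
    select_edm_extremes,
    simulate_gametes_dataset,
)


def xor_model():
    """Penetrance 1 on the odd-allele-sum cells at MAF 0.5: K=0.5, h2=1."""
    f = np.zeros((3, 3))
    for g1, g2 in [(0, 1), (1, 0), (1, 2), (2, 1)]:
        f[g1, g2] = 1.0
    return PenetranceModel(f=f, maf=0.5, K=0.5, h2=1.0, edm_score=1.0)


class TestPenetranceModel:
    def test_xor_closed_form(self):
        m = xor_model()
        assert compute_heritability(m) == pytest.approx(1.0, abs=1e-12)
        assert edm_proxy(m) == pytest.approx(1.0, abs=1e-12)
        for marg in m.marginal_penetrances():
            assert np.allclose(marg, 0.5, atol=1e-12)

    def test_constant_table_has_zero_h2_and_chance_edm(self):
        m = PenetranceModel(
            f=np.full((3, 3), 0.3), maf=0.2, K=0.3, h2=0.0, edm_score=0.5
        )
        assert compute_heritability(m) == pytest.approx(0.0, abs=1e-15)
        assert edm_proxy(m) == pytest.approx(0.5, abs=1e-15)

    def test_scaling_deviations_is_quadratic_in_h2(self):
        m = random_pure_epistasis_model(0.2, 0.2, K=0.3, seed=0)
        half = PenetranceModel(
            f=m.K + 0.5 * (m.f - m.K), maf=m.maf, K=m.K, h2=m.h2 / 4,
            edm_score=0.5,
        )
        assert compute_heritability(half) == pytest.approx(m.h2 / 4, abs=1e-12)

    def test_inconsistent_stored_values_rejected(self):
        with pytest.raises(ValueError):
            PenetranceModel(f=np.full((3, 3), 0.3), maf=0.2, K=0.4, h2=0.0,
                            edm_score=0.5)


@pytest.mark.parametrize("h2", [0.05, 0.1, 0.2, 0.4])
def test_random_pure_models_have_exact_invariants(h2):
    m = random_pure_epistasis_model(0.2, h2, K=0.3, seed=11)
    row, col = m.marginal_penetrances()
    assert np.allclose(row, m.K, atol=1e-12)
    assert np.allclose(col, m.K, atol=1e-12)
    assert compute_heritability(m) == pytest.approx(h2, abs=1e-9)
    assert m.f.min() >= 0 and m.f.max() <= 1
    again = random_pure_epistasis_model(0.2, h2, K=0.3, seed=11)
    assert np.array_equal(m.f, again.f)


def test_infeasible_heritability_raises():
    with pytest.raises(InfeasibleModelError):
        random_pure_epistasis_model(0.2, 0.95, K=0.3, seed=0, max_retries=20_000)


class TestEdmSelection:
    def test_singleton_population(self):
        m = xor_model()
        assert select_edm_extremes([m]) == (m, m)

    def test_ordering(self):
        lo = PenetranceModel(f=np.full((3, 3), 0.3), maf=0.2, K=0.3, h2=0.0,
                             edm_score=0.58)
        hi = PenetranceModel(f=np.full((3, 3), 0.3), maf=0.2, K=0.3, h2=0.0,
                             edm_score=0.61)
        assert select_edm_extremes([lo, hi]) == (lo, hi)

    def test_empty_population(self):
        with pytest.raises(ValueError):
            select_edm_extremes([])

    def test_extremes_over_random_population(self):
        rng = np.random.default_rng(0)
        pop = [
            random_pure_epistasis_model(0.2, 0.1, K=0.3, seed=int(s))
            for s in rng.integers(0, 2**31, size=200)
        ]
        hard, easy = select_edm_extremes(pop)
        scores = [m.edm_score for m in pop]
        assert hard.edm_score == min(scores)
        assert easy.edm_score == max(scores)
        assert easy.edm_score >= hard.edm_score
        assert all(0.5 <= s <= 1.0 for s in scores)


class TestCombination:
    def test_zero_share_degenerates_to_pure_pair(self):
        epi = random_pure_epistasis_model(0.2, 0.2, K=0.3, seed=4)
        cm = combine_with_main_effect(epi, main_share=0.0)
        assert cm.c_m == 0.0
        assert np.allclose(cm.table(), epi.f[:, :, None].repeat(3, axis=2))
        assert cm.h2_total == pytest.approx(epi.h2, abs=1e-12)

    def test_additive_deviation_has_zero_hwe_mean(self):
        # q=0.2: d ∝ (-0.4, 0.6, 1.6); HWE weights (0.64, 0.32, 0.04)
        d = main_effect_deviation(0.2, 0.05, 0.3, profile="additive")
        w = hwe_probs(0.2)
        assert float(w @ d) == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(d / d[0], np.array([-0.4, 0.6, 1.6]) / -0.4)

    def test_combined_total_matches_table_recomputation(self):
        # not every pair model can host the main effect at the full total;
        # scan seeds the way the architecture sampler does
        cm = None
        for seed in range(20):
            epi = random_pure_epistasis_model(0.2, 0.1, K=0.3, seed=seed)
            try:
                cm = combine_with_main_effect(epi, main_share=1 / 3, h2_total=0.1)
                break
            except InfeasibleModelError:
                continue
        assert cm is not None
        assert cm.heritability() == pytest.approx(0.1, abs=1e-9)
        assert cm.h2_total == pytest.approx(0.1, abs=1e-9)
        # main effect contributes its share of the total
        w = hwe_probs(0.2)
        v_main = float(w @ (cm.c_m * cm.d_main) ** 2)
        assert v_main / (cm.K * (1 - cm.K)) == pytest.approx(0.1 / 3, abs=1e-9)

    def test_unreachable_total_raises(self):
        epi = random_pure_epistasis_model(0.2, 0.4, K=0.3, seed=2)
        with pytest.raises(InfeasibleModelError):
            combine_with_main_effect(epi, main_share=1 / 3, h2_total=0.4)

    def test_additive_main_infeasible_at_high_h2(self):
        with pytest.raises(InfeasibleModelError):
            main_effect_deviation(0.2, 0.4, 0.3, profile="additive")


def test_architecture_sampling_orders_difficulty():
    models = sample_architecture_models(h2=0.1, n_candidates=300, seed=8)
    assert models["easy"].epi.edm_score >= models["hard"].epi.edm_score
    for m in models.values():
        assert m.h2_total == pytest.approx(0.1, abs=1e-9)
        assert m.heritability() == pytest.approx(m.h2_total, abs=1e-9)


@pytest.fixture(scope="module")
def model():
    return sample_architecture_models(h2=0.2, n_candidates=100, seed=3)["easy"]


class TestSimulatedDatasets:

    def test_default_shape_and_truth(self, model):
        ds = simulate_gametes_dataset(model, seed=5)
        assert ds.genotypes.values.shape == (2000, 100)
        assert ds.phenotype.n_cases == 1000
        assert ds.phenotype.n_controls == 1000
        assert ds.truth.causal_ids == {"G1", "G2", "G3"}
        assert ds.genotypes.n_features - len(ds.truth.causal_ids) == 97

    def test_determinism_given_seed(self, model):
        a = simulate_gametes_dataset(model, n_snps=10, n_cases=50, n_controls=50, seed=2)
        b = simulate_gametes_dataset(model, n_snps=10, n_cases=50, n_controls=50, seed=2)
        assert np.array_equal(a.genotypes.values, b.genotypes.values)

    def test_shuffle_keeps_truth_aligned(self, model):
        plain = simulate_gametes_dataset(
            model, n_snps=10, n_cases=100, n_controls=100, seed=2
        )
        shuf = simulate_gametes_dataset(
            model, n_snps=10, n_cases=100, n_controls=100, seed=2, shuffle=True
        )
        # the column permutation is drawn after sampling, so the shuffled
        # predictive ids must point at the same data as plain columns 0-2
        (pair, _), (main, _) = shuf.truth.effect_structure
        predictive = (*pair, *main)
        for old_col, fid in enumerate(predictive):
            new_col = shuf.genotypes.feature_ids.index(fid)
            assert np.array_equal(
                shuf.genotypes.values[:, new_col], plain.genotypes.values[:, old_col]
            )

    def test_empirical_penetrance_matches_table(self, model):
        """Large-cohort case rates per 27-cell agree with the penetrance table."""
        rng = np.random.default_rng(17)
        geno, status = draw_candidates(model, 150_000, rng, n_snps=3)
        f = model.table()
        cell = (geno[:, 0] * 9 + geno[:, 1] * 3 + geno[:, 2]).astype(int)
        for c in range(27):
            mask = cell == c
            n = int(mask.sum())
            if n < 200:
                continue
            expected = f.ravel()[c]
            se = np.sqrt(max(expected * (1 - expected), 1e-4) / n)
            assert abs(status[mask].mean() - expected) < 4 * se
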