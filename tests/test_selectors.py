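import numpy as np
import pytest

from epicollect.dataio import FeatureRanking
from epicollect.selectors import (
    SelectorConfig,
    get_ranker,
    mdr_rank,
    multisurf_star_rank,
    turf_wrap,
)

from conftest import make_dataset, random_dataset
from oracles import mdr_oracle, multisurf_star_oracle


class TestMDR:
    def test_hand_worked_single_snp(self):
        # cases (0,0,1), controls (2,2,1): cell 0 high, cells 1/2 low
        ds = make_dataset([[0], [0], [1], [2], [2], [1]], [1, 1, 1, 0, 0, 0])
        ranking, models = mdr_rank(ds, max_order=1)
        assert models[0].balanced_accuracy == pytest.approx(5 / 6, abs=1e-12)
        assert models[0].cell_labels == {(0,): "high", (1,): "low", (2,): "low"}
        assert ranking.scores["G1"] == pytest.approx(5 / 6, abs=1e-12)

    def test_tied_cells_are_low_risk(self):
        # every cell's case:control ratio equals the overall ratio (1:1):
        # all cells low, TPR=0, TNR=1, BA=0.5
        ds = make_dataset([[0], [1], [2], [0], [1], [2]], [1, 1, 1, 0, 0, 0])
        ranking, models = mdr_rank(ds, max_order=1)
        assert models[0].balanced_accuracy == pytest.approx(0.5, abs=1e-12)
        assert set(models[0].cell_labels.values()) == {"low"}

    def test_matches_bruteforce_oracle(self, rng):
        ds = random_dataset(rng, 40, 6)
        _, models = mdr_rank(ds)
        expected = mdr_oracle(ds.genotypes.values, ds.phenotype.labels)
        fid_to_idx = {f: i for i, f in enumerate(ds.genotypes.feature_ids)}
        assert len(models) == 6 + 15
        for m in models:
            loci = tuple(fid_to_idx[f] for f in m.loci)
            assert m.balanced_accuracy == pytest.approx(
                expected[loci], abs=1e-12
            ), f"model {m.loci}"

    def test_feature_score_is_max_over_containing_models(self, rng):
        ds = random_dataset(rng, 30, 5)
        ranking, models = mdr_rank(ds)
        for j, fid in enumerate(ds.genotypes.feature_ids):
            best = max(m.balanced_accuracy for m in models if fid in m.loci)
            assert ranking.scores[fid] == pytest.approx(best, abs=1e-12)

    def test_feature_permutation_equivariance(self, rng):
        ds = random_dataset(rng, 30, 5)
        perm = [3, 1, 4, 0, 2]
        permuted = make_dataset(
            ds.genotypes.values[:, perm], ds.phenotype.labels, prefix="H"
        )
        base, _ = mdr_rank(ds)
        shuf, _ = mdr_rank(permuted)
        for new_j, old_j in enumerate(perm):
            assert shuf.scores[f"H{new_j + 1}"] == pytest.approx(
                base.scores[f"G{old_j + 1}"], abs=1e-15
            )

    def test_sample_permutation_invariance(self, rng):
        ds = random_dataset(rng, 30, 4)
        order = rng.permutation(30)
        permuted = make_dataset(
            ds.genotypes.values[order], ds.phenotype.labels[order]
        )
        a, _ = mdr_rank(ds)
        b, _ = mdr_rank(permuted)
        assert a.scores == b.scores


class TestMultiSURFStar:
    def test_constant_attribute_scores_zero(self, rng):
        values = rng.integers(0, 3, size=(20, 3))
        values[:, 1] = 2
        ds = make_dataset(values, [0, 1] * 10)
        r = multisurf_star_rank(ds)
        assert r.scores["G2"] == 0.0

    def test_duplicated_attribute_scores_equal(self, rng):
        values = rng.integers(0, 3, size=(20, 3))
        values[:, 2] = values[:, 0]
        ds = make_dataset(values, [0, 1] * 10)
        r = multisurf_star_rank(ds)
        assert r.scores["G1"] == pytest.approx(r.scores["G3"], abs=1e-12)

    @pytest.mark.parametrize("n,p,seed", [(8, 3, 0), (15, 4, 1), (30, 6, 2)])
    def test_matches_pairwise_oracle(self, n, p, seed):
        ds = random_dataset(np.random.default_rng(seed), n, p)
        r = multisurf_star_rank(ds)
        expected = multisurf_star_oracle(ds.genotypes.values, ds.phenotype.labels)
        got = np.array([r.scores[f] for f in ds.genotypes.feature_ids])
        assert np.allclose(got, expected, atol=1e-12)

    def test_sample_permutation_invariance(self, rng):
        ds = random_dataset(rng, 25, 4)
        order = rng.permutation(25)
        permuted = make_dataset(
            ds.genotypes.values[order], ds.phenotype.labels[order]
        )
        a = multisurf_star_rank(ds)
        b = multisurf_star_rank(permuted)
        for f in ds.genotypes.feature_ids:
            assert a.scores[f] == pytest.approx(b.scores[f], abs=1e-9)


class TestTuRF:
    @staticmethod
    def index_ranker(ds):
        """Scores features by their numeric id: G<k> scores k."""
        return FeatureRanking.from_scores(
            "index",
            ds.genotypes.feature_ids,
            [float(f[1:]) for f in ds.genotypes.feature_ids],
        )

    def test_drop_count_arithmetic(self, rng):
        ds = random_dataset(rng, 20, 100)
        seen = []

        def spy(sub):
            seen.append(sub.genotypes.n_features)
            return self.index_ranker(sub)

        turf_wrap(spy, ds, drop_fraction=0.10, min_features=50)
        assert seen[0] == 100 and seen[1] == 90  # floor(0.1*100)=10 removed

    def test_at_least_one_removed_when_floor_is_zero(self, rng):
        ds = random_dataset(rng, 20, 12)
        seen = []

        def spy(sub):
            seen.append(sub.genotypes.n_features)
            return self.index_ranker(sub)

        turf_wrap(spy, ds, drop_fraction=0.01, min_features=8)
        assert seen == [12, 11, 10, 9]

    def test_final_order_with_index_ranker(self, rng):
        ds = random_dataset(rng, 10, 10)
        r = turf_wrap(self.index_ranker, ds, drop_fraction=0.2, min_features=3)
        assert r.order == tuple(f"G{k}" for k in range(10, 0, -1))

    def test_no_iterations_when_already_small(self, rng):
        ds = random_dataset(rng, 10, 4)
        r = turf_wrap(self.index_ranker, ds, drop_fraction=0.5, min_features=5)
        assert r.order == ("G4", "G3", "G2", "G1")


class TestRegistry:
    def test_every_method_resolves_and_scores_all_features(self, rng):
        ds = random_dataset(rng, 60, 5)
        cfg = SelectorConfig(
            seed=0, rf_n_trees=20, gbm_n_trees=20, turf_min_features=2,
            penalized_loss="squared",
        )
        for name in ("mdr", "multisurf_star", "turf:multisurf_star", "rf",
                     "gbm", "lasso", "lasso_int", "enet"):
            r = get_ranker(name)(ds, cfg)
            assert set(r.order) == set(ds.genotypes.feature_ids)
            assert all(np.isfinite(v) for v in r.scores.values())

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            get_ranker("pca")

    def test_interaction_preset_matches_published_settings(self):
        cfg = SelectorConfig.preset("interaction", n_snps=100)
        assert cfg.rf_n_trees == 4500 and cfg.rf_mtry == 70
        assert cfg.gbm_n_trees == 15_000
        assert SelectorConfig.preset("interaction", n_snps=500).rf_mtry == 200
        main = SelectorConfig.preset("main")
        assert main.rf_n_trees == 1000 and main.gbm_n_trees == 800
        assert main.gbm_shrinkage == 0.01 and main.gbm_bag_fraction == 0.5
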