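from __future__ import annotations

import numpy as np
import pytest
from lifelines.utils import concordance_index as lifelines_cindex

from cascadewx import (
    FeatureRanking,
    SurvivalFitConfig,
    SyntheticConfig,
    evaluate_top_k_curve,
    generate_cohort,
    harrell_c_index,
    kaplan_meier,
    log_rank_test,
    median_split_log_rank,
    merge_rankings,
    preprocess,
    stratified_kfold,
)

from _oracles import cindex_pair_counts, merge_points
from conftest import make_surv, random_surv


class TestHarrellCIndex:
    def test_perfect_concordance(self):
        surv = make_surv([1, 2, 3], [False] * 3)
        assert harrell_c_index(np.array([3.0, 2.0, 1.0]), surv).value == 1.0

    def test_perfect_anticoncordance(self):
        surv = make_surv([1, 2, 3], [False] * 3)
        assert harrell_c_index(np.array([1.0, 2.0, 3.0]), surv).value == 0.0

    def test_matches_exhaustive_enumeration_with_ties(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            surv = random_surv(rng, 40, censor_frac=0.35, tie_times=True)
            risk = rng.integers(0, 5, size=40).astype(float)  # force risk ties
            res = harrell_c_index(risk, surv)
            val, conc, disc, tied = cindex_pair_counts(
                risk, surv.time_days, surv.event_observed
            )
            assert (res.concordant, res.discordant, res.tied_risk) == (conc, disc, tied)
            assert res.value == val

    def test_agrees_with_lifelines_on_tie_free_data(self):
        rng = np.random.default_rng(78)
        surv = random_surv(rng, 50, censor_frac=0.3)
        risk = rng.normal(size=50)
        res = harrell_c_index(risk, surv)
        want = lifelines_cindex(surv.time_days, -risk,
                                surv.event_observed.astype(int))
        np.testing.assert_allclose(res.value, want, atol=1e-12)

    def test_antisymmetry_without_risk_ties(self):
        rng = np.random.default_rng(79)
        surv = random_surv(rng, 30, censor_frac=0.4)
        risk = rng.normal(size=30)
        a = harrell_c_index(risk, surv).value
        b = harrell_c_index(-risk, surv).value
        np.testing.assert_allclose(a + b, 1.0, atol=1e-12)

    def test_no_comparable_pairs_errors(self):
        surv = make_surv([1.0], [False])
        with pytest.raises(ValueError, match="comparable"):
            harrell_c_index(np.array([0.0]), surv)


class TestLogRank:
    def test_identical_groups_give_null_statistic(self):
        times = [1, 2, 3, 4, 5]
        cens = [False, True, False, False, True]
        surv = make_surv(times + times, cens + cens)
        group = np.array([0] * 5 + [1] * 5, dtype=bool)
        res = log_rank_test(surv, group)
        np.testing.assert_allclose(res.statistic, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.p_value, 1.0, atol=1e-12)

    def test_hand_computed_four_event_table(self):
        # group0 deaths at 1, 2; group1 deaths at 3, 4; no censoring.
        # O-E accumulates 1-1/2 and 1-1/3; variances 1/4 and 2/9;
        # statistic = (7/6)^2 / (17/36) = 49/17.
        surv = make_surv([1, 2, 3, 4], [False] * 4)
        res = log_rank_test(surv, np.array([0, 0, 1, 1], dtype=bool))
        np.testing.assert_allclose(res.statistic, 49.0 / 17.0, atol=1e-9)

    def test_group_label_swap_invariance(self):
        rng = np.random.default_rng(80)
        surv = random_surv(rng, 40, censor_frac=0.3)
        group = rng.random(40) < 0.5
        a = log_rank_test(surv, group)
        b = log_rank_test(surv, ~group)
        np.testing.assert_allclose(a.statistic, b.statistic, atol=1e-9)
        assert 0.0 <= a.p_value <= 1.0

    def test_one_sided_group_errors(self):
        surv = make_surv([1, 2], [False, False])
        with pytest.raises(ValueError, match="non-empty"):
            log_rank_test(surv, np.array([True, True]))

    def test_zero_events_errors(self):
        surv = make_surv([1, 2], [True, True])
        with pytest.raises(ValueError, match="event"):
            log_rank_test(surv, np.array([True, False]))


class TestKaplanMeier:
    def test_four_distinct_deaths(self):
        surv = make_surv([1, 2, 3, 4], [False] * 4)
        km = kaplan_meier(surv)
        for t, s in [(0.9, 1.0), (1.5, 0.75), (2.5, 0.5), (3.5, 0.25), (4.5, 0.0)]:
            np.testing.assert_allclose(km.at(t * 365.25), s, atol=1e-12)

    def test_all_censored_is_flat_one(self):
        surv = make_surv([1, 2, 3], [True] * 3)
        km = kaplan_meier(surv)
        assert np.all(km.survival == 1.0)

    def test_mixed_toy_product_limit(self):
        # deaths at 1 and 3, censoring at 2: S(1) = 2/3, S(3) = 0
        surv = make_surv([1, 2, 3], [False, True, False])
        km = kaplan_meier(surv)
        np.testing.assert_allclose(km.at(1 * 365.25), 2.0 / 3.0, atol=1e-12)
        np.testing.assert_allclose(km.at(3 * 365.25), 0.0, atol=1e-12)

    def test_curve_shape_properties(self):
        rng = np.random.default_rng(81)
        surv = random_surv(rng, 50, censor_frac=0.4)
        km = kaplan_meier(surv)
        assert km.survival[0] == 1.0
        assert np.all(np.diff(km.survival) <= 0)


class TestStratifiedKFold:
    def test_balanced_strata_split_evenly(self):
        surv = make_surv(list(range(1, 21)), [True] * 10 + [False] * 10)
        folds = stratified_kfold(surv, 5, seed=0)
        for ids in folds.fold_ids:
            sub = surv.subset(ids.tolist())
            assert sub.n_samples == 4
            assert int(sub.censored.sum()) == 2

    def test_partition_property(self):
        rng = np.random.default_rng(82)
        surv = random_surv(rng, 37, censor_frac=0.4)
        folds = stratified_kfold(surv, 5, seed=3)
        seen = [s for ids in folds.fold_ids for s in ids.tolist()]
        assert sorted(seen) == sorted(surv.sample_ids.tolist())
        assert len(seen) == len(set(seen))

    def test_seed_determinism_and_variation(self):
        rng = np.random.default_rng(83)
        surv = random_surv(rng, 30, censor_frac=0.5)
        a = stratified_kfold(surv, 5, seed=0)
        b = stratified_kfold(surv, 5, seed=0)
        c = stratified_kfold(surv, 5, seed=1)
        assert [x.tolist() for x in a.fold_ids] == [x.tolist() for x in b.fold_ids]
        assert [x.tolist() for x in a.fold_ids] != [x.tolist() for x in c.fold_ids]

    def test_small_stratum_errors(self):
        surv = make_surv([1, 2, 3, 4, 5, 6], [True] + [False] * 5)
        with pytest.raises(ValueError, match="stratum"):
            stratified_kfold(surv, 3, seed=0)


def _ranking_from_order(order):
    n = len(order)
    return FeatureRanking(
        np.asarray(order, dtype=object),
        np.arange(n, 0, -1, dtype=float),
    )


class TestMergeRankings:
    def test_unanimous_top_gene(self):
        genes = [f"g{i:03d}" for i in range(100)]
        rankings = [_ranking_from_order(genes) for _ in range(5)]
        merged = merge_rankings(rankings)
        assert merged.points[0] == 5 * 99
        assert merged.gene_ids[0] == "g000"

    def test_symmetric_ranks_tie_break_by_id(self):
        r1 = _ranking_from_order(["A", "B", "C"])
        r2 = _ranking_from_order(["B", "A", "C"])
        merged = merge_rankings([r1, r2])
        assert merged.gene_ids.tolist() == ["A", "B", "C"]
        assert merged.points.tolist() == [3, 3, 0]

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(84)
        genes = [f"g{i}" for i in range(20)]
        rankings = []
        for _ in range(5):
            order = list(rng.permutation(genes))
            rankings.append(_ranking_from_order(order))
        merged = merge_rankings(rankings)
        order, points = merge_points([r.ranks() for r in rankings])
        assert merged.gene_ids.tolist() == order
        assert merged.points.tolist() == [points[g] for g in order]

    def test_invariant_to_fold_order(self):
        rng = np.random.default_rng(85)
        genes = [f"g{i}" for i in range(15)]
        rankings = [_ranking_from_order(list(rng.permutation(genes)))
                    for _ in range(4)]
        a = merge_rankings(rankings)
        b = merge_rankings(rankings[::-1])
        assert a.gene_ids.tolist() == b.gene_ids.tolist()
        assert a.points.tolist() == b.points.tolist()

    def test_gene_set_mismatch_errors(self):
        r1 = _ranking_from_order(["A", "B"])
        r2 = _ranking_from_order(["A", "C"])
        with pytest.raises(ValueError, match="gene sets"):
            merge_rankings([r1, r2])


@pytest.fixture(scope="module")
def prognostic_cohort():
    cfg = SyntheticConfig(n_samples=160, n_genes=30, n_causal=1,
                          causal_beta=2.0, seed=21)
    X, surv, truth = generate_cohort(cfg)
    return preprocess(X), surv, truth


class TestEvaluateTopK:
    def test_bookkeeping_and_signal(self, prognostic_cohort):
        Xp, surv, truth = prognostic_cohort
        causal = truth.causal_gene_ids[0]
        order = [causal] + [g for g in Xp.gene_ids.tolist() if g != causal]
        ranking = _ranking_from_order(order)
        folds = stratified_kfold(surv, 3, seed=1)
        curve = evaluate_top_k_curve(
            Xp, surv, ranking, folds, ks=[1, 2],
            cfg=SurvivalFitConfig(seed=5, max_epochs=40),
        )
        assert sorted(curve.per_fold["k"].unique().tolist()) == [1, 2]
        assert (curve.per_fold.groupby("k").size() == folds.k).all()
        # a single strongly prognostic gene should beat chance at k=1
        assert curve.mean_by_k.loc[1] > 0.6

    def test_k_beyond_ranking_errors(self, prognostic_cohort):
        Xp, surv, _ = prognostic_cohort
        ranking = _ranking_from_order(Xp.gene_ids.tolist())
        folds = stratified_kfold(surv, 3, seed=1)
        with pytest.raises(ValueError, match="exceeds"):
            evaluate_top_k_curve(Xp, surv, ranking, folds, ks=[Xp.n_genes + 1],
                                 cfg=SurvivalFitConfig(seed=5))

    def test_median_split_log_rank_separates_prognostic_risk(self, prognostic_cohort):
        Xp, surv, truth = prognostic_cohort
        risk = Xp.subset_genes(truth.causal_gene_ids.tolist()).values[:, 0]
        risk = risk * np.sign(truth.betas[0])
        res = median_split_log_rank(risk, surv)
        assert res.p_value < 0.05
        assert res.n_group0 + res.n_group1 == surv.n_samples


def test_null_ranking_gives_chance_level_cindex():
    """Pure-noise genes should score near 0.5 mean test c-index."""
    cfg = SyntheticConfig(n_samples=200, n_genes=10, n_causal=1,
                          causal_beta=0.0, seed=31)
    X, surv, _ = generate_cohort(cfg)
    Xp = preprocess(X)
    ranking = _ranking_from_order(Xp.gene_ids.tolist())
    folds = stratified_kfold(surv, 3, seed=2)
    curve = evaluate_top_k_curve(Xp, surv, ranking, folds, ks=[3],
                                 cfg=SurvivalFitConfig(seed=6, max_epochs=40))
    assert abs(curve.mean_by_k.loc[3] - 0.5) <= 0.1
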