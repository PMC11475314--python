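"""Summary statistics: RSE tables, growth ratios, groupings, ranking."""

import numpy as np
import pytest

from fluxprop.propagation import PropagationConfig, propagate
from fluxprop.simulate import NoiseModel, make_schedule
from fluxprop.stats import (
    GroupAssignment,
    detectability_curve,
    growth_ratio_summary,
    low_uptake_essential_set,
    pairwise_ranking,
    random_grouping,
    summarize_rse,
    top_k_by_rse,
)


@pytest.fixture(scope="module")
def prop_zero_noise(k1par, k1par_ref, toy_network, sched6):
    cfg = PropagationConfig(sched6, NoiseModel(0.0), n_draws=5, seed=1)
    return propagate(k1par_ref, k1par, toy_network, cfg)


class TestSummarizeRse:
    def test_zero_noise_gives_zero_rse(self, prop_zero_noise):
        summary = summarize_rse(prop_zero_noise)
        assert (summary["median_rse"] < 1e-6).all()
        assert (summary["n_converged"] == 5).all()

    def test_rse_grows_with_noise_level(self, prop_2pct, prop_20pct):
        s2, s20 = summarize_rse(prop_2pct), summarize_rse(prop_20pct)
        assert (s20["median_rse"] > s2["median_rse"]).all()

    def test_low_uptake_metabolites_have_high_rse(self, prop_2pct):
        """Rates tiny relative to the medium pool carry the largest RSE:
        proline (uptake far below its medium stock) tops the table, and
        tryptophan (smallest uptake) is noisier than glucose (largest)."""
        s = summarize_rse(prop_2pct)
        assert s["median_rse"].idxmax() == "proline"
        assert s.loc["tryptophan", "median_rse"] > s.loc["glucose", "median_rse"]


class TestLowUptakeEssentialSet:
    def test_published_sets_emerge_from_the_fixtures(self, k1par_ref, hyher_ref, toy_network):
        assert low_uptake_essential_set(k1par_ref, toy_network) == {
            "arginine", "lysine", "phenylalanine", "threonine", "tryptophan", "cysteine",
        }
        assert low_uptake_essential_set(hyher_ref, toy_network) == {
            "arginine", "leucine", "lysine", "methionine", "phenylalanine",
            "tryptophan", "cysteine",
        }

    def test_zero_factor_gives_empty_set(self, k1par_ref, toy_network):
        assert low_uptake_essential_set(k1par_ref, toy_network, factor=0.0) == frozenset()

    def test_large_factor_captures_all_essentials(self, k1par_ref, toy_network):
        covered = low_uptake_essential_set(k1par_ref, toy_network, factor=100.0)
        assert covered == toy_network.essential_set & set(k1par_ref.rates_complete)


class TestTopKByRse:
    def test_edge_sizes(self, prop_2pct):
        s = summarize_rse(prop_2pct)
        assert top_k_by_rse(s, 0) == frozenset()
        assert top_k_by_rse(s, len(s)) == frozenset(s.index)
        with pytest.raises(ValueError):
            top_k_by_rse(s, len(s) + 1)

    def test_top_set_contains_the_worst_metabolite(self, prop_2pct):
        s = summarize_rse(prop_2pct)
        assert s["median_rse"].idxmax() in top_k_by_rse(s, 7)

    def test_ties_broken_toward_smaller_uptake(self, prop_2pct):
        s = summarize_rse(prop_2pct).copy()
        s["median_rse"] = 1.0  # force a full tie
        picked = top_k_by_rse(s, 3)
        expected = set(s["q_ref"].abs().nsmallest(3).index)
        assert picked == expected


class TestGrowthRatioSummary:
    def test_zero_noise_ratios_are_one(self, prop_zero_noise):
        g = growth_ratio_summary(prop_zero_noise)
        assert g["iqr"] == pytest.approx(0.0, abs=1e-6)
        assert g["quantiles"]["q50"] == pytest.approx(1.0, rel=1e-6)
        assert g["feasible_fraction"] == 1.0

    def test_iqr_non_decreasing_along_rsd_ladder(self, k1par, k1par_ref, toy_network, sched6):
        iqrs = []
        for rsd in (0.05, 0.10, 0.15, 0.20):
            cfg = PropagationConfig(sched6, NoiseModel(rsd), 200, seed=55)
            iqrs.append(growth_ratio_summary(propagate(k1par_ref, k1par, toy_network, cfg))["iqr"])
        assert all(a <= b + 1e-12 for a, b in zip(iqrs, iqrs[1:]))

    def test_draw_order_invariance(self, prop_20pct):
        import copy

        shuffled = copy.copy(prop_20pct)
        perm = np.random.default_rng(0).permutation(prop_20pct.n_draws)
        shuffled.mu_fba = prop_20pct.mu_fba[perm]
        shuffled.feasible = prop_20pct.feasible[perm]
        assert growth_ratio_summary(shuffled) == growth_ratio_summary(prop_20pct)


class TestPairwiseRanking:
    def test_self_comparison_is_a_coin_flip_with_ties_incorrect(self, prop_2pct):
        r = pairwise_ranking(prop_2pct, prop_2pct, true_sign=1, delta_mu_true=0.01)
        n = prop_2pct.n_draws
        assert r.p_correct == pytest.approx((n * n - n) / 2 / n**2, abs=1e-12)
        assert r.tie_rate >= n / n**2

    def test_disjoint_supports_rank_perfectly(self, prop_2pct, k1par, k1par_ref, toy_network):
        import copy

        slower = copy.copy(prop_2pct)
        slower.mu_fba = prop_2pct.mu_fba * 0.1
        r = pairwise_ranking(prop_2pct, slower, true_sign=1, delta_mu_true=0.9 * 0.0384)
        assert r.p_correct == 1.0

    def test_two_toy_lines_with_16pct_gap_rank_correctly_at_low_noise(
        self, prop_2pct, hyher, hyher_ref, toy_network, sched6
    ):
        cfg = PropagationConfig(sched6, NoiseModel(0.02), 300, seed=202)
        res_b = propagate(hyher_ref, hyher, toy_network, cfg)
        r = pairwise_ranking(prop_2pct, res_b)
        assert r.p_correct >= 0.8
        assert r.n_pairs_compared <= r.n_pairs_total

    def test_zero_true_difference_rejected(self, prop_2pct):
        with pytest.raises(ValueError):
            pairwise_ranking(prop_2pct, prop_2pct)

    def test_infeasible_draws_dropped_from_denominator(self, prop_2pct, prop_20pct):
        import copy

        lossy = copy.copy(prop_20pct)
        lossy.feasible = prop_20pct.feasible.copy()
        lossy.feasible[:50] = False
        r = pairwise_ranking(prop_2pct, lossy, true_sign=1, delta_mu_true=0.01)
        assert r.n_pairs_compared == prop_2pct.feasible.sum() * lossy.feasible.sum()


class TestRandomGrouping:
    def test_exact_partition(self):
        mets = [f"m{i}" for i in range(12)]
        g = random_grouping(mets, [5, 7], seed=3)
        assert g.groups["group1"] | g.groups["group2"] == set(mets)
        assert len(g.groups["group1"]) == 5

    def test_different_seeds_differ(self):
        mets = [f"m{i}" for i in range(12)]
        assert random_grouping(mets, [6, 6], 1).groups != random_grouping(mets, [6, 6], 2).groups

    def test_bad_sizes_rejected(self):
        with pytest.raises(ValueError):
            random_grouping(["a", "b"], [3], seed=0)

    def test_overlapping_assignment_rejected(self):
        with pytest.raises(ValueError):
            GroupAssignment(groups={"g1": frozenset({"a"}), "g2": frozenset({"a", "b"})})

    def test_random_groups_do_not_match_biology_based_improvement(
        self, k1par, k1par_ref, toy_network, sched6, prop_20pct
    ):
        """An arbitrary 6-metabolite group measured accurately helps far less
        than the low-uptake essential set of the same size."""
        from fluxprop.propagation import grouped_propagate

        mets = sorted(k1par_ref.rates_complete)
        low = low_uptake_essential_set(k1par_ref, toy_network)
        cfg = PropagationConfig(sched6, NoiseModel(0.20), 300, seed=101)
        res_bio = grouped_propagate(k1par_ref, k1par, toy_network, cfg,
                                    {low: 0.02, frozenset(set(mets) - low): 0.20})
        rnd = random_grouping(mets, [len(low), len(mets) - len(low)], seed=17)
        g1 = rnd.groups["group1"]
        assert g1 != low  # overwhelmingly likely; fixed seed makes it certain
        res_rnd = grouped_propagate(k1par_ref, k1par, toy_network, cfg,
                                    {g1: 0.02, frozenset(set(mets) - g1): 0.20})
        assert growth_ratio_summary(res_bio)["iqr"] < growth_ratio_summary(res_rnd)["iqr"]


class TestDetectability:
    def test_curve_monotone_endpoints_and_threshold(self, k1par, k1par_ref, toy_network, sched6):
        from fluxprop.synthetic_data import scaled_dataset

        mets = set(k1par_ref.rates_complete)
        low = low_uptake_essential_set(k1par_ref, toy_network)
        rsd_map = {low: 0.02, frozenset(mets - low): 0.20}
        from fluxprop.propagation import grouped_propagate
        from fluxprop.reference_fba import build_reference

        cfg = PropagationConfig(sched6, NoiseModel(0.20), 200, seed=31)
        res_a = grouped_propagate(k1par_ref, k1par, toy_network, cfg, rsd_map)
        pairs = []
        for k, delta in enumerate((0.05, 0.20, 0.40)):
            ds_b = scaled_dataset(k1par, k1par_ref.mu_ref, k1par_ref.mu_ref / (1 + delta))
            ref_b = build_reference(ds_b, toy_network)
            cfg_b = PropagationConfig(sched6, NoiseModel(0.20), 200, seed=40 + k)
            low_b = low_uptake_essential_set(ref_b, toy_network)
            res_b = grouped_propagate(ref_b, ds_b, toy_network, cfg_b,
                                      {low_b: 0.02, frozenset(mets - low_b): 0.20})
            pairs.append((res_a, res_b))
        tab = detectability_curve(pairs)
        assert tab["delta_mu_pct"].is_monotonic_increasing
        assert tab["p_correct"].iloc[-1] >= tab["p_correct"].iloc[0]
        # a >= 20% growth difference is reliably detected with accurate
        # low-uptake measurements
        assert (tab.loc[tab["delta_mu_pct"] >= 19.0, "p_correct"] >= 0.8).all()


def test_doubling_replicates_changes_ranking_little(k1par, k1par_ref, hyher, hyher_ref, toy_network):
    ps = {}
    for nrep in (3, 6):
        sched = make_schedule("regular", 12.0, n_replicates=nrep)
        cfg_a = PropagationConfig(sched, NoiseModel(0.10), 200, seed=51)
        cfg_b = PropagationConfig(sched, NoiseModel(0.10), 200, seed=52)
        res_a = propagate(k1par_ref, k1par, toy_network, cfg_a)
        res_b = propagate(hyher_ref, hyher, toy_network, cfg_b)
        ps[nrep] = pairwise_ranking(res_a, res_b).p_correct
    assert abs(ps[6] - ps[3]) < 0.1
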