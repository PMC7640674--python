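"""Respondent/response/VAS simulation: distributions, determinism, substreams."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from bwspref.counting import counting_table
from bwspref.synthetic_data import (
    UtilityConfig,
    block_pair_probabilities,
    maxdiff_pair_prob,
    simulate_bws_responses,
    simulate_profiles,
    simulate_vas,
    study_utilities,
)


def brute_force_pair_prob(utilities, block, i, j):
    """Independent oracle: normalise exp(u_i - u_j) by explicit summation
    over every ordered pair of the block."""
    denom = sum(
        math.exp(utilities[a] - utilities[b])
        for a, b in itertools.permutations(block, 2)
    )
    return math.exp(utilities[i] - utilities[j]) / denom


class TestPairProbabilities:
    def test_uniform_when_utilities_equal(self):
        u = {x: 0.0 for x in "ABCD"}
        for i, j in itertools.permutations("ABCD", 2):
            assert maxdiff_pair_prob(u, "ABCD", i, j) == pytest.approx(1 / 12, abs=1e-12)

    def test_single_strong_item(self):
        u = {"A": 2.0, "B": 0.0, "C": 0.0, "D": 0.0}
        expected = brute_force_pair_prob(u, "ABCD", "A", "B")
        # closed form: exp(2) / (3 exp(2) + 3 exp(-2) + 6)
        assert expected == pytest.approx(
            math.exp(2) / (3 * math.exp(2) + 3 * math.exp(-2) + 6), rel=1e-14
        )
        assert expected == pytest.approx(0.2586, abs=5e-5)
        assert maxdiff_pair_prob(u, "ABCD", "A", "B") == pytest.approx(expected, abs=1e-12)

    def test_invalid_pairs_rejected(self):
        u = {x: 0.0 for x in "ABCD"}
        with pytest.raises(ValueError):
            maxdiff_pair_prob(u, "ABCD", "A", "A")
        with pytest.raises(ValueError):
            maxdiff_pair_prob(u, "ABC", "A", "D")

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=4, max_size=4))
    def test_matches_brute_force_and_normalises(self, values):
        block = ["w", "x", "y", "z"]
        u = dict(zip(block, values))
        pairs, probs = block_pair_probabilities(u, block)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        for (i, j), p in zip(pairs, probs):
            assert p == pytest.approx(brute_force_pair_prob(u, block, i, j), abs=1e-12)


class TestProfiles:
    def test_deterministic_under_seed(self):
        a = simulate_profiles(25, stratum="rural", seed=9)
        b = simulate_profiles(25, stratum="rural", seed=9)
        assert a == b
        c = simulate_profiles(25, stratum="rural", seed=10)
        assert a != c

    def test_zero_respondents(self):
        assert simulate_profiles(0, stratum="urban", seed=1) == []

    def test_marginal_frequencies_recovered(self):
        # female fraction among n=913 within 99% binomial bounds of 0.5323
        profiles = simulate_profiles(913, stratum="urban", seed=3,
                                     marginals={"sex": {"male": 0.4677, "female": 0.5323},
                                                "age": (49.78, 8.148, 40.0)})
        frac = np.mean([p.sex == "female" for p in profiles])
        half_width = 2.576 * math.sqrt(0.5323 * 0.4677 / 913)
        assert abs(frac - 0.5323) < half_width
        assert all(p.age >= 40.0 for p in profiles)

    def test_invalid_probability_vector_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            simulate_profiles(5, marginals={"sex": {"male": 0.6, "female": 0.5}}, seed=0)


class TestResponseSimulation:
    def test_uniform_utilities_give_uniform_pairs(self, design13):
        util = UtilityConfig(
            utilities={i: 0.0 for i in design13.catalog.items}, reference="myopathy"
        )
        profiles = simulate_profiles(2000, stratum="urban", seed=11)
        ds = simulate_bws_responses(design13, util, profiles, seed=11)
        # pool alternative slots over blocks: 26000 draws over 12 slots
        slot_counts = np.zeros(12)
        for bi, bid in enumerate(design13.block_ids):
            members = design13.block_items(bi)
            pairs = [(i, j) for i in members for j in members if i != j]
            sub = ds.records[ds.records["block_id"] == bid]
            observed = list(zip(sub["best_item"], sub["worst_item"]))
            for s, pair in enumerate(pairs):
                slot_counts[s] += observed.count(pair)
        chi2 = ((slot_counts - slot_counts.mean()) ** 2 / slot_counts.mean()).sum()
        assert stats.chi2.sf(chi2, df=11) > 1e-3

    def test_dominant_item_always_best(self, design13):
        u = {i: 0.0 for i in design13.catalog.items}
        u["cancer"] = 10.0
        util = UtilityConfig(utilities=u, reference="myopathy")
        profiles = simulate_profiles(300, stratum="urban", seed=12)
        ds = simulate_bws_responses(design13, util, profiles, seed=12)
        in_block = ds.records["block_id"].isin(
            [design13.block_ids[b] for b in design13.blocks_containing("cancer")]
        )
        frac = (ds.records.loc[in_block, "best_item"] == "cancer").mean()
        # exact lower bound: 3 exp(10) / (3 exp(10) + 3 exp(-10) + 6) > 0.999
        assert frac > 0.99

    def test_missing_rate_bounds(self, design13, util_total):
        profiles = simulate_profiles(50, stratum="urban", seed=13)
        none = simulate_bws_responses(design13, util_total, profiles, seed=13, missing_rate=1.0)
        assert none.n_records == 0
        some = simulate_bws_responses(design13, util_total, profiles, seed=13, missing_rate=0.3)
        assert 0 < some.n_records < 50 * 13

    def test_respondent_substreams_stable_under_sample_growth(self, design13, util_total):
        profiles = simulate_profiles(30, stratum="urban", seed=14)
        small = simulate_bws_responses(design13, util_total, profiles[:10], seed=14)
        large = simulate_bws_responses(design13, util_total, profiles, seed=14)
        ids = {p.respondent_id for p in profiles[:10]}
        subset = large.records[large.records["respondent_id"].isin(ids)].reset_index(drop=True)
        assert subset.equals(small.records)

    def test_byte_identical_under_seed(self, design13, util_total, tmp_path):
        profiles = simulate_profiles(20, stratum="provider", seed=15)
        files = []
        for run in range(2):
            ds = simulate_bws_responses(design13, util_total, profiles, seed=15)
            path = tmp_path / f"run{run}.csv"
            ds.records.to_csv(path, index=False)
            files.append(path.read_bytes())
        assert files[0] == files[1]

    def test_records_valid_against_design(self, small_dataset):
        assert small_dataset.validate() == []

    def test_covariate_effects_shift_choices(self, design13):
        u = {i: 0.0 for i in design13.catalog.items}
        util = UtilityConfig(
            utilities=u,
            reference="myopathy",
            covariate_effects={("sex", "female"): {"cancer": 8.0}},
        )
        profiles = simulate_profiles(200, stratum="urban", seed=16)
        ds = simulate_bws_responses(design13, util, profiles, seed=16)
        female = {p.respondent_id for p in profiles if p.sex == "female"}
        rec = ds.records[ds.records["best_item"] == "cancer"]
        frac_female = rec["respondent_id"].isin(female).mean()
        assert frac_female > 0.8  # cancer picked best almost only by women


class TestVAS:
    def test_noise_free_scores_monotone_in_utility(self, util_total):
        cfg = UtilityConfig(
            utilities=util_total.utilities, reference="myopathy", vas_noise_sd=0.0
        )
        profiles = simulate_profiles(3, stratum="urban", seed=17)
        vas = simulate_vas(cfg, profiles, seed=17)
        by_item = vas.groupby("item_id")["score"].first()
        order = sorted(cfg.utilities, key=cfg.utilities.get)
        assert by_item.reindex(order).is_monotonic_increasing

    def test_scores_within_unit_interval(self, util_total):
        profiles = simulate_profiles(100, stratum="urban", seed=18)
        vas = simulate_vas(util_total, profiles, seed=18)
        assert ((vas["score"] > 0) & (vas["score"] < 1)).all()

    def test_mean_rank_order_matches_utility_order(self, util_total):
        cfg = UtilityConfig(
            utilities=util_total.utilities, reference="myopathy", vas_noise_sd=0.2
        )
        profiles = simulate_profiles(1000, stratum="urban", seed=19)
        vas = simulate_vas(cfg, profiles, seed=19)
        means = vas.groupby("item_id")["score"].mean()
        by_util = sorted(cfg.utilities, key=cfg.utilities.get)
        assert list(means.reindex(by_util).sort_values().index) == by_util


def test_counting_ranks_recover_separated_utilities(design13, util_total):
    """Mean B-W ranks on simulated data reproduce the utility order for
    all item pairs separated by at least 0.3 utility units (n=913)."""
    u = util_total.utilities
    separated = [
        (a, b)
        for a, b in itertools.combinations(u, 2)
        if abs(u[a] - u[b]) >= 0.3
    ]
    for seed in (101, 102, 103):
        profiles = simulate_profiles(913, stratum="urban", seed=seed)
        ds = simulate_bws_responses(design13, util_total, profiles, seed=seed)
        mean_bw = counting_table(ds)["mean_bw"]
        for a, b in separated:
            assert (mean_bw[a] - mean_bw[b]) * (u[a] - u[b]) > 0
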