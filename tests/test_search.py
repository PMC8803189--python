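import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from attapriori.dynamics import enumerate_all_attractors
from attapriori.search import (
    AttractorCriteria,
    SearchConfig,
    UnreachableTargetError,
    attapriori_search,
    canonicalize_prior,
    iterate_start_vectors,
    rank_start_vector,
    trial_index_of_target,
    uniform_prior,
    unrank_start_vector,
)
from attapriori.synthetic import NKConfig, derive_seed, generate_nk, perturb_state


def names(n):
    return [f"x{i+1}" for i in range(n)]


class TestCanonicalize:
    def test_role_exchange_below_half(self):
        prior = canonicalize_prior(["a"], [1], [0.3])
        assert prior.guess == (0,) and prior.confidence == (0.7,)

    def test_above_half_unchanged(self):
        prior = canonicalize_prior(["a"], [0], [0.75])
        assert prior.guess == (0,) and prior.confidence == (0.75,)

    def test_class_partition(self):
        prior = canonicalize_prior(names(3), [0, 0, 0], [1.0, 0.9, 0.5])
        classes = prior.classes
        assert [c.confidence for c in classes] == [1.0, 0.9, 0.5]
        assert classes[0].fixed and classes[2].uninformed
        covered = sorted(p for c in classes for p in c.positions)
        assert covered == [0, 1, 2]

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_invalid_probability(self, bad):
        with pytest.raises(ValueError):
            canonicalize_prior(["a"], [0], [bad])


class TestRankUnrank:
    def test_printed_order_for_three_bits(self):
        prior = uniform_prior(names(3), (0, 0, 0), 0.75)
        order = ["000", "001", "010", "100", "011", "101", "110", "111"]
        for i, pattern in enumerate(order, start=1):
            v = tuple(int(c) for c in pattern)
            assert rank_start_vector(prior, v) == i
            assert unrank_start_vector(prior, i) == v

    def test_guess_is_always_first(self):
        prior = uniform_prior(names(5), (1, 0, 1, 1, 0), 0.8)
        assert rank_start_vector(prior, (1, 0, 1, 1, 0)) == 1

    def test_bijection_n12(self):
        prior = uniform_prior(names(12), (0,) * 12, 0.9)
        for i in range(1, 4097):
            assert rank_start_vector(prior, unrank_start_vector(prior, i)) == i

    def test_agrees_with_materialized_stream(self):
        rng = np.random.default_rng(7)
        for trial in range(10):
            n = int(rng.integers(4, 9))
            guess = tuple(int(b) for b in rng.integers(0, 2, n))
            prior = uniform_prior(names(n), guess, 0.8)
            stream = list(iterate_start_vectors(prior))
            picks = rng.integers(0, 1 << n, size=5)
            for idx in picks:
                target = stream[int(idx)]
                assert trial_index_of_target(prior, target) == int(idx) + 1

    def test_conflict_with_fixed_bit_is_unreachable(self):
        prior = canonicalize_prior(names(3), [0, 0, 0], [1.0, 0.8, 0.8])
        with pytest.raises(UnreachableTargetError):
            trial_index_of_target(prior, (1, 0, 0))

    def test_index_out_of_range(self):
        prior = uniform_prior(names(3), (0, 0, 0), 0.8)
        with pytest.raises(ValueError):
            unrank_start_vector(prior, 9)


class TestStream:
    def test_all_fixed_yields_only_guess(self):
        prior = canonicalize_prior(names(4), [1, 0, 1, 0], [1.0] * 4)
        assert list(iterate_start_vectors(prior)) == [(1, 0, 1, 0)]

    @pytest.mark.parametrize("n", [3, 6, 8])
    def test_completeness_single_class(self, n):
        prior = uniform_prior(names(n), (0,) * n, 0.7)
        stream = list(iterate_start_vectors(prior))
        assert len(stream) == 1 << n
        assert len(set(stream)) == 1 << n

    def test_hamming_distance_nondecreasing(self):
        guess = (1, 0, 1, 0, 1, 1)
        prior = uniform_prior(names(6), guess, 0.8)
        dists = [
            sum(a != b for a, b in zip(s, guess))
            for s in iterate_start_vectors(prior)
        ]
        assert dists == sorted(dists)

    def test_two_class_log_odds_cost_nondecreasing(self):
        # bits 0-2 at 0.9, bits 3-5 at 0.7: stream cost must never decrease
        probs = [0.9] * 3 + [0.7] * 3
        prior = canonicalize_prior(names(6), [0] * 6, probs)
        w = {0.9: math.log(0.9 / 0.1), 0.7: math.log(0.7 / 0.3)}
        costs = []
        for s in iterate_start_vectors(prior):
            costs.append(sum(w[p] for s_i, g_i, p in zip(s, prior.guess, probs) if s_i != g_i))
        assert len(costs) == 64
        for a, b in zip(costs, costs[1:]):
            assert b >= a - 1e-9

    def test_two_class_stream_matches_sorted_bruteforce(self):
        probs = [0.9] * 2 + [0.7] * 3
        prior = canonicalize_prior(names(5), [0] * 5, probs)
        stream = list(iterate_start_vectors(prior))
        assert sorted(stream) == sorted(itertools.product((0, 1), repeat=5))
        w = [math.log(p / (1 - p)) for p in probs]
        def cost(s):
            return sum(wi for si, wi in zip(s, w) if si == 1)
        brute = sorted(itertools.product((0, 1), repeat=5), key=cost)
        # compare total cost profile (ties are broken differently but cost order must agree)
        assert [round(cost(s), 9) for s in stream] == [round(cost(s), 9) for s in brute]

    def test_fixed_bits_invariant_across_stream(self):
        prior = canonicalize_prior(names(4), [1, 0, 0, 1], [1.0, 0.8, 0.8, 1.0])
        for s in iterate_start_vectors(prior):
            assert s[0] == 1 and s[3] == 1

    def test_uninformed_bits_complete_and_seeded(self):
        probs = [0.8, 0.5, 0.5]
        prior = canonicalize_prior(names(3), [0] * 3, probs)
        s1 = list(iterate_start_vectors(prior, SearchConfig(seed=1)))
        s2 = list(iterate_start_vectors(prior, SearchConfig(seed=1)))
        s3 = list(iterate_start_vectors(prior, SearchConfig(seed=2)))
        assert s1 == s2
        assert sorted(s1) == sorted(itertools.product((0, 1), repeat=3))
        assert sorted(s3) == sorted(s1)  # same coverage, different order allowed

    def test_class_threshold_limits_flips(self):
        prior = uniform_prior(names(5), (0,) * 5, 0.8)
        config = SearchConfig(class_thresholds={0.8: 1})
        stream = list(iterate_start_vectors(prior, config))
        assert len(stream) == 6  # guess + 5 single flips
        assert all(sum(s) <= 1 for s in stream)


class TestSearch:
    def test_guess_on_fixed_point_found_at_trial_one(self, net3):
        prior = uniform_prior(net3.node_names, (0, 0, 0), 0.9)
        res = attapriori_search(net3, prior)
        assert res.trials_used == 1
        assert res.attractors[0].cycle == ((0, 0, 0),)
        assert res.termination_reason == "criteria_met"

    def test_period_criteria_rejects_then_finds(self, net3):
        prior = uniform_prior(net3.node_names, (1, 1, 0), 0.9)
        res = attapriori_search(net3, prior, AttractorCriteria(period_min=2))
        assert res.trials_used == 2
        assert res.attractors[0].cycle == ((0, 1, 1), (1, 0, 0))

    def test_collect_all_equals_bruteforce_census(self, net3):
        prior = uniform_prior(net3.node_names, (0, 0, 0), 0.9)
        res = attapriori_search(net3, prior, config=SearchConfig(mode="collect_all"))
        assert set(res.attractors) == enumerate_all_attractors(net3)
        assert res.trials_used == 8 and res.termination_reason == "exhausted"

    @pytest.mark.parametrize("seed", range(15))
    def test_collect_all_oracle_equivalence_random_networks(self, seed):
        net = generate_nk(NKConfig(n=7, k=2, seed=seed))
        prior = uniform_prior(net.node_names, (0,) * 7, 0.7)
        res = attapriori_search(net, prior, config=SearchConfig(mode="collect_all"))
        assert set(res.attractors) == enumerate_all_attractors(net)

    def test_trial_limit_exact(self, net3):
        prior = uniform_prior(net3.node_names, (1, 1, 1), 0.9)
        res = attapriori_search(
            net3,
            prior,
            AttractorCriteria(period_min=99),
            SearchConfig(max_trials=3),
        )
        assert res.trials_used == 3
        assert res.termination_reason == "trial_limit"

    def test_required_values_stable_in_every_state(self, net3):
        # the period-2 cycle {011,100} has no node stable at 1
        prior = uniform_prior(net3.node_names, (1, 1, 0), 0.9)
        res = attapriori_search(
            net3,
            prior,
            AttractorCriteria(period_min=2, required_values={"x1": 1}),
            SearchConfig(max_trials=8),
        )
        assert res.attractors == []

    def test_node_set_mismatch(self, net3):
        prior = uniform_prior(["a", "b", "c"], (0, 0, 0), 0.9)
        with pytest.raises(ValueError):
            attapriori_search(net3, prior)


class TestMonotonePriorBenefit:
    def test_higher_confidence_means_fewer_trials(self):
        """Paired over seeded targets: mean trial index at p=0.9 <= at p=0.7."""
        n = 20
        diffs = []
        for r in range(300):
            target = tuple(int(b) for b in np.random.default_rng(r).integers(0, 2, n))
            idx = {}
            for p in (0.9, 0.7):
                guess = perturb_state(target, p, derive_seed(42, "mono", r, int(p * 10)))
                prior = uniform_prior(names(n), guess, p)
                idx[p] = trial_index_of_target(prior, target)
            diffs.append(idx[0.7] - idx[0.9])
        diffs = np.asarray(diffs, dtype=float)
        se = diffs.std(ddof=1) / math.sqrt(len(diffs))
        assert diffs.mean() + 3 * se > 0
        assert diffs.mean() > 0
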