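"""Richness-preserving null model machinery: exact formulas and Monte Carlo."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gillsym.errors import DataError
from gillsym.null_models import (
    NullTestConfig,
    cooccurrence_report,
    exact_combination_null,
    guarantee_prob,
    mc_randomize,
    pair_absence_test,
    pair_inclusion_prob,
)

from conftest import brute_force_guarantee, brute_force_pair_absence, make_pm

POOL = [f"sp{i}" for i in range(1, 8)]


class TestPairInclusionProb:
    @pytest.mark.parametrize("k,S,expected", [
        (0, 7, 0.0),
        (1, 7, 0.0),
        (2, 7, 1 / 21),
        (7, 7, 1.0),
    ])
    def test_known_values(self, k, S, expected):
        assert pair_inclusion_prob(k, S) == pytest.approx(expected, abs=1e-15)

    def test_enumeration_oracle_k2_s7(self):
        # exactly one of the 21 2-subsets of 7 species contains a fixed pair
        subsets = list(itertools.combinations(range(7), 2))
        hits = sum(1 for s in subsets if {0, 1} <= set(s))
        assert pair_inclusion_prob(2, 7) == pytest.approx(hits / len(subsets))

    def test_closed_form_identity_up_to_s12(self):
        for S in range(2, 13):
            for k in range(0, S + 1):
                expected = k * (k - 1) / (S * (S - 1)) if k >= 2 else 0.0
                assert pair_inclusion_prob(k, S) == pytest.approx(expected, abs=1e-12)

    def test_strictly_increasing_in_k(self):
        for S in range(3, 13):
            probs = [pair_inclusion_prob(k, S) for k in range(2, S + 1)]
            assert all(b > a for a, b in zip(probs, probs[1:]))

    def test_k_beyond_pool_rejected(self):
        with pytest.raises(DataError):
            pair_inclusion_prob(8, 7)


class TestPairAbsence:
    def test_all_richness_one_gives_p_one(self):
        pm = make_pm([{"sp1"}, {"sp2"}, {"sp3"}], POOL)
        for res in pair_absence_test(pm):
            assert res.p_exact == pytest.approx(1.0)

    def test_two_hosts_of_richness_two(self):
        pm = make_pm([{"sp1", "sp2"}, {"sp3", "sp4"}], POOL)
        res = pair_absence_test(pm, pairs=[("sp5", "sp6")])
        assert res[0].p_exact == pytest.approx((20 / 21) ** 2)

    def test_full_pool_host_forces_p_zero(self):
        # a host carrying the whole pool co-occurs every pair with certainty:
        # its absence factor 1 - p(k=S) is exactly zero, and no unobserved
        # pair remains for the automatic test to consider
        assert pair_inclusion_prob(7, 7) == 1.0
        pm = make_pm([set(POOL)], POOL)
        assert pair_absence_test(pm) == []

    def test_observed_pair_is_rejected(self):
        pm = make_pm([{"sp1", "sp2"}], POOL)
        with pytest.raises(DataError, match="observed together"):
            pair_absence_test(pm, pairs=[("sp1", "sp2")])

    def test_default_pairs_are_the_never_cooccurring_ones(self):
        pm = make_pm([{"sp1", "sp2"}, {"sp1", "sp3"}], ["sp1", "sp2", "sp3"])
        res = pair_absence_test(pm)
        assert {tuple(sorted(r.pair)) for r in res} == {("sp2", "sp3")}

    @pytest.mark.parametrize("richness,S", [
        ([2, 2], 4), ([2, 3], 5), ([1, 2, 3], 4), ([3, 3, 2, 2], 5), ([2], 3),
    ])
    def test_matches_brute_force_enumeration(self, richness, S):
        pool = POOL[:S]
        rows = [set(pool[i] for i in range(k)) for k in richness]
        # craft a pair that never co-occurs: use last two taxa, absent from rows
        pm = make_pm(rows, pool)
        res = pair_absence_test(pm, pairs=[(pool[-1], pool[-2])])
        oracle = brute_force_pair_absence(richness, S)
        assert res[0].p_exact == pytest.approx(oracle, abs=1e-12)


class TestGuarantee:
    @pytest.mark.parametrize("ks,S,m,expected", [
        ([1], 7, 3, 3 / 7),
        ([5], 7, 3, 1.0),
        ([], 7, 3, 1.0),
        ([0, 2], 7, 3, 0.0),
    ])
    def test_known_values(self, ks, S, m, expected):
        assert guarantee_prob(ks, S, m).probability == pytest.approx(expected)

    def test_designated_equals_pool_gives_one(self):
        assert guarantee_prob([1, 2, 3], 5, 5).probability == pytest.approx(1.0)

    @pytest.mark.parametrize("richness,S,m", [
        ([1, 2], 4, 2), ([2, 2, 3], 5, 2), ([1, 1, 1, 1], 3, 1), ([3, 2], 5, 3),
    ])
    def test_matches_brute_force_enumeration(self, richness, S, m):
        res = guarantee_prob(richness, S, m)
        oracle = brute_force_guarantee(richness, S, m)
        assert res.probability == pytest.approx(oracle, abs=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.integers(0, 6), max_size=8), st.integers(0, 6))
    def test_monotone_in_m_and_k(self, ks, m):
        S = 7
        base = guarantee_prob(ks, S, m).probability
        if m < S:
            assert guarantee_prob(ks, S, m + 1).probability >= base - 1e-12
        for i, k in enumerate(ks):
            if k < S:
                bumped = list(ks)
                bumped[i] = k + 1
                assert guarantee_prob(bumped, S, m).probability >= base - 1e-12


class TestExactCombinationNull:
    def test_single_host_observed_once(self):
        expected, p = exact_combination_null(n_k=1, S=7, k=2, observed=1)
        assert expected == pytest.approx(1 / 21)
        assert p == pytest.approx(2 / 21)

    def test_nothing_observable(self):
        assert exact_combination_null(0, 7, 2, 0) == (0.0, 1.0)

    def test_observation_at_the_mode_clips_to_one(self):
        expected, p = exact_combination_null(21, 7, 2, 1)
        assert expected == pytest.approx(1.0)
        assert p == 1.0

    def test_observed_beyond_hosts_rejected(self):
        with pytest.raises(DataError):
            exact_combination_null(3, 7, 2, 4)


class TestMcRandomize:
    def test_specimen_conservation_of_null_means(self):
        # with all k=2, null means over the 21 pairs must sum to n
        pm = make_pm([{POOL[i % 7], POOL[(i + 1) % 7]} for i in range(10)], POOL)
        res = mc_randomize(pm, NullTestConfig(replicates=2000, seed=1))
        assert sum(r.null_mean for r in res) == pytest.approx(10.0, abs=1e-9)

    def test_null_means_near_expected_for_21_pairs(self):
        pairs = list(itertools.combinations(POOL, 2))
        pm = make_pm([set(p) for p in pairs], POOL)  # n=21, all k=2
        res = mc_randomize(pm, NullTestConfig(replicates=10_000, seed=2))
        sd = math.sqrt(21 * (1 / 21) * (20 / 21))
        tol = 4 * sd / math.sqrt(10_000)
        assert len(res) == 21
        for r in res:
            assert abs(r.null_mean - 1.0) <= tol

    def test_planted_pattern_hits_pseudocount_floor(self):
        pm = make_pm([{"sp1", "sp3", "sp4"}] * 20, POOL)
        res = mc_randomize(pm, NullTestConfig(replicates=10_000, seed=3))
        planted = next(r for r in res if r.pattern == {"sp1", "sp3", "sp4"})
        assert planted.observed == 20
        assert planted.p_two == pytest.approx(2 / 10_001)
        assert planted.p_holm < 0.05

    def test_envelope_brackets_null_mean(self):
        pm = make_pm([{"sp1", "sp2"}, {"sp3"}, {"sp4", "sp5", "sp6"}], POOL)
        for r in mc_randomize(pm, NullTestConfig(replicates=500, seed=4)):
            assert r.env_low <= round(r.null_mean) or r.env_low <= r.null_mean
            assert r.env_low <= r.env_high
            assert 0 < r.p_two <= 1 and r.p_holm >= r.p_two - 1e-12

    def test_seed_determinism(self):
        pm = make_pm([{"sp1", "sp2"}, {"sp2", "sp3"}], POOL)
        a = mc_randomize(pm, NullTestConfig(replicates=1000, seed=5))
        b = mc_randomize(pm, NullTestConfig(replicates=1000, seed=5))
        assert a == b

    def test_universe_options(self):
        pm = make_pm([{"sp1"}, {"sp1", "sp2"}], POOL)
        sizes = mc_randomize(pm, NullTestConfig(replicates=50, seed=6))
        assert len(sizes) == 7 + 21
        observed = mc_randomize(pm, NullTestConfig(
            replicates=50, seed=6, combination_universe="observed_only"))
        assert {r.pattern for r in observed} == {
            frozenset({"sp1"}), frozenset({"sp1", "sp2"})}
        allne = mc_randomize(pm, NullTestConfig(
            replicates=50, seed=6, combination_universe="all_nonempty"))
        assert len(allne) == 2**7 - 1

    def test_invalid_config_rejected(self):
        with pytest.raises(DataError):
            NullTestConfig(replicates=0)
        with pytest.raises(DataError):
            NullTestConfig(envelope_level=1.0)
        with pytest.raises(DataError):
            NullTestConfig(combination_universe="everything")


class TestCooccurrenceReport:
    def test_single_group_equals_plain_mc(self):
        pm = make_pm([{"sp1", "sp2"}, {"sp3"}], POOL, groups=["A", "A"])
        cfg = NullTestConfig(replicates=500, seed=11)
        report = cooccurrence_report(pm, cfg)
        direct = mc_randomize(pm, NullTestConfig(replicates=500, seed=11))
        assert report.per_group["A"] == direct
        assert set(report.per_group) == {"A", "combined"}

    def test_deterministic_given_seed(self):
        pm = make_pm([{"sp1", "sp2"}, {"sp2", "sp3"}, {"sp1"}], POOL,
                     groups=["A", "B", "B"])
        cfg = NullTestConfig(replicates=300, seed=12)
        r1 = cooccurrence_report(pm, cfg, fixers=["sp1", "sp2"])
        r2 = cooccurrence_report(pm, cfg, fixers=["sp1", "sp2"])
        assert r1.per_group == r2.per_group
        assert r1.guarantee == r2.guarantee

    def test_guarantee_uses_observed_richness(self):
        pm = make_pm([{"sp1"}, {"sp2", "sp3"}], POOL, groups=["A", "A"])
        report = cooccurrence_report(pm, NullTestConfig(replicates=50, seed=13),
                                     fixers=["sp1", "sp2", "sp4"])
        expected = (3 / 7) * (1 - math.comb(4, 2) / math.comb(7, 2))
        assert report.guarantee.probability == pytest.approx(expected)

    def test_unknown_fixer_rejected(self):
        pm = make_pm([{"sp1"}], POOL)
        with pytest.raises(DataError):
            cooccurrence_report(pm, NullTestConfig(replicates=10, seed=1),
                                fixers=["nope"])
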