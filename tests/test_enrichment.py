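"""The running-sum enrichment score, permutation null, NES, and p-values."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgsea import (
    ChemicalGeneSet,
    ConfigurationError,
    DegenerateNullError,
    DegenerateSetError,
    DegenerateWeightError,
    EnrichmentConfig,
    InputError,
    RankedGeneList,
    bh_fdr,
    compute_es,
    empirical_p,
    normalize_es,
    permute_null,
    running_sum,
)
from conftest import brute_force_es, make_ranked


class TestComputeEs:
    def test_worked_example_top_heavy_set(self, toy_ranked):
        # NR = 3 + 1 = 4; walk: .75, .4167, .6667, .3333 -> max .75
        assert compute_es(toy_ranked, {"G1", "G3"}, w=1.0) == pytest.approx(0.75)

    def test_worked_example_bottom_set_is_negative(self, toy_ranked):
        assert compute_es(toy_ranked, {"G5"}, w=1.0) == pytest.approx(-0.25)

    def test_single_hit_at_top_attains_maximum(self, toy_ranked):
        assert compute_es(toy_ranked, {"G1"}, w=1.0) == pytest.approx(1.0)

    def test_members_outside_universe_ignored(self, toy_ranked):
        es_with = compute_es(toy_ranked, {"G1", "G3", "ABSENT"}, w=1.0)
        assert es_with == compute_es(toy_ranked, {"G1", "G3"}, w=1.0)

    def test_empty_intersection_raises(self, toy_ranked):
        with pytest.raises(DegenerateSetError):
            compute_es(toy_ranked, {"ABSENT"}, w=1.0)

    def test_full_universe_set_raises(self, toy_ranked):
        with pytest.raises(DegenerateSetError):
            compute_es(toy_ranked, {"G1", "G2", "G3", "G4", "G5"}, w=1.0)

    def test_zero_weight_mass_raises(self):
        ranked = RankedGeneList(["G1", "G2", "G3"], [1.0, 0.0, -1.0])
        with pytest.raises(DegenerateWeightError):
            compute_es(ranked, {"G2"}, w=1.0)

    def test_agrees_with_brute_force_enumeration_bitwise(self):
        rng = np.random.default_rng(11)
        for n in range(3, 9):
            ranked = make_ranked(rng, n)
            for n_c in range(1, min(3, n - 1) + 1):
                for pos in combinations(range(n), n_c):
                    members = {ranked.genes[i] for i in pos}
                    assert compute_es(ranked, members, 1.0) \
                        == brute_force_es(ranked.stats, pos, 1.0)

    def test_w0_reduces_to_unweighted_ks_statistic(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(10, 60))
            ranked = make_ranked(rng, n)
            pos = rng.choice(n, size=int(rng.integers(1, n // 2)), replace=False)
            members = {ranked.genes[i] for i in pos}
            n_c = len(pos)
            # direct unweighted KS-like running sum: hits climb by 1/N_C
            running, best = 0.0, -np.inf
            member_set = set(pos.tolist())
            for i in range(n - 1):
                running += 1.0 / n_c if i in member_set else -1.0 / (n - n_c)
                best = max(best, running)
            assert compute_es(ranked, members, w=0.0) == pytest.approx(best)

    def test_scale_invariance_at_w1(self):
        rng = np.random.default_rng(8)
        ranked = make_ranked(rng, 30)
        members = set(rng.choice(ranked.genes, 6, replace=False))
        scaled = RankedGeneList(ranked.genes, ranked.stats * 13.7)
        assert compute_es(scaled, members, 1.0) \
            == pytest.approx(compute_es(ranked, members, 1.0))

    def test_running_sum_conservation(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            n = int(rng.integers(5, 100))
            ranked = make_ranked(rng, n)
            size = int(rng.integers(1, n))
            members = set(rng.choice(ranked.genes, size, replace=False))
            rs = running_sum(ranked, members, w=1.0)
            assert abs(rs[-1]) <= 1e-9

    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 3.0))
    @settings(deadline=None, max_examples=40)
    def test_es_bounded_above_by_one(self, seed, w):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        ranked = make_ranked(rng, n)
        size = int(rng.integers(1, n))
        members = set(rng.choice(ranked.genes, size, replace=False))
        try:
            es = compute_es(ranked, members, w)
        except DegenerateWeightError:
            return
        assert -1.0 < es <= 1.0 + 1e-12


def _sets_of(ranked, positions_by_key):
    return {
        key: ChemicalGeneSet(key, key,
                             frozenset(ranked.genes[i] for i in pos))
        for key, pos in positions_by_key.items()
    }


class TestPermuteNull:
    def test_seeded_runs_are_bit_identical(self):
        rng = np.random.default_rng(1)
        ranked = make_ranked(rng, 50)
        sets = _sets_of(ranked, {"D1": [0, 3, 9], "D2": [5, 10, 20, 40]})
        cfg = EnrichmentConfig(permutations=25, seed=99)
        a = permute_null(ranked, sets, cfg)
        b = permute_null(ranked, sets, cfg)
        for key in sets:
            assert np.array_equal(a[key], b[key])

    def test_different_seeds_differ(self):
        rng = np.random.default_rng(1)
        ranked = make_ranked(rng, 50)
        sets = _sets_of(ranked, {"D1": [0, 3, 9]})
        a = permute_null(ranked, sets, EnrichmentConfig(permutations=25, seed=1))
        b = permute_null(ranked, sets, EnrichmentConfig(permutations=25, seed=2))
        assert not np.array_equal(a["D1"], b["D1"])

    def test_null_values_are_valid_scores(self):
        rng = np.random.default_rng(4)
        ranked = make_ranked(rng, 40)
        sets = _sets_of(ranked, {"D1": range(5)})
        cfg = EnrichmentConfig(permutations=200, seed=0)
        null = permute_null(ranked, sets, cfg)["D1"]
        assert null.shape == (200,)
        assert np.all(null > -1.0) and np.all(null <= 1.0)

    @pytest.mark.parametrize("per_set", [False, True])
    def test_monte_carlo_mean_matches_exhaustive_enumeration(self, per_set):
        # N=5, set size 2: ES depends only on member positions, so the
        # label-shuffle null averages ES over all C(5,2)=10 position pairs.
        rng = np.random.default_rng(17)
        ranked = make_ranked(rng, 5)
        exact = [brute_force_es(ranked.stats, pos, 1.0)
                 for pos in combinations(range(5), 2)]
        exact_mean, exact_sd = np.mean(exact), np.std(exact, ddof=1)
        sets = _sets_of(ranked, {"D1": [0, 1]})
        cfg = EnrichmentConfig(permutations=20000, seed=3, per_set_null=per_set)
        null = permute_null(ranked, sets, cfg)["D1"]
        se = exact_sd / np.sqrt(20000)
        assert abs(null.mean() - exact_mean) < 3 * se

    def test_equal_magnitude_stats_null_support_matches_enumeration(self):
        # with all |stats| equal and w=1 every shuffle realizes one of the
        # finitely many position geometries; the null support must be a
        # subset of the enumerated ES values
        ranked = RankedGeneList(list("ABCDE"), [1.0, 1.0, 1.0, -1.0, -1.0])
        exact = sorted({round(brute_force_es(ranked.stats, pos, 1.0), 12)
                        for pos in combinations(range(5), 2)})
        sets = _sets_of(ranked, {"D1": [0, 1]})
        null = permute_null(ranked, sets,
                            EnrichmentConfig(permutations=500, seed=0))["D1"]
        assert set(np.round(null, 12)) <= set(exact)

    def test_invalid_permutation_count_rejected(self):
        with pytest.raises(ConfigurationError):
            EnrichmentConfig(permutations=0)


class TestNormalizeEs:
    def test_centering_identity(self):
        null = [0.1, 0.2, 0.3]
        nes, _ = normalize_es(0.2, null)
        assert nes == pytest.approx(0.0)

    def test_worked_two_point_null(self):
        nes, nes_null = normalize_es(0.4, [0.1, 0.3])
        assert nes == pytest.approx(1.4142135, abs=1e-6)
        assert nes_null == pytest.approx([-0.7071068, 0.7071068], abs=1e-6)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        null = rng.normal(size=100)
        obs = 1.3
        nes, _ = normalize_es(obs, null)
        nes2, _ = normalize_es(2.5 * obs + 0.7, 2.5 * null + 0.7)
        assert nes2 == pytest.approx(nes)

    def test_null_standardized_to_unit_moments(self):
        rng = np.random.default_rng(9)
        null = rng.normal(0.3, 0.05, size=500)
        _, nes_null = normalize_es(0.5, null)
        assert abs(nes_null.mean()) < 1e-9
        assert abs(nes_null.std(ddof=1) - 1.0) < 1e-9

    def test_zero_spread_null_raises(self):
        with pytest.raises(DegenerateNullError):
            normalize_es(0.5, [0.2, 0.2, 0.2])


class TestEmpiricalP:
    def test_zero_exceedances_gives_add_one_floor(self):
        assert empirical_p(2.0, [0.5, 1.0, 1.5]) == pytest.approx(0.25)

    def test_observed_below_all_nulls_saturates_at_one(self):
        assert empirical_p(-5.0, [0.5, 1.0, 1.5]) == 1.0

    def test_ties_count_as_exceedances(self):
        assert empirical_p(1.0, [0.5, 1.0, 1.5]) == pytest.approx(3 / 4)

    def test_floor_at_5000_permutations(self):
        null = np.linspace(-3, 3, 5000)
        p = empirical_p(10.0, null)
        assert p == pytest.approx(1 / 5001)
        assert round(p, 4) == 0.0002


class TestBhFdr:
    def test_textbook_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_independent_step_up_oracle(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(1e-6, 1, size=37)
        m = p.size
        order = np.argsort(p)
        adj = np.empty(m)
        running_min = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running_min = min(running_min, p[i] * m / (rank_idx + 1))
            adj[i] = running_min
        assert bh_fdr(p) == pytest.approx(adj)

    def test_monotone_above_input_and_capped(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(1e-6, 1, size=50)
        q = bh_fdr(p)
        assert np.all(q >= p) and np.all(q <= 1.0)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.2], [np.nan]])
    def test_out_of_range_p_rejected(self, bad):
        with pytest.raises(InputError):
            bh_fdr(bad)
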