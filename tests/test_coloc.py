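"""Category-pair statistics, nearest spatial neighbours and CLIC detection,
each checked against independent brute-force oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

from clichunter import (
    ContactMap,
    SimulationConfig,
    category_pair_scores,
    clic_test,
    compare_category_pairs,
    detect_clics,
    enumerate_category_pairs,
    holm_adjust,
    nearest_spatial_neighbor_scores,
    plant_clic_contacts,
    rank_normalize,
    rank_sum_test,
    simulate_contact_map,
)
from clichunter.clusters import NI, I, RI, BinnedInsertionProfile, InsertionCluster


def exact_ranksum_oracle(x, y, alternative):
    """Enumerate every assignment of pooled ranks to the x-sample."""
    pooled = np.concatenate([x, y])
    n = len(x)
    u_obs = stats.rankdata(pooled)[:n].sum() - n * (n + 1) / 2
    total = 0
    count = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        ranks = stats.rankdata(pooled)[list(combo)]
        u = ranks.sum() - n * (n + 1) / 2
        total += 1
        if alternative == "greater":
            count += u >= u_obs
        elif alternative == "less":
            count += u <= u_obs
        else:
            mean_u = n * len(y) / 2
            count += abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12
    return count / total


def holm_oracle(pvals):
    """Textbook step-down: sort, multiply by (m - i), enforce monotonicity."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


class TestEnumeration:
    def test_six_categories_fifteen_comparisons(self):
        pairs, comparisons = enumerate_category_pairs()
        assert len(pairs) == 6
        assert len(comparisons) == 15
        assert len(set(pairs)) == 6
        assert all(a != b for a, b in comparisons)


class TestCategoryScores:
    def _profile(self, cats):
        counts = np.array([0 if c == NI else (1 if c == I else 6) for c in cats])
        return BinnedInsertionProfile("chr1", 40_000, counts, np.array(cats, dtype=object))

    def test_all_ni_pair_returns_every_off_diagonal(self, random_map):
        norm = rank_normalize(random_map)
        n = norm.n_bins
        prof = self._profile([NI] * n)
        scores = category_pair_scores(norm, prof, (NI, NI))
        assert scores.size == n * (n - 1) // 2

    def test_ri_ri_count_is_choose_two(self, random_map):
        norm = rank_normalize(random_map)
        cats = [NI] * norm.n_bins
        cats[3] = cats[10] = cats[20] = RI
        scores = category_pair_scores(norm, self._profile(cats), (RI, RI))
        assert scores.size == 3

    def test_matches_brute_force_double_loop(self, random_map, rng):
        norm = rank_normalize(random_map)
        n = norm.n_bins
        cats = rng.choice([NI, I, RI], size=n).tolist()
        prof = self._profile(cats)
        for pair in [(NI, I), (I, RI), (I, I)]:
            got = np.sort(category_pair_scores(norm, prof, pair))
            expected = []
            for i in range(n):
                for j in range(i + 1, n):
                    if {cats[i], cats[j]} == set(pair) and (
                        pair[0] != pair[1] or cats[i] == cats[j] == pair[0]
                    ):
                        expected.append(norm.ranks[i, j])
            np.testing.assert_allclose(got, np.sort(expected))

    def test_bin_subset_restricts_both_bins(self, random_map):
        norm = rank_normalize(random_map)
        prof = self._profile([I] * norm.n_bins)
        subset = np.arange(5)
        scores = category_pair_scores(norm, prof, (I, I), bin_subset=subset)
        assert scores.size == 10  # C(5, 2)

    def test_empty_result_signalled(self, random_map):
        norm = rank_normalize(random_map)
        prof = self._profile([NI] * norm.n_bins)
        with pytest.raises(ValueError, match="RI"):
            category_pair_scores(norm, prof, (RI, RI))


class TestRankSum:
    def test_identical_samples_give_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        test = compare_category_pairs(a, a.copy())
        assert test.p_value == pytest.approx(1.0)
        assert test.effect_size == 0.0

    def test_planted_shift_detected(self, rng):
        a = rng.normal(1.0, 1.0, size=100)
        b = rng.normal(0.0, 1.0, size=100)
        test = compare_category_pairs(a, b)
        assert test.p_value < 0.01
        assert test.effect_size > 0

    @pytest.mark.parametrize("n,m", [(3, 3), (3, 5), (5, 5), (2, 4)])
    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_exact_p_matches_full_enumeration(self, n, m, alternative):
        rng = np.random.default_rng(n * 100 + m)
        x = rng.normal(size=n)
        y = rng.normal(size=m)
        _, p, exact = rank_sum_test(x, y, alternative)
        assert exact
        assert p == pytest.approx(exact_ranksum_oracle(x, y, alternative), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test(np.array([]), np.array([1.0]))


class TestHolm:
    def test_matches_brute_force_step_down(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            m = int(rng.integers(1, 40))
            p = rng.uniform(0, 1, size=m)
            np.testing.assert_allclose(holm_adjust(p), holm_oracle(p), atol=1e-12)


class TestNearestNeighbor:
    def test_planted_pair_is_mutual_nearest(self):
        # noiseless decay map: unboosted scores tie within each distance pool
        # while the boosted A x B entries top their pools, so the planted
        # partner is the unambiguous nearest spatial neighbour of each locus
        cfg = SimulationConfig(
            n_bins=150, compartment_contrast=1.0, noise_dispersion=0.0, seed=2
        )
        cmap = plant_clic_contacts(
            simulate_contact_map(cfg), [((40, 43), (110, 113), 50.0)]
        )
        norm = rank_normalize(cmap)
        counts = np.zeros(150, dtype=int)
        counts[40:43] = 6
        counts[110:113] = 6
        prof = BinnedInsertionProfile("chr1", 40_000, counts)
        hits = {r["bin"]: r for r in nearest_spatial_neighbor_scores(norm, prof)}
        assert 110 <= hits[41]["neighbor_bin"] < 113
        assert 40 <= hits[111]["neighbor_bin"] < 43
        assert hits[41]["neighbor_count"] == 6

    def test_null_map_neighbor_counts_match_marginal(self, rng):
        raw = rng.uniform(0.5, 1.5, size=(200, 200))
        norm = rank_normalize(ContactMap("chr1", 40_000, (raw + raw.T) / 2))
        counts = rng.poisson(2, size=200)
        recs = nearest_spatial_neighbor_scores(norm, prof := BinnedInsertionProfile("chr1", 40_000, counts))
        neigh = [r["neighbor_count"] for r in recs]
        assert abs(np.mean(neigh) - counts.mean()) < 0.5


def _ic(start, end, chrom="chr1"):
    return InsertionCluster(chrom, start * 40_000.0, 1.0, start, end)


class TestClicTest:
    def test_minimum_size_ics_give_nine_positive_points(self, decay_map):
        norm = rank_normalize(decay_map)
        res = clic_test(norm, _ic(5, 8), _ic(20, 23), L=50)
        assert res.n_pos == 9
        assert res.d_min == 20 - 7
        assert res.d_max == 22 - 5

    def test_p_matches_independent_null_assembly(self, decay_map):
        # independent double loop over all bin pairs in the distance range,
        # excluding the positive entries, then the same rank-sum call
        norm = rank_normalize(decay_map)
        ia, ib = _ic(5, 8), _ic(20, 23)
        res = clic_test(norm, ia, ib, L=50)
        n = norm.n_bins
        pos, neg = [], []
        for i in range(n):
            for j in range(i + 1, n):
                d = j - i
                if not res.d_min <= d <= res.d_max:
                    continue
                in_pos = (5 <= i < 8 and 20 <= j < 23) or (20 <= i < 23 and 5 <= j < 8)
                (pos if in_pos else neg).append(norm.ranks[i, j])
        assert len(pos) == 9
        _, p_expected, _ = rank_sum_test(
            np.array(pos), np.array(neg), alternative="greater"
        )
        assert res.p_raw == pytest.approx(p_expected, abs=1e-12)

    def test_positive_entries_excluded_from_negative(self, decay_map):
        # boost the whole A x B block, then rebuild the null both ways: the
        # reported p must match the positives-excluded assembly and differ
        # from the positives-included one
        scores = decay_map.scores.copy()
        scores[5:8, 20:23] *= 50.0
        scores[20:23, 5:8] *= 50.0
        norm = rank_normalize(ContactMap("chr1", 40_000, scores))
        res = clic_test(norm, _ic(5, 8), _ic(20, 23), L=50)
        n = norm.n_bins
        pos, neg_excl, neg_incl = [], [], []
        for d in range(res.d_min, res.d_max + 1):
            for i in range(n - d):
                j = i + d
                v = norm.ranks[i, j]
                in_pos = 5 <= i < 8 and 20 <= j < 23
                neg_incl.append(v)
                (pos if in_pos else neg_excl).append(v)
        _, p_excl, _ = rank_sum_test(np.array(pos), np.array(neg_excl), "greater")
        _, p_incl, _ = rank_sum_test(np.array(pos), np.array(neg_incl), "greater")
        assert res.p_raw == pytest.approx(p_excl, abs=1e-12)
        assert res.p_raw != pytest.approx(p_incl, rel=1e-3)

    def test_overlapping_ics_rejected(self, decay_map):
        norm = rank_normalize(decay_map)
        with pytest.raises(ValueError, match="disjoint"):
            clic_test(norm, _ic(5, 10), _ic(8, 12), L=20)

    def test_symmetric_in_ic_order(self, decay_map):
        norm = rank_normalize(decay_map)
        a = clic_test(norm, _ic(5, 8), _ic(20, 23), L=50)
        b = clic_test(norm, _ic(20, 23), _ic(5, 8), L=50)
        assert a.p_raw == b.p_raw
        assert (a.d_min, a.d_max, a.n_pos) == (b.d_min, b.d_max, b.n_pos)

    def test_impossible_null_size_rejected(self, decay_map):
        norm = rank_normalize(decay_map)
        with pytest.raises(ValueError, match="too short"):
            clic_test(norm, _ic(5, 8), _ic(20, 23), L=10**6)

    def test_null_p_values_roughly_uniform(self):
        ps = []
        for seed in range(100):
            cfg = SimulationConfig(n_bins=120, compartment_contrast=1.0, seed=seed)
            norm = rank_normalize(simulate_contact_map(cfg))
            rng = np.random.default_rng(seed)
            a0 = int(rng.integers(0, 50))
            b0 = int(rng.integers(a0 + 8, 115))
            ps.append(clic_test(norm, _ic(a0, a0 + 3), _ic(b0, b0 + 3), L=240).p_raw)
        frac = np.mean(np.array(ps) < 0.05)
        assert 0.0 <= frac <= 0.12
        assert stats.kstest(ps, "uniform").pvalue > 0.001

    def test_power_monotone_in_boost(self):
        cfg = SimulationConfig(n_bins=300, compartment_contrast=1.0, seed=17)
        base = simulate_contact_map(cfg)
        ps = []
        for boost in (1.5, 3.0, 5.0):
            cmap = plant_clic_contacts(base, [((50, 53), (200, 203), boost)])
            norm = rank_normalize(cmap)
            ps.append(clic_test(norm, _ic(50, 53), _ic(200, 203), L=600).p_raw)
        assert ps[0] >= ps[1] >= ps[2]


class TestDetectClics:
    def test_pair_count_combinatorics(self, decay_map):
        norm = {"chr1": rank_normalize(decay_map)}
        ics = [_ic(s, s + 3) for s in (2, 10, 20, 30, 40)]
        out = detect_clics(norm, ics, alpha=0.05, L=50)
        assert len(out) == 10  # C(5, 2)

    def test_symmetric_records(self, decay_map):
        norm = {"chr1": rank_normalize(decay_map)}
        ics = [_ic(2, 5), _ic(20, 23)]
        out_ab = detect_clics(norm, ics, alpha=0.05, L=50)
        out_ba = detect_clics(norm, ics[::-1], alpha=0.05, L=50)
        assert out_ab[0].p_raw == out_ba[0].p_raw
        assert out_ab[0].p_holm == out_ba[0].p_holm

    def test_planted_pair_flagged_off_target_not(self):
        cfg = SimulationConfig(n_bins=300, compartment_contrast=1.0, seed=8)
        cmap = plant_clic_contacts(
            simulate_contact_map(cfg), [((50, 53), (200, 203), 5.0)]
        )
        norm = {"chr1": rank_normalize(cmap)}
        ics = [_ic(50, 53), _ic(200, 203), _ic(120, 123), _ic(260, 263)]
        out = detect_clics(norm, ics, alpha=0.05)
        flagged = {
            (c.ic_a.start_bin, c.ic_b.start_bin) for c in out if c.significant
        }
        assert flagged == {(50, 200)}
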