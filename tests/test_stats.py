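import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirrorloop.montage import standard_montage
from mirrorloop.stats import (Adjacency, TFCEParams, channel_adjacency,
                              cohens_d_cluster, f_stat_timecourse,
                              permutation_test_1d,
                              spatiotemporal_cluster_test, tfce_enhance)


def brute_force_tfce(stat, params):
    """Independent oracle: per-position threshold integral with explicit
    neighborhood expansion."""
    stat = np.asarray(stat, dtype=float)
    out = np.zeros_like(stat)
    n_steps = int(np.floor(stat.max() / params.dh + 1e-9))
    hs = params.dh * np.arange(1, n_steps + 1)
    for i in range(len(stat)):
        for h in hs:
            if stat[i] < h:
                continue
            lo = i
            while lo > 0 and stat[lo - 1] >= h:
                lo -= 1
            hi = i
            while hi < len(stat) - 1 and stat[hi + 1] >= h:
                hi += 1
            out[i] += (hi - lo + 1) ** params.E * h ** params.H * params.dh
    return out


class TestFStat:
    def test_identical_conditions_give_zero(self, rng):
        a = rng.standard_normal((8, 20))
        np.testing.assert_array_equal(f_stat_timecourse(a, a), 0.0)

    def test_hand_computed_toy(self):
        # 5 subjects, one time point: t = mean / (sd/sqrt(n))
        d = np.array([1.0, 2.0, 3.0, 4.0, 5.0])[:, None]
        t = 3.0 / (np.std(d, ddof=1) / np.sqrt(5))
        F = f_stat_timecourse(d)
        assert F[0] == pytest.approx(t ** 2, abs=1e-12)

    def test_zero_variance_handling(self):
        d = np.tile([[2.0, 0.0]], (4, 1))  # constant 2 and constant 0
        with pytest.warns(RuntimeWarning, match="capped"):
            F = f_stat_timecourse(d)
        assert F[0] > 1e10  # flagged degenerate
        assert F[1] == 0.0

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError, match="at least 3"):
            f_stat_timecourse(np.zeros((2, 5)))


class TestTFCE:
    def test_zero_map_unchanged(self):
        np.testing.assert_array_equal(tfce_enhance(np.zeros(50)), 0.0)

    def test_rectangular_bump_matches_oracle(self):
        stat = np.zeros(20)
        stat[7:12] = 3.0
        params = TFCEParams()
        got = tfce_enhance(stat, params)
        want = brute_force_tfce(stat, params)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_random_maps_match_oracle(self, rng):
        params = TFCEParams()
        for _ in range(25):
            stat = np.abs(rng.standard_normal(30)) * 3
            np.testing.assert_allclose(tfce_enhance(stat, params),
                                       brute_force_tfce(stat, params),
                                       atol=1e-9)

    def test_monotone_in_the_stat_map(self, rng):
        params = TFCEParams()
        for _ in range(10):
            stat = np.abs(rng.standard_normal(25)) * 2
            base = tfce_enhance(stat, params)
            bumped = stat.copy()
            bumped[rng.integers(25)] += 1.0
            assert np.all(tfce_enhance(bumped, params) >= base - 1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=10.0),
                    min_size=2, max_size=30))
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_matches_oracle_on_arbitrary_maps(self, values):
        stat = np.asarray(values)
        params = TFCEParams()
        np.testing.assert_allclose(tfce_enhance(stat, params),
                                   brute_force_tfce(stat, params), atol=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="finite and non-negative"):
            tfce_enhance(np.array([1.0, -0.5]))
        with pytest.raises(ValueError, match="dh > 0"):
            tfce_enhance(np.ones(5), TFCEParams(dh=0.0))


class TestPermutation1D:
    def test_exhaustive_matches_hand_enumeration(self):
        """n=5 design: compare against explicit enumeration of all 32
        sign-flip assignments using the brute-force TFCE oracle."""
        rng = np.random.default_rng(0)
        d = rng.standard_normal((5, 12)) + 0.8
        params = TFCEParams()
        res = permutation_test_1d(d, None, params, n_perm=100, seed=0,
                                  exhaustive=True)
        obs_max = tfce_enhance(f_stat_timecourse(d), params).max()
        count = 0
        for signs in itertools.product([-1.0, 1.0], repeat=5):
            flipped = np.asarray(signs)[:, None] * d
            m = brute_force_tfce(f_stat_timecourse(flipped), params).max()
            if m >= obs_max - 1e-12:
                count += 1
        expected_p = count / 32
        assert res.extra["exhaustive"]
        if res.clusters:
            global_p = res.p_values.min()
            assert global_p == pytest.approx(expected_p, abs=1e-12)

    def test_planted_effect_detected_over_window(self):
        params = TFCEParams()
        hits = 0
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            d = rng.standard_normal((20, 60))
            d[:, 20:40] += 2.0  # d = 2 planted effect
            res = permutation_test_1d(d, None, params, n_perm=500, seed=seed)
            covered = any(sl.start < 40 and sl.stop > 20
                          for sl, p in zip(res.clusters, res.p_values)
                          if p < 0.05)
            hits += covered
        assert hits == 3

    def test_seeded_bit_reproducibility(self, rng):
        d = rng.standard_normal((15, 40))
        a = permutation_test_1d(d, None, n_perm=300, seed=9)
        b = permutation_test_1d(d, None, n_perm=300, seed=9)
        np.testing.assert_array_equal(a.null_max, b.null_max)
        np.testing.assert_array_equal(a.p_values, b.p_values)

    def test_paired_contrast_equals_difference_form(self, rng):
        a = rng.standard_normal((10, 30))
        b = rng.standard_normal((10, 30))
        r1 = permutation_test_1d(a, b, n_perm=200, seed=4)
        r2 = permutation_test_1d(a - b, None, n_perm=200, seed=4)
        np.testing.assert_array_equal(r1.stat_map, r2.stat_map)
        np.testing.assert_array_equal(r1.null_max, r2.null_max)

    def test_exhaustive_and_sampled_p_agree(self):
        """On an n=10 design the sampled null (4000 draws) reproduces the
        exhaustive (1024 flips) p-value within binomial error."""
        rng = np.random.default_rng(6)
        d = rng.standard_normal((10, 20)) + 0.9
        ex = permutation_test_1d(d, None, n_perm=2000, seed=0,
                                 exhaustive=True, alpha=0.2)
        sa = permutation_test_1d(d, None, n_perm=4000, seed=1,
                                 exhaustive=False, alpha=0.2)
        assert ex.clusters and sa.clusters
        p_ex, p_sa = ex.p_values.min(), sa.p_values.min()
        se = np.sqrt(p_ex * (1 - p_ex) / 4000) + 1 / 4000
        assert abs(p_ex - p_sa) <= 4 * se + 5e-4

    def test_minimum_permutations_enforced(self, rng):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test_1d(rng.standard_normal((5, 10)), n_perm=10)


class TestAdjacency:
    def test_single_channel_has_no_neighbors(self):
        m = standard_montage(["Cz"])
        adj = channel_adjacency(m)
        assert adj.neighbors == [[]]

    def test_c3_neighbors_include_c1_and_fc3(self, montage):
        adj = channel_adjacency(montage)
        names = montage.channel_names
        nb = {names[j] for j in adj.neighbors[montage.index("C3")]}
        assert {"C1", "FC3"} <= nb

    def test_median_neighbor_count_in_range(self, montage):
        adj = channel_adjacency(montage)
        counts = [len(nb) for nb in adj.neighbors]
        assert 4 <= np.median(counts) <= 8

    def test_symmetry_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            Adjacency([[1], []], 0.5)
        with pytest.raises(ValueError, match="self-neighbors"):
            Adjacency([[0]], 0.5)


class TestSpatioTemporal:
    def test_planted_errp_like_cluster_found(self, montage):
        """A difference planted at {FCz, Cz, FC1, FC2} x 470-520 ms is
        recovered with the right channels and overlapping time range."""
        rng = np.random.default_rng(2)
        n, n_t = 20, 250  # 500 ms window grid at 500 Hz
        times = 0.3 + np.arange(n_t) / 500.0
        d = rng.standard_normal((n, 48, n_t))
        picks = [montage.index(c) for c in ("FCz", "Cz", "FC1", "FC2")]
        tsel = (times >= 0.47) & (times <= 0.52)
        d[np.ix_(range(n), picks, np.flatnonzero(tsel))] += 2.0
        adj = channel_adjacency(montage)
        res = spatiotemporal_cluster_test(d, None, threshold=20.0,
                                          adjacency=adj, n_perm=300, seed=0)
        sig = [c for c, p in zip(res.clusters, res.p_values) if p < 0.05]
        assert sig
        ch_idx, t_idx = res.clusters[int(np.argmax(res.cluster_stats))]
        found_names = {montage.channel_names[c] for c in ch_idx}
        assert {"FCz", "Cz"} <= found_names
        t_lo, t_hi = times[t_idx.min()], times[t_idx.max()]
        assert t_lo < 0.52 and t_hi > 0.47

    def test_null_data_rarely_significant(self, montage):
        adj = channel_adjacency(montage)
        n_sig = 0
        for seed in range(5):
            rng = np.random.default_rng(300 + seed)
            d = rng.standard_normal((12, 48, 60))
            res = spatiotemporal_cluster_test(d, None, threshold=20.0,
                                              adjacency=adj, n_perm=200,
                                              seed=seed)
            n_sig += res.any_significant
        assert n_sig <= 1

    def test_cluster_membership_invariant_to_channel_order(self, montage):
        rng = np.random.default_rng(5)
        n, n_t = 10, 40
        d = rng.standard_normal((n, 48, n_t))
        d[:, [10, 11], 20:25] += 3.0
        adj = channel_adjacency(montage)
        res = spatiotemporal_cluster_test(d, None, threshold=15.0,
                                          adjacency=adj, n_perm=100, seed=0)
        perm = np.random.default_rng(0).permutation(48)
        inv = np.argsort(perm)
        adj_p = Adjacency([sorted(inv[j] for j in adj.neighbors[perm[i]])
                           for i in range(48)], adj.max_dist)
        res_p = spatiotemporal_cluster_test(d[:, perm], None, threshold=15.0,
                                            adjacency=adj_p, n_perm=100,
                                            seed=0)
        def canon(clusters, chmap=None):
            out = []
            for ch, t in clusters:
                ch = ch if chmap is None else chmap[ch]
                out.append(frozenset(zip(ch.tolist(), t.tolist())))
            return set(out)
        assert canon(res.clusters) == canon(res_p.clusters, chmap=perm)


class TestCohensD:
    def test_hand_arithmetic(self):
        a = np.array([2.0, 0.0, 2.0, 0.0])[:, None, None]
        b = np.zeros((4, 1, 1))
        d = cohens_d_cluster(a, b, (np.array([0]), np.array([0])))
        assert d == pytest.approx(1.0 / np.std([2, 0, 2, 0], ddof=1), abs=1e-9)
        assert d == pytest.approx(0.866, abs=1e-3)

    def test_zero_spread_flagged_infinite(self):
        a = np.ones((4, 1, 1))
        b = np.zeros((4, 1, 1))
        with pytest.warns(RuntimeWarning, match="infinite"):
            d = cohens_d_cluster(a, b, (np.array([0]), np.array([0])))
        assert np.isinf(d)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cohens_d_cluster(np.zeros((4, 1, 1)), np.zeros((4, 1, 1)),
                             (np.array([], dtype=int), np.array([], dtype=int)))
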