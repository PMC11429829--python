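"""Null TRFs, adjacency, cluster permutation test, effect sizes, d-prime."""

import numpy as np
import pytest
from scipy import stats as sps

from tactrf import montage, trf
from tactrf.envelope import TactileEnvelope
from tactrf.preprocessing import EEGSegment, zscore_segment
from tactrf.stats import (
    DEFAULT_ADJACENCY_THRESHOLD_M,
    MIN_DATA_ALPHA,
    AdjacencyGraph,
    _find_clusters,
    _spatiotemporal_graph,
    build_adjacency,
    cluster_permutation_test,
    cluster_table,
    cohens_d_unbiased,
    dprime,
    make_null_trf,
    minimum_data_analysis,
    normalize_topographies,
    paired_t_map,
)
from tactrf.synth import (
    SimulationConfig,
    default_condition_kernel,
    generate_stroke_train,
    render_envelope,
    simulate_eeg_trial,
)


def simulated_segments(n_seg, snr_db, seed, seconds=60.0, condition="right_thumb"):
    kernel = default_condition_kernel(condition)
    focal = None if condition == "control" else montage.focal_set(condition)
    out = []
    for i in range(n_seg):
        env = render_envelope(generate_stroke_train(trial_length=seconds, seed=seed + i))
        eeg = simulate_eeg_trial(env, kernel, snr_db=snr_db, seed=seed + 100 + i,
                                 focal_channels=focal)
        out.append((env, zscore_segment(EEGSegment(eeg))))
    return out


class TestNullTRF:
    def test_identical_envelopes_null_equals_tactile(self):
        """Mismatching identical stimuli changes nothing: null == tactile."""
        rng = np.random.default_rng(0)
        env = TactileEnvelope(values=rng.uniform(0, 1, 640), fs=64.0)
        segs = [(env, EEGSegment(rng.normal(size=(4, 640)))) for _ in range(4)]
        lags = trf.LagWindow()
        tactile = trf.fit_subject_trf(segs, lam=1.0, lags=lags)
        null = make_null_trf(segs, lam=1.0, lags=lags, n_permutations=5, seed=1)
        np.testing.assert_allclose(null.weights, tactile.weights, atol=1e-9)

    def test_deterministic_given_seed(self):
        segs = simulated_segments(3, snr_db=0.0, seed=5, seconds=20.0)
        a = make_null_trf(segs, n_permutations=1, seed=9)
        b = make_null_trf(segs, n_permutations=1, seed=9)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_single_segment_rejected(self):
        segs = simulated_segments(1, snr_db=0.0, seed=5, seconds=20.0)
        with pytest.raises(ValueError, match="at least 2"):
            make_null_trf(segs)

    def test_two_segments_forced_swap(self):
        """n=2 has exactly one derangement (the swap), used for the 2-minute
        point of the minimum-data analysis."""
        segs = simulated_segments(2, snr_db=0.0, seed=6, seconds=20.0)
        lags = trf.LagWindow()
        a = make_null_trf(segs, lags=lags, n_permutations=3, seed=0)
        cache = trf.LaggedStats([e for e, _ in segs], [g.data for _, g in segs], lags)
        w_swap, _ = cache.loo_average([(1, 0), (0, 1)], 1e2)
        np.testing.assert_allclose(a.weights, w_swap, atol=1e-12)

    def test_null_amplitude_below_tactile_in_simulation(self, focal_left):
        """Across simulated subjects at study SNR, the tactile TRF's focal
        amplitude exceeds the mismatched-pairing null's on average."""
        lags = trf.LagWindow()
        t_max, n_max = [], []
        for s in range(6):
            segs = simulated_segments(5, snr_db=-10.0, seed=1000 + 7 * s)
            cache = trf.LaggedStats([e for e, _ in segs], [g.data for _, g in segs], lags)
            w, _ = cache.loo_average([(i, i) for i in range(5)], 1e2)
            null = make_null_trf(cache, lam=1e2, lags=lags, n_permutations=30, seed=s)
            t_max.append(np.abs(w[focal_left]).max())
            n_max.append(np.abs(null.weights[focal_left]).max())
        assert np.mean(t_max) > np.mean(n_max)

    def test_null_sd_shrinks_as_inverse_sqrt_permutations(self, focal_left):
        """SD of the null TRF across replicates scales ~1/sqrt(n_perm)."""
        segs = simulated_segments(4, snr_db=-10.0, seed=77, seconds=20.0)
        lags = trf.LagWindow()
        cache = trf.LaggedStats([e for e, _ in segs], [g.data for _, g in segs], lags)
        cell = (focal_left[0], 30)

        def replicate_sd(n_perm, n_rep=14):
            vals = [
                make_null_trf(cache, lags=lags, n_permutations=n_perm,
                              seed=1000 * n_perm + r).weights[cell]
                for r in range(n_rep)
            ]
            return np.std(vals, ddof=1)

        sd10, sd160 = replicate_sd(10), replicate_sd(160)
        ratio = sd10 / sd160
        assert 2.0 < ratio < 8.0  # ideal 4, wide band for 14 replicates


class TestAdjacency:
    def test_zero_threshold_empty_graph(self):
        adj = build_adjacency(distance_threshold=0.0)
        assert adj.matrix.sum() == 0

    def test_infinite_threshold_complete_graph(self):
        adj = build_adjacency(distance_threshold=np.inf)
        assert adj.matrix.sum() == 64 * 63

    def test_default_symmetric_irreflexive_connected(self):
        adj = build_adjacency()
        np.testing.assert_array_equal(adj.matrix, adj.matrix.T)
        assert not np.any(np.diag(adj.matrix))
        assert np.all(adj.matrix.sum(axis=1) >= 1)

    def test_focal_cluster_is_spatially_compact(self):
        """E22's neighborhood includes most of the contralateral focal set."""
        adj = build_adjacency()
        neighbors = set(adj.neighbors("E22"))
        assert len(neighbors & {"E25", "E26", "E27", "E28"}) >= 2


class TestPairedTMap:
    def test_equal_inputs_zero_t(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(5, 3, 4))
        tmap = paired_t_map(a, a.copy())
        np.testing.assert_array_equal(tmap.t, 0.0)
        assert tmap.df == 4

    def test_zero_variance_sentinel(self):
        a = np.zeros((4, 1, 1))
        b = np.full((4, 1, 1), -1.0)  # differences all +1
        tmap = paired_t_map(a, b)
        assert tmap.t[0, 0] >= 1e6

    def test_matches_textbook_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(12, 4, 6))
        b = rng.normal(size=(12, 4, 6))
        tmap = paired_t_map(a, b)
        oracle = sps.ttest_rel(a, b, axis=0)
        np.testing.assert_allclose(tmap.t, oracle.statistic, atol=1e-12)


def bfs_cluster_oracle(tmap, channel_adj, threshold):
    """Brute-force clustering: BFS over supra-threshold (ch, lag) cells with
    scalp neighbors at the same lag and +-1-lag cells on the same channel."""
    n_ch, n_lags = tmap.shape
    clusters = []
    for sign in (1, -1):
        mask = tmap * sign > threshold
        seen = np.zeros_like(mask)
        for ch in range(n_ch):
            for lag in range(n_lags):
                if not mask[ch, lag] or seen[ch, lag]:
                    continue
                stack, members = [(ch, lag)], []
                seen[ch, lag] = True
                while stack:
                    c, l = stack.pop()
                    members.append((c, l))
                    for c2 in np.flatnonzero(channel_adj[c]):
                        if mask[c2, l] and not seen[c2, l]:
                            seen[c2, l] = True
                            stack.append((c2, l))
                    for l2 in (l - 1, l + 1):
                        if 0 <= l2 < n_lags and mask[c, l2] and not seen[c, l2]:
                            seen[c, l2] = True
                            stack.append((c, l2))
                clusters.append((frozenset(members), sign,
                                 sum(tmap[c, l] for c, l in members)))
    return clusters


class TestClusterPermutationTest:
    def test_equal_conditions_no_clusters(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(8, 64, 10))
        result = cluster_permutation_test(a, a.copy(), build_adjacency(),
                                          n_permutations=20, seed=0)
        assert result.clusters == []

    def test_clustering_matches_bfs_oracle(self):
        """Sparse-graph component labelling agrees with a brute-force BFS
        oracle on random t-maps: same member sets and sum-t."""
        rng = np.random.default_rng(5)
        adj = build_adjacency()
        graph = _spatiotemporal_graph(adj.matrix, 12)
        for _ in range(10):
            tmap = rng.normal(scale=2.0, size=(64, 12))
            ours = _find_clusters(tmap, graph, 2.0)
            ours_sets = {
                (frozenset((m // 12, m % 12) for m in members), sign, round(s, 9))
                for members, sign, s in ours
            }
            oracle = {
                (members, sign, round(s, 9))
                for members, sign, s in bfs_cluster_oracle(tmap, adj.matrix, 2.0)
            }
            assert ours_sets == oracle

    def test_planted_block_effect_detected(self):
        """A strong effect on a known 5-channel x 8-lag block yields exactly
        one significant positive cluster covering >=80% of the block."""
        rng = np.random.default_rng(11)
        n, n_lags = 27, 26
        focal = montage.channel_index(list(montage.LEFT_CENTRAL))
        a = rng.normal(size=(n, 64, n_lags))
        b = rng.normal(size=(n, 64, n_lags))
        block_lags = np.arange(6, 14)
        a[:, np.ix_(focal, block_lags)[0], np.ix_(focal, block_lags)[1]] += 2.0
        result = cluster_permutation_test(a, b, build_adjacency(),
                                          n_permutations=200, seed=2)
        significant = result.significant
        positive = [c for c in significant if c.sign > 0]
        assert len(positive) == 1
        block = {(ch, lag) for ch in focal for lag in block_lags}
        covered = block & set(positive[0].members)
        assert len(covered) >= 0.8 * len(block)
        assert not [c for c in significant if c.sign < 0]

    def test_p_floor_includes_observed(self):
        """Monte-Carlo p-values count the observed statistic: the smallest
        attainable p is 1/(n_perm+1), never 0."""
        rng = np.random.default_rng(4)
        n = 12
        a = rng.normal(size=(n, 64, 8)) + 3.0   # huge uniform effect
        b = rng.normal(size=(n, 64, 8))
        result = cluster_permutation_test(a, b, build_adjacency(),
                                          n_permutations=50, seed=1)
        assert result.clusters
        assert min(c.p_value for c in result.clusters) == pytest.approx(1 / 51)

    def test_lag_window_restriction(self):
        lags = trf.LagWindow()
        rng = np.random.default_rng(6)
        a = rng.normal(size=(6, 64, lags.n_lags))
        result = cluster_permutation_test(
            a, rng.normal(size=a.shape), build_adjacency(),
            lag_axis_ms=lags.lag_axis_ms, lag_window_ms=(0.0, 400.0),
            n_permutations=10, seed=0,
        )
        assert result.lag_axis_ms[0] >= 0.0
        assert result.lag_axis_ms[-1] <= 400.0
        assert result.lag_axis_ms.size == 26

    def test_empty_window_rejected(self):
        a = np.zeros((4, 64, 10))
        with pytest.raises(ValueError, match="empty lag window"):
            cluster_permutation_test(a, a, build_adjacency(),
                                     lag_axis_ms=np.arange(10.0),
                                     lag_window_ms=(100.0, 200.0))

    def test_cluster_table_roundtrip(self, tmp_path):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(10, 64, 8)) + 1.5
        b = rng.normal(size=(10, 64, 8))
        result = cluster_permutation_test(a, b, build_adjacency(),
                                          n_permutations=30, seed=3)
        table = cluster_table(result)
        from tactrf.io import read_tsv, write_tsv
        path = tmp_path / "clusters.tsv"
        write_tsv(path, table)
        back = read_tsv(path)
        assert list(back.columns) == list(table.columns)
        np.testing.assert_allclose(back["sum_t"], table["sum_t"])


class TestNormalizeTopographies:
    def test_uniform_topography_rejected(self):
        trfs = np.ones((3, 4, 5))
        with pytest.raises(ValueError, match="zero across-channel"):
            normalize_topographies(trfs)

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        trfs = rng.normal(size=(5, 8, 6))
        scaled = trfs.copy()
        scaled[2] *= 10.0
        np.testing.assert_allclose(
            normalize_topographies(trfs)[2], normalize_topographies(scaled)[2],
            atol=1e-12,
        )

    def test_moments_per_subject_and_lag(self):
        rng = np.random.default_rng(9)
        out = normalize_topographies(rng.normal(size=(4, 16, 7)))
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1), 1.0, atol=1e-12)

    def test_additive_per_lag_offset_removed(self):
        rng = np.random.default_rng(10)
        trfs = rng.normal(size=(3, 8, 5))
        shifted = trfs + rng.normal(size=(3, 1, 5))
        np.testing.assert_allclose(
            normalize_topographies(trfs), normalize_topographies(shifted), atol=1e-12,
        )


class TestCohensD:
    def test_constant_nonzero_difference_rejected(self):
        a = np.arange(5.0)
        with pytest.raises(ValueError, match="zero-variance"):
            cohens_d_unbiased(a + 2.0, a)

    def test_identical_inputs_zero_effect(self):
        a = np.arange(5.0)
        effect = cohens_d_unbiased(a, a.copy())
        assert effect.d == 0.0
        assert effect.ci_low <= 0.0 <= effect.ci_high

    def test_bias_correction_recovers_unit_effect(self):
        """10^4 replicates of n=27 N(1,1) differences: the corrected
        estimator's mean lands within 2 SE of the true d = 1 (the naive
        estimator would sit ~3% high)."""
        rng = np.random.default_rng(12)
        n, reps = 27, 10_000
        diffs = rng.normal(1.0, 1.0, size=(reps, n))
        estimates = np.array([
            cohens_d_unbiased(d, np.zeros(n), n_boot=0).d for d in diffs
        ])
        se = estimates.std(ddof=1) / np.sqrt(reps)
        assert abs(estimates.mean() - 1.0) < 2 * se
        naive = estimates.mean() / (1 - 3 / (4 * (n - 1) - 1))
        assert naive - 1.0 > 2 * se  # the correction is doing real work

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(13)
        effect = cohens_d_unbiased(rng.normal(1, 1, 27), rng.normal(0, 1, 27),
                                   n_boot=1000, seed=5)
        assert effect.ci_low <= effect.d <= effect.ci_high


class TestDPrime:
    def test_equal_rates_zero_to_machine_precision(self):
        result = dprime(hits=10, misses=10, fas=10, crs=10)
        assert result.dprime == 0.0

    def test_quantile_oracle(self):
        """17/20 hits, 3/20 false alarms: d' = z(0.85) - z(0.15)."""
        result = dprime(hits=17, misses=3, fas=3, crs=17, adjust_extremes=False)
        expected = sps.norm.ppf(0.85) - sps.norm.ppf(0.15)
        assert result.dprime == pytest.approx(expected, abs=1e-12)

    def test_extreme_rate_adjustment(self):
        result = dprime(hits=20, misses=0, fas=5, crs=15)
        assert result.hit_rate == pytest.approx(1 - 1 / 40)

    def test_antisymmetry(self):
        a = dprime(hits=15, misses=5, fas=4, crs=16)
        b = dprime(hits=4, misses=16, fas=15, crs=5)
        assert a.dprime == pytest.approx(-b.dprime, abs=1e-12)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            dprime(hits=0, misses=0, fas=1, crs=1)


class TestMinimumData:
    def _subject_stats(self, n_subjects, condition, seed0):
        lags = trf.LagWindow()
        out = []
        for s in range(n_subjects):
            segs = simulated_segments(9, snr_db=-10.0, seed=seed0 + 31 * s,
                                      seconds=60.0, condition=condition)
            out.append(trf.LaggedStats([e for e, _ in segs],
                                       [g.data for _, g in segs], lags))
        return out

    def test_no_effect_gives_no_detection(self):
        """Control-condition data (zero kernel): none of the eight tests
        reaches the Bonferroni threshold."""
        stats_list = self._subject_stats(6, "control", 400)
        table = minimum_data_analysis(
            stats_list, electrode_set=montage.LEFT_CENTRAL,
            null_permutations=20, seed=1,
        )
        assert len(table) == 8
        assert not table["significant"].any()

    def test_bonferroni_preset(self):
        assert MIN_DATA_ALPHA == pytest.approx(0.05 / 8)
        assert MIN_DATA_ALPHA == pytest.approx(0.00625)

    def test_insufficient_segments_rejected(self):
        lags = trf.LagWindow()
        segs = simulated_segments(4, snr_db=0.0, seed=4, seconds=20.0)
        cache = trf.LaggedStats([e for e, _ in segs], [g.data for _, g in segs], lags)
        with pytest.raises(ValueError, match="at least 9"):
            minimum_data_analysis([cache], electrode_set=montage.LEFT_CENTRAL)
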