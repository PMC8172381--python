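"""Inter-ILS distances, random-placement null, rank-sum test, partitioning."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ilsscan.clustering import (
    ILSSegmentSet,
    compare_distributions,
    inter_ils_distances,
    partition_clustered,
    simulate_null,
)

W = 500


def make_segset(ils_starts, n_analyzable, chrom="chr1", w=W):
    """Contiguous analyzable tiling [0, n*w) with ILS at the given starts."""
    analyzable = pd.DataFrame(
        dict(chrom=chrom, start=np.arange(n_analyzable) * w,
             end=(np.arange(n_analyzable) + 1) * w)
    )
    ils = pd.DataFrame(
        dict(chrom=chrom, start=list(ils_starts),
             end=[s + w for s in ils_starts], label="HB_ILS")
    )
    return ILSSegmentSet(window_size=w, ils=ils, analyzable=analyzable)


class TestInterDistances:
    def test_gap_definition(self):
        seg = make_segset([0, 1500, 2500], 10)
        d = inter_ils_distances(seg)
        assert list(d.pooled) == [1000, 500]

    def test_single_segment_contributes_nothing(self):
        assert list(inter_ils_distances(make_segset([1000], 10)).pooled) == []

    def test_adjacent_windows_have_zero_gap(self):
        assert list(inter_ils_distances(make_segset([0, 500], 10)).pooled) == [0]

    def test_overlapping_segments_rejected(self):
        seg = make_segset([0, 0], 10)
        with pytest.raises(ValueError):
            inter_ils_distances(seg)

    def test_cross_chromosome_gaps_not_counted(self):
        a = make_segset([0, 1000], 10, chrom="chr1")
        b = make_segset([0, 2000], 10, chrom="chr2")
        seg = ILSSegmentSet(
            window_size=W,
            ils=pd.concat([a.ils, b.ils], ignore_index=True),
            analyzable=pd.concat([a.analyzable, b.analyzable], ignore_index=True),
        )
        d = inter_ils_distances(seg)
        assert sorted(d.pooled) == [500, 1500]
        assert set(d.per_chrom) == {"chr1", "chr2"}


class TestNull:
    def test_forced_all_ils(self):
        seg = make_segset(np.arange(10) * W, 10)
        null = simulate_null(seg, n_sims=5, seed=1)
        assert set(null.gap_values.tolist()) == {0}

    def test_determinism(self):
        seg = make_segset(np.arange(0, 5000 * W, 7 * W), 5000)
        a = simulate_null(seg, n_sims=50, seed=42)
        b = simulate_null(seg, n_sims=50, seed=42)
        assert np.array_equal(a.gap_values, b.gap_values)
        assert np.array_equal(a.gap_counts, b.gap_counts)

    def test_mean_matches_uniform_spacing_formula(self):
        """E[gap] = W (N - n) / (n + 1) for uniform placement on a contiguous
        tiling; closed form re-derived by exhaustive enumeration at N=10, n=2."""
        # brute-force oracle at N=10, n=2
        N, n = 10, 2
        gaps = [
            (j - i - 1) * W
            for i, j in itertools.combinations(range(N), n)
        ]
        assert np.mean(gaps) == pytest.approx(W * (N - n) / (n + 1))

        seg = make_segset(np.arange(n) * W, N)
        null = simulate_null(seg, n_sims=20_000, seed=3)
        assert null.mean_gap() == pytest.approx(W * (N - n) / (n + 1), rel=0.02)

        N, n = 1000, 10
        seg = make_segset(np.arange(n) * W, N)
        null = simulate_null(seg, n_sims=10_000, seed=4)
        assert null.mean_gap() == pytest.approx(W * (N - n) / (n + 1), rel=0.02)

    def test_observed_count_exceeding_analyzable_rejected(self):
        seg = make_segset(np.arange(10) * W, 10)
        seg.analyzable = seg.analyzable.iloc[:5]
        with pytest.raises(ValueError):
            simulate_null(seg, n_sims=1, seed=0)


class TestCompare:
    def test_self_comparison_is_null(self):
        seg = make_segset(np.arange(0, 200 * W, 4 * W), 1000)
        null = simulate_null(seg, n_sims=2000, seed=9)
        obs = inter_ils_distances(seg)
        obs.pooled = null.sample_gaps(500)  # a draw matching the null law
        res = compare_distributions(obs, null)
        assert res.pvalue > 0.5

    def test_strong_clustering_detected(self):
        seg = make_segset(np.arange(0, 200 * W, 4 * W), 1000)
        null = simulate_null(seg, n_sims=2000, seed=9)
        obs = inter_ils_distances(seg)
        obs.pooled = (null.sample_gaps(200) // 10)
        res = compare_distributions(obs, null)
        assert res.pvalue < 1e-6

    def test_rank_sum_against_hand_normal_approximation(self):
        """Cross-check the returned p against a directly computed
        tie-corrected normal approximation of the rank-sum statistic."""
        rng = np.random.default_rng(0)
        x = rng.integers(0, 50, 300).astype(float) * W
        seg = make_segset(np.arange(0, 200 * W, 4 * W), 1000)
        null = simulate_null(seg, n_sims=1000, seed=9)
        y = null.sample_gaps(5000).astype(float)
        obs = inter_ils_distances(seg)
        obs.pooled = x
        res = compare_distributions(obs, null, max_null=5000)

        from scipy.stats import norm, rankdata

        allv = np.concatenate([x, y])
        ranks = rankdata(allv)
        n1, n2 = len(x), len(y)
        r1 = ranks[:n1].sum()
        u1 = r1 - n1 * (n1 + 1) / 2
        mu = n1 * n2 / 2
        _, t = np.unique(allv, return_counts=True)
        tie = (t ** 3 - t).sum() / ((n1 + n2) * (n1 + n2 - 1))
        sigma = np.sqrt(n1 * n2 / 12 * ((n1 + n2 + 1) - tie))
        z = (abs(u1 - mu) - 0.5) / sigma
        p_hand = 2 * norm.sf(z)
        assert res.pvalue == pytest.approx(p_hand, rel=1e-6)

    def test_degenerate_single_values(self):
        seg = make_segset([0, 3 * W], 10)
        obs = inter_ils_distances(seg)
        null = simulate_null(seg, n_sims=1, seed=0)
        null.gap_values = np.array([2 * W - 500])
        null.gap_counts = np.array([1])
        obs.pooled = np.array([2 * W - 500])
        res = compare_distributions(obs, null)
        assert res.pvalue == pytest.approx(1.0)

    def test_empty_rejected(self):
        seg = make_segset([0, 3 * W], 10)
        null = simulate_null(seg, n_sims=10, seed=0)
        obs = inter_ils_distances(seg)
        obs.pooled = np.array([])
        with pytest.raises(ValueError):
            compare_distributions(obs, null)


class TestPartition:
    def test_all_far_apart_none_clustered(self):
        n, N = 8, 5000
        seg = make_segset(np.arange(n) * 600 * W, N)
        null = simulate_null(seg, n_sims=500, seed=5)
        # move observations beyond the largest null gap
        far = make_segset(np.arange(n) * 620 * W, N)
        far.analyzable = seg.analyzable
        null.nn_values = np.array([0, W])
        null.nn_counts = np.array([1, 19])
        part = partition_clustered(far, null, q=0.05)
        assert part.clustered_fraction == 0.0
        assert len(part.non_clustered) == n

    def test_adjacent_run_fully_clustered(self):
        seg = make_segset(np.arange(20) * W, 1000)
        null = simulate_null(seg, n_sims=500, seed=6)
        part = partition_clustered(seg, null, q=0.05)
        assert part.clustered_fraction == 1.0

    def test_invalid_quantile(self):
        seg = make_segset(np.arange(20) * W, 1000)
        null = simulate_null(seg, n_sims=10, seed=6)
        with pytest.raises(ValueError):
            partition_clustered(seg, null, q=1.5)

    def test_scale_equivariance(self):
        """Multiplying coordinates (and W) by k scales gaps and threshold by k
        and leaves the clustered set unchanged."""
        starts = np.array([0, 2, 3, 9, 40, 41, 80]) * W
        seg = make_segset(starts, 500)
        null = simulate_null(seg, n_sims=2000, seed=7)
        part = partition_clustered(seg, null, q=0.1)

        k = 3
        seg_k = make_segset(starts * k, 500, w=W * k)
        null_k = simulate_null(seg_k, n_sims=2000, seed=7)
        part_k = partition_clustered(seg_k, null_k, q=0.1)
        assert part_k.threshold_bp == pytest.approx(part.threshold_bp * k)
        assert np.array_equal(part_k.clustered["start"].to_numpy(),
                              part.clustered["start"].to_numpy() * k)

    def test_null_calibration(self):
        """Partitioning data drawn from the null returns fraction ~= q."""
        q = 0.05
        N, n = 20_000, 100
        seg = make_segset(np.arange(n) * W, N)
        null = simulate_null(seg, n_sims=5000, seed=11)
        rng = np.random.default_rng(13)
        fracs = []
        for _ in range(30):
            starts = np.sort(rng.choice(N, size=n, replace=False)) * W
            draw = make_segset(starts, N)
            fracs.append(partition_clustered(draw, null, q=q).clustered_fraction)
        fracs = np.asarray(fracs)
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - q) <= 3 * se
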