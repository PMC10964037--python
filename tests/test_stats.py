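"""Group inference: t-maps vs closed forms, smoothness estimation, cluster
Monte-Carlo thresholding, FDR, Lilliefors, Mann-Whitney, clinical r."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage
from scipy import stats as sps

from benfc.stats import (
    cluster_mc_threshold,
    clinical_correlation,
    estimate_smoothness,
    extract_clusters,
    fdr_bh,
    lilliefors_normality,
    mann_whitney_u,
    paired_t_map,
    percent_change,
    two_sample_t_map,
)
from benfc.types import BrainMask, ScalarMap, VolumeGrid


def maps_from(arrays, grid, kind="ben"):
    return [ScalarMap(grid, a, kind) for a in arrays]


@pytest.fixture()
def grid1():
    return VolumeGrid.isotropic((2, 2, 2), 3.0)


class TestTMaps:
    def test_post_equals_pre_gives_zero_or_undefined(self, grid1, rng):
        a = [rng.standard_normal(grid1.dims) for _ in range(5)]
        res = paired_t_map(maps_from(a, grid1), maps_from([x.copy() for x in a], grid1))
        assert np.all(np.isnan(res.t.values))  # zero-variance differences

    def test_paired_closed_form_diffs_1_2_3(self, grid1):
        pre = maps_from([np.zeros(grid1.dims) for _ in range(3)], grid1)
        post = maps_from([np.full(grid1.dims, v) for v in (1.0, 2.0, 3.0)], grid1)
        res = paired_t_map(pre, post)
        assert res.df == 2
        assert res.t.values[0, 0, 0] == pytest.approx(3.464, abs=1e-3)

    def test_paired_df_is_n_minus_1_for_46_pairs(self, grid1, rng):
        pre = maps_from(rng.standard_normal((46, *grid1.dims)), grid1)
        post = maps_from(rng.standard_normal((46, *grid1.dims)), grid1)
        assert paired_t_map(pre, post).df == 45

    def test_two_sample_closed_form(self, grid1):
        a = maps_from([np.full(grid1.dims, v) for v in (1.0, 2.0, 3.0)], grid1)
        b = maps_from([np.full(grid1.dims, v) for v in (4.0, 5.0, 6.0)], grid1)
        res = two_sample_t_map(a, b)
        assert res.df == 4
        assert abs(res.t.values[0, 0, 0]) == pytest.approx(3.674, abs=1e-3)

    def test_matches_scipy_per_voxel(self, grid1, rng):
        pre = rng.standard_normal((8, *grid1.dims))
        post = rng.standard_normal((8, *grid1.dims))
        res = paired_t_map(maps_from(pre, grid1), maps_from(post, grid1))
        t_ref = sps.ttest_rel(post, pre, axis=0)
        assert np.allclose(res.t.values, t_ref.statistic, atol=1e-10)
        assert np.allclose(res.p.values, t_ref.pvalue, atol=1e-10)
        res2 = two_sample_t_map(maps_from(post, grid1), maps_from(pre, grid1))
        t_ref2 = sps.ttest_ind(post, pre, axis=0)
        assert np.allclose(res2.t.values, t_ref2.statistic, atol=1e-10)

    def test_misaligned_lists_raise(self, grid1, rng):
        a = maps_from(rng.standard_normal((4, *grid1.dims)), grid1)
        with pytest.raises(ValueError):
            paired_t_map(a, a[:3])


class TestSmoothness:
    def test_white_noise_hits_voxel_floor(self, rng):
        grid = VolumeGrid.isotropic((20, 20, 20), 3.0)
        mask = BrainMask(grid, np.ones(grid.dims, bool))
        maps = maps_from(rng.standard_normal((6, *grid.dims)), grid)
        fwhm = estimate_smoothness(maps, mask)
        for f in fwhm:
            assert 0.8 * 3.0 <= f <= 1.3 * 3.0

    def test_known_smoothing_recovered_within_15pct(self):
        grid = VolumeGrid.isotropic((24, 24, 24), 3.0)
        mask = BrainMask(grid, np.ones(grid.dims, bool))
        target = 8.0
        sigma = target / 2.3548 / 3.0
        est = []
        for s in range(20):
            rng = np.random.default_rng(s)
            smoothed = [
                ndimage.gaussian_filter(rng.standard_normal(grid.dims), sigma)
                for _ in range(4)
            ]
            est.append(np.mean(estimate_smoothness(maps_from(smoothed, grid), mask)))
        assert abs(np.mean(est) - target) / target < 0.15

    def test_constant_residuals_raise(self, rng):
        grid = VolumeGrid.isotropic((8, 8, 8), 3.0)
        mask = BrainMask(grid, np.ones(grid.dims, bool))
        maps = maps_from([np.ones(grid.dims)] * 3, grid)
        with pytest.raises(ValueError):
            estimate_smoothness(maps, mask)


class TestClusterMC:
    def test_alpha_one_gives_min_size_one(self):
        grid = VolumeGrid.isotropic((8, 8, 8), 3.0)
        mask = BrainMask(grid, np.ones(grid.dims, bool))
        assert cluster_mc_threshold(mask, 0.0, alpha=1.0, n_sim=100, seed=0) == 1

    def test_independent_voxels_small_threshold(self):
        grid = VolumeGrid.isotropic((22, 22, 22), 3.0)  # ~10k voxels
        mask = BrainMask(grid, np.ones(grid.dims, bool))
        for seed in (0, 1):
            mcs = cluster_mc_threshold(mask, 0.0, voxel_p=0.001, n_sim=300,
                                       seed=seed)
            assert mcs <= 3

    def test_threshold_non_decreasing_in_fwhm(self):
        grid = VolumeGrid.isotropic((16, 16, 16), 3.0)
        mask = BrainMask(grid, np.ones(grid.dims, bool))
        sizes = [
            cluster_mc_threshold(mask, f, n_sim=300, seed=7)
            for f in (0.0, 6.0, 12.0)
        ]
        assert sizes == sorted(sizes)

    def test_small_n_sim_warns(self):
        grid = VolumeGrid.isotropic((6, 6, 6), 3.0)
        mask = BrainMask(grid, np.ones(grid.dims, bool))
        with pytest.warns(UserWarning, match="n_sim"):
            cluster_mc_threshold(mask, 0.0, n_sim=50, seed=0)


class TestExtractClusters:
    def test_null_map_empty_report(self, rng):
        grid = VolumeGrid.isotropic((6, 6, 6), 3.0)
        pre = maps_from(rng.standard_normal((6, *grid.dims)), grid)
        post = maps_from(rng.standard_normal((6, *grid.dims)), grid)
        res = paired_t_map(pre, post)
        rep = extract_clusters(res, voxel_p=1e-6, min_cluster_size=1)
        assert len(rep) == 0

    def test_single_supra_voxel_is_one_cluster(self, grid1):
        pre = maps_from([np.zeros(grid1.dims) for _ in range(4)], grid1)
        arrs = []
        for v in (1.0, 1.1, 0.9, 1.05):
            a = np.zeros(grid1.dims)
            a[0, 0, 0] = v
            arrs.append(a)
        res = paired_t_map(pre, maps_from(arrs, grid1))
        rep = extract_clusters(res, voxel_p=0.01, min_cluster_size=1)
        assert len(rep) == 1
        assert rep.clusters[0].voxel_count == 1
        assert rep.clusters[0].sign == 1


class TestFdrBH:
    def test_four_value_fixture(self):
        reject, adj = fdr_bh([0.005, 0.01, 0.03, 0.04])
        assert np.allclose(adj, [0.02, 0.02, 0.04, 0.04])
        assert reject.all()

    def test_all_ones_no_rejection(self):
        reject, adj = fdr_bh([1.0, 1.0, 1.0])
        assert not reject.any()

    def test_single_p_identity(self):
        reject, adj = fdr_bh([0.04])
        assert reject[0] and adj[0] == pytest.approx(0.04)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.001, 1.0, 20)
        perm = rng.permutation(20)
        _, adj = fdr_bh(p)
        _, adj_perm = fdr_bh(p[perm])
        assert np.allclose(adj_perm, adj[perm], atol=1e-12)

    def test_empty_input(self):
        reject, adj = fdr_bh([])
        assert reject.size == 0 and adj.size == 0


class TestLilliefors:
    def test_null_rejection_rate_near_nominal(self):
        rej = 0
        for s in range(200):
            x = np.random.default_rng(s).standard_normal(200)
            _, p = lilliefors_normality(x)
            rej += p < 0.05
        assert rej / 200 <= 0.10  # ~5% nominal, binomial slack

    def test_exponential_power(self):
        rej = 0
        for s in range(50):
            x = np.random.default_rng(s).exponential(size=200)
            _, p = lilliefors_normality(x)
            rej += p < 0.05
        assert rej >= 48  # >= 95% power

    def test_tiny_sample_raises(self):
        with pytest.raises(ValueError):
            lilliefors_normality([1.0, 2.0, 3.0])


class TestMannWhitney:
    def test_separated_triplets_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_identical_samples(self):
        u, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert u == pytest.approx(4.5)  # n^2 / 2
        assert p == pytest.approx(1.0)

    def test_large_shift_significant(self, rng):
        a = rng.standard_normal(20)
        u, p = mann_whitney_u(a, a + 10.0)
        assert p < 0.001


class TestClinicalCorrelation:
    def test_perfect_linear_relation(self):
        d = np.arange(10.0)
        out = clinical_correlation({"ben": d}, {"hamd": 2 * d})
        assert out.r.iloc[0] == pytest.approx(1.0)

    def test_null_r_mostly_small_at_n46(self):
        small = 0
        for s in range(50):
            rng = np.random.default_rng(s)
            out = clinical_correlation(
                {"m": rng.standard_normal(46)}, {"c": rng.standard_normal(46)}
            )
            small += abs(out.r.iloc[0]) < 0.3
        assert small >= 48  # >= 95% of seeds

    def test_planted_negative_coupling_recovered(self):
        # mirrors an FC-change vs cognition-change anticorrelation
        neg = 0
        for s in range(50):
            rng = np.random.default_rng(s)
            x = rng.standard_normal(46)
            y = -0.5 * x + np.sqrt(1 - 0.25) * rng.standard_normal(46)
            out = clinical_correlation({"fc": x}, {"mmse": y})
            neg += out.r.iloc[0] < 0
        assert neg >= 48

    def test_percent_change_drops_zero_baseline(self):
        with pytest.warns(UserWarning, match="zero-baseline"):
            pc = percent_change(np.array([10.0, 0.0]), np.array([5.0, 5.0]))
        assert pc[0] == pytest.approx(-50.0)
        assert np.isnan(pc[1])
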