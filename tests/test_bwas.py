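import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bwaspipe.bwas import (
    compute_ma,
    count_links,
    extract_clusters,
    fwe_threshold,
    link_group_test,
    pair_indices,
    run_bwas,
    voxel_fc_fisher,
)
from bwaspipe.cohort_stats import two_sample_t
from bwaspipe.errors import (
    ConfigurationError,
    DataError,
    DegenerateDesignError,
    DegenerateVoxelError,
    SaturationError,
    UndercountError,
)
from bwaspipe.types import LinkTestTable, MAMap, VoxelCohort


def _cohort_from_matrix(data):
    """Wrap an (n_subjects, n_voxels, T) array as a flat-grid cohort."""
    data = np.asarray(data, dtype=float)
    mask = np.ones((data.shape[1], 1, 1), dtype=bool)
    ids = [f"sub-{k:03d}" for k in range(data.shape[0])]
    return VoxelCohort(subject_ids=ids, data=data, mask=mask, affine=np.eye(4))


def _pheno(n_cn, n_scd, rng):
    n = n_cn + n_scd
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{k:03d}" for k in range(n)],
            "group": ["CN"] * n_cn + ["SCD"] * n_scd,
            "age": rng.normal(64, 7, n),
            "education": rng.normal(12, 2.6, n),
            "mean_fd": rng.uniform(0.05, 0.2, n),
            "itv": rng.normal(1400, 100, n),
        }
    )


class TestCountLinks:
    def test_full_scale_value(self):
        assert count_links(23178) == 268_609_842

    def test_two_voxels(self):
        assert count_links(2) == 2  # floor(4/2) printed convention

    def test_one_voxel(self):
        assert count_links(1) == 0

    def test_pairs_convention(self):
        assert count_links(23178, convention="pairs") == 23178 * 23177 // 2

    def test_nonpositive_raises(self):
        with pytest.raises(ConfigurationError):
            count_links(0)


class TestVoxelFcFisher:
    def test_independent_noise_small_z(self):
        rng = np.random.default_rng(0)
        cohort = _cohort_from_matrix(rng.standard_normal((1, 2, 500)))
        z = voxel_fc_fisher(cohort)
        assert abs(z[0, 0]) < 0.15

    def test_no_self_links(self, rng):
        cohort = _cohort_from_matrix(rng.standard_normal((2, 5, 50)))
        z = voxel_fc_fisher(cohort)
        assert z.shape == (2, 10)  # 5*4/2 pairs, no (i, i)

    def test_constructed_r_half(self):
        # build a pair with exact sample correlation 0.5
        rng = np.random.default_rng(3)
        x = rng.standard_normal(100)
        x = (x - x.mean()) / x.std()
        e = rng.standard_normal(100)
        e = e - x * (x @ e) / (x @ x)  # orthogonalize
        e = (e - e.mean()) / e.std()
        y = 0.5 * x + np.sqrt(1 - 0.25) * e
        cohort = _cohort_from_matrix(np.stack([x, y])[None])
        z = voxel_fc_fisher(cohort)
        assert z[0, 0] == pytest.approx(np.arctanh(0.5), abs=1e-6)

    def test_zero_variance_raises_with_indices(self, rng):
        data = rng.standard_normal((1, 4, 50))
        data[0, 2] = 3.0
        with pytest.raises(DegenerateVoxelError, match=r"\[2\]"):
            voxel_fc_fisher(_cohort_from_matrix(data))

    def test_perfect_correlation_raises(self, rng):
        series = rng.standard_normal(50)
        data = np.stack([series, series])[None]
        with pytest.raises(SaturationError):
            voxel_fc_fisher(_cohort_from_matrix(data))


class TestLinkGroupTest:
    def test_no_covariates_equals_pooled_t(self, rng):
        z = rng.standard_normal((30, 6))
        pheno = _pheno(15, 15, rng)
        table = link_group_test(z, pheno, covariates=())
        for k in range(6):
            t_expected, _, p_expected = two_sample_t(z[:15, k], z[15:, k])
            # group coding is SCD=1, so the GLM t is -(CN-vs-SCD pooled t)
            assert table.t_stat[k] == pytest.approx(-t_expected, abs=1e-10)
            assert table.p_value[k] == pytest.approx(p_expected, abs=1e-10)

    def test_covariate_equal_to_group_raises(self, rng):
        z = rng.standard_normal((20, 3))
        pheno = _pheno(10, 10, rng)
        pheno["age"] = (pheno["group"] == "SCD").astype(float)
        with pytest.raises(DegenerateDesignError):
            link_group_test(z, pheno)

    def test_small_group_raises(self, rng):
        z = rng.standard_normal((5, 3))
        pheno = _pheno(4, 1, rng)
        with pytest.raises(DataError):
            link_group_test(z, pheno, covariates=())

    def test_injected_effect_links_dominate(self, effect_cohort):
        cohort, pheno, _, truth = effect_cohort
        z = voxel_fc_fisher(cohort)
        table = link_group_test(z, pheno)
        iu, ju = pair_indices(cohort.n_voxels)
        coords = cohort.voxel_coords
        # one endpoint per cluster (clusters sit at x<=1 and x>=8)
        in_a = coords[:, 0] <= 1
        in_b = coords[:, 0] >= 8
        affected = {tuple(c) for c in truth.affected_voxels}
        member = np.array([tuple(c) in affected for c in coords])
        cross = (
            ((in_a[iu] & in_b[ju]) | (in_b[iu] & in_a[ju]))
            & member[iu] & member[ju]
        )
        top = np.argsort(table.p_value)[: int(cross.sum())]
        assert cross[top].mean() > 0.9

    def test_retention_keeps_family_size(self, rng):
        z = rng.standard_normal((30, 10))
        pheno = _pheno(15, 15, rng)
        table = link_group_test(z, pheno, covariates=(), retain_p=0.5)
        assert table.n_links == count_links(5)
        assert len(table) <= 10
        assert np.all(table.p_value < 0.5)

    def test_residualize_method_close_to_glm(self, rng):
        z = rng.standard_normal((40, 10))
        pheno = _pheno(20, 20, rng)
        glm = link_group_test(z, pheno, method="glm")
        res = link_group_test(z, pheno, method="residualize")
        assert np.corrcoef(glm.t_stat, res.t_stat)[0, 1] > 0.99

    def test_subject_permutation_invariance(self, rng):
        z = rng.standard_normal((30, 6))
        pheno = _pheno(15, 15, rng)
        perm = rng.permutation(30)
        t1 = link_group_test(z, pheno, covariates=("age",)).t_stat
        t2 = link_group_test(
            z[perm], pheno.iloc[perm].reset_index(drop=True), covariates=("age",)
        ).t_stat
        assert np.allclose(t1, t2, atol=1e-10)


class TestFweThreshold:
    def test_paper_scale_cutoff(self):
        cutoff = fwe_threshold(3.33e-2, 268_609_842)
        assert cutoff == pytest.approx(1.2397e-10, rel=1e-3)

    def test_single_test(self):
        assert fwe_threshold(0.05, 1) == 0.05

    def test_monotone_decreasing(self):
        cuts = [fwe_threshold(0.05, n) for n in (1, 10, 100, 10_000)]
        assert all(a > b for a, b in zip(cuts, cuts[1:]))

    def test_zero_links_raises(self):
        with pytest.raises(ConfigurationError):
            fwe_threshold(0.05, 0)

    def test_bad_alpha_raises(self):
        with pytest.raises(ConfigurationError):
            fwe_threshold(1.5, 10)


def _table_from_pairs(n_voxels, sig_pairs, rng=None):
    iu, ju = pair_indices(n_voxels)
    p = np.full(len(iu), 0.9)
    sig = {tuple(sorted(pr)) for pr in sig_pairs}
    for k in range(len(iu)):
        if (iu[k], ju[k]) in sig:
            p[k] = 1e-12
    return LinkTestTable(
        i=iu, j=ju, t_stat=np.zeros(len(iu)), p_value=p,
        n_links=count_links(n_voxels), n_voxels=n_voxels,
    )


class TestComputeMa:
    def test_no_significant_links(self):
        table = _table_from_pairs(5, [])
        ma = compute_ma(table, alpha=0.05)
        assert np.all(ma.counts == 0)

    def test_incidence_counting(self):
        table = _table_from_pairs(5, [(0, 1), (0, 2), (1, 2)])
        ma = compute_ma(table, alpha=0.05)
        assert ma.counts.tolist() == [2, 2, 2, 0, 0]

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        n = 30
        iu, ju = pair_indices(n)
        p = rng.uniform(0, 1e-3, len(iu))
        table = LinkTestTable(
            i=iu, j=ju, t_stat=np.zeros(len(iu)), p_value=p,
            n_links=count_links(n), n_voxels=n,
        )
        alpha = 0.05
        ma = compute_ma(table, alpha)
        cutoff = alpha / count_links(n)
        expected = np.zeros(n, dtype=int)
        for i in range(n):  # brute-force double loop over all pairs
            for j in range(n):
                if i == j:
                    continue
                a, b = min(i, j), max(i, j)
                k = np.flatnonzero((iu == a) & (ju == b))[0]
                if p[k] < cutoff:
                    expected[i] += 1
        assert ma.counts.tolist() == expected.tolist()
        assert ma.counts.sum() == 2 * (p < cutoff).sum()

    def test_conservation_random(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            n = int(rng.integers(5, 40))
            iu, ju = pair_indices(n)
            p = rng.uniform(0, 2e-4, len(iu))
            table = LinkTestTable(
                i=iu, j=ju, t_stat=np.zeros(len(iu)), p_value=p,
                n_links=count_links(n), n_voxels=n,
            )
            ma = compute_ma(table, 0.05)
            n_sig = (p < 0.05 / count_links(n)).sum()
            assert ma.counts.sum() == 2 * n_sig

    def test_retention_below_cutoff_raises(self):
        table = _table_from_pairs(5, [(0, 1)])
        with pytest.raises(UndercountError):
            compute_ma(table, alpha=0.05, retain_p=1e-20)


def _ma_from_volume(vol, alpha=0.05):
    vol = np.asarray(vol)
    mask = np.ones(vol.shape, dtype=bool)
    return MAMap(counts=vol[mask], mask=mask, affine=np.eye(4), alpha=alpha)


class TestExtractClusters:
    def test_all_zero(self):
        clusters = extract_clusters(_ma_from_volume(np.zeros((5, 5, 5), int)))
        assert len(clusters) == 0

    def test_single_block(self):
        vol = np.zeros((6, 6, 6), int)
        vol[1:4, 1:4, 1:4] = 100
        clusters = extract_clusters(_ma_from_volume(vol), ma_min=40,
                                    min_cluster_voxels=20)
        assert len(clusters) == 1
        assert clusters.clusters[0].size == 27

    def test_diagonal_blocks_connectivity(self):
        # 12-voxel and 10-voxel blocks touching only at a corner diagonal
        vol = np.zeros((8, 8, 8), int)
        vol[1:4, 1:3, 1:3] = 50  # 3*2*2 = 12 voxels
        vol[4:6, 3:4, 3:8] = 50  # 2*1*5 = 10 voxels; (4,3,3) touches (3,2,2)
        c26 = extract_clusters(_ma_from_volume(vol), ma_min=40,
                               min_cluster_voxels=20, connectivity=26)
        c6 = extract_clusters(_ma_from_volume(vol), ma_min=40,
                              min_cluster_voxels=20, connectivity=6)
        assert len(c26) == 1 and c26.clusters[0].size == 22
        assert len(c6) == 0

    def test_threshold_is_strict(self):
        vol = np.full((4, 4, 4), 40, int)
        assert len(extract_clusters(_ma_from_volume(vol), ma_min=40,
                                    min_cluster_voxels=1)) == 0
        assert len(extract_clusters(_ma_from_volume(vol), ma_min=39,
                                    min_cluster_voxels=1)) == 1

    def test_peak_tie_lowest_linear_index(self):
        vol = np.zeros((4, 4, 4), int)
        vol[2, 2, 2] = 50
        vol[2, 2, 3] = 50  # tie: peak must be the lower linear index
        clusters = extract_clusters(_ma_from_volume(vol), ma_min=40,
                                    min_cluster_voxels=1)
        assert clusters.clusters[0].peak_coord.tolist() == [2, 2, 2]

    def test_peak_world_coordinate_uses_affine(self):
        vol = np.zeros((4, 4, 4), int)
        vol[1, 2, 3] = 60
        mask = np.ones(vol.shape, bool)
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        affine[:3, 3] = [-4, -4, -4]
        ma = MAMap(counts=vol[mask], mask=mask, affine=affine, alpha=0.05)
        clusters = extract_clusters(ma, ma_min=40, min_cluster_voxels=1)
        assert clusters.clusters[0].peak_world.tolist() == [-2.0, 0.0, 2.0]


class TestMaInvariants:
    @given(st.integers(0, 50))
    def test_conservation_property(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        iu, ju = pair_indices(n)
        p = rng.uniform(0, 1e-3, len(iu))
        table = LinkTestTable(
            i=iu, j=ju, t_stat=np.zeros(len(iu)), p_value=p,
            n_links=count_links(n), n_voxels=n,
        )
        ma = compute_ma(table, 0.05)
        assert ma.counts.sum() == 2 * (p < 0.05 / count_links(n)).sum()
        assert np.all(ma.counts <= n - 1)


class TestGroupLabelShuffleDestroysRecovery:
    def test_shuffled_labels_kill_clusters(self, effect_cohort):
        cohort, pheno, _, _ = effect_cohort
        rng = np.random.default_rng(123)
        shuffled = pheno.copy()
        shuffled["group"] = rng.permutation(shuffled["group"].to_numpy())
        _, _, clusters_true = run_bwas(cohort, pheno, ma_min=10,
                                       min_cluster_voxels=10)
        _, _, clusters_null = run_bwas(cohort, shuffled, ma_min=10,
                                       min_cluster_voxels=10)
        assert len(clusters_true) >= 1
        assert len(clusters_null) == 0
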