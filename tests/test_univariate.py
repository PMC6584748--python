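import numpy as np
import pytest
from scipy import stats

from rehopipe.io import BrainMask
from rehopipe.reho import ReHoMap
from rehopipe.univariate import (StatMap, chi2_gender, clinical_correlations,
                                 cluster_fwe, clusters_to_table, demographics,
                                 form_clusters, pearson_p_from_r, pearson_with_p,
                                 roi_mean, ttest_from_summary, voxelwise_ttest)
import pandas as pd


def _maps(values, affine=None):
    """values: (n, x, y, z) array -> list of ReHoMap."""
    affine = np.eye(4) if affine is None else affine
    return [ReHoMap(data=np.asarray(v, dtype=float), affine=affine) for v in values]


def _mask(shape):
    return BrainMask(data=np.ones(shape, bool), affine=np.eye(4))


class TestVoxelwiseTtest:
    def test_single_voxel_hand_value(self):
        """A={1,2,3}, B={4,5,6}: pooled t = -3/(1*sqrt(2/3)) = -3.674."""
        A = _maps(np.array([1.0, 2, 3]).reshape(3, 1, 1, 1))
        B = _maps(np.array([4.0, 5, 6]).reshape(3, 1, 1, 1))
        stat = voxelwise_ttest(A, B, _mask((1, 1, 1)))
        assert stat.t_values[0, 0, 0] == pytest.approx(-3.6742346, abs=1e-6)
        assert stat.df == 4

    def test_matches_scipy_on_random_maps(self, rng):
        shape = (4, 4, 4)
        A = _maps(rng.standard_normal((5,) + shape))
        B = _maps(rng.standard_normal((6,) + shape))
        stat = voxelwise_ttest(A, B, _mask(shape))
        a = np.stack([m.data for m in A]); b = np.stack([m.data for m in B])
        expected = stats.ttest_ind(a, b, axis=0, equal_var=True).statistic
        assert np.allclose(stat.t_values, expected)

    def test_equal_means_give_near_zero(self, rng):
        shape = (3, 3, 3)
        base = rng.standard_normal(shape)
        A = _maps([base + 0.1, base - 0.1, base + 0.05, base - 0.05])
        B = _maps([base + 0.1, base - 0.1, base + 0.05, base - 0.05])
        stat = voxelwise_ttest(A, B, _mask(shape))
        assert np.abs(stat.t_values).max() < 1e-10

    def test_sign_symmetry(self, rng):
        shape = (4, 4, 4)
        A = _maps(rng.standard_normal((4,) + shape) + 0.5)
        B = _maps(rng.standard_normal((4,) + shape))
        ab = voxelwise_ttest(A, B, _mask(shape))
        ba = voxelwise_ttest(B, A, _mask(shape))
        assert np.allclose(ab.t_values, -ba.t_values)

    def test_small_group_rejected(self, rng):
        A = _maps(rng.standard_normal((1, 2, 2, 2)))
        B = _maps(rng.standard_normal((3, 2, 2, 2)))
        with pytest.raises(ValueError):
            voxelwise_ttest(A, B, _mask((2, 2, 2)))

    def test_zero_variance_voxels_warn_and_zero(self):
        A = _maps(np.ones((3, 2, 2, 2)))
        B = _maps(np.ones((3, 2, 2, 2)))
        with pytest.warns(UserWarning, match="zero-variance"):
            stat = voxelwise_ttest(A, B, _mask((2, 2, 2)))
        assert not stat.t_values.any()


class TestFormClusters:
    def _stat(self, t_vol, df=20):
        return StatMap(t_values=np.asarray(t_vol, float), df=df, affine=np.eye(4),
                       mask=_mask(np.asarray(t_vol).shape))

    def test_zero_map_no_clusters(self):
        assert form_clusters(self._stat(np.zeros((6, 6, 6)))) == []

    def test_extent_filter_discards_small_blob(self):
        t = np.zeros((8, 8, 8)); t[2:4, 2:4, 2:4] = 10.0  # 8-voxel blob
        assert form_clusters(self._stat(t), min_extent=100) == []
        found = form_clusters(self._stat(t), min_extent=5)
        assert len(found) == 1 and found[0].extent == 8

    def test_corner_touching_blobs_split_by_connectivity(self):
        t = np.zeros((8, 8, 8))
        t[1:3, 1:3, 1:3] = 8.0
        t[3:5, 3:5, 3:5] = 8.0  # touches only at the (3,3,3)/(2,2,2) corner
        by_corner = form_clusters(self._stat(t), min_extent=1, connectivity=26)
        by_face = form_clusters(self._stat(t), min_extent=1, connectivity=6)
        assert len(by_corner) == 1
        assert len(by_face) == 2

    def test_signs_reported_separately(self):
        t = np.zeros((8, 8, 8))
        t[1:3, 1:3, 1:3] = 9.0
        t[5:7, 5:7, 5:7] = -9.0
        found = form_clusters(self._stat(t), min_extent=1)
        assert sorted(c.sign for c in found) == ["negative", "positive"]
        neg = next(c for c in found if c.sign == "negative")
        assert neg.peak_t == -9.0

    def test_peak_coordinates_through_affine(self):
        t = np.zeros((6, 6, 6)); t[2, 3, 4] = 10.0
        stat = StatMap(t_values=t, df=20, affine=np.diag([3.0, 3, 3, 1]),
                       mask=_mask((6, 6, 6)))
        c = form_clusters(stat, min_extent=1)[0]
        assert c.peak_voxel == (2, 3, 4)
        assert c.peak_mm == (6.0, 9.0, 12.0)


class TestClusterFwe:
    def _planted(self, rng, effect=3.0, n=6, shape=(7, 7, 7)):
        A = rng.standard_normal((n,) + shape) * 0.3
        B = rng.standard_normal((n,) + shape) * 0.3
        A[:, 2:5, 2:5, 2:5] += effect
        return _maps(A), _maps(B), _mask(shape)

    def test_strong_effect_saturates_p(self, rng):
        A, B, mask = self._planted(rng)
        clusters = cluster_fwe(A, B, mask, min_extent=5, n_perm=200, seed=0)
        assert clusters, "planted cluster not found"
        top = max(clusters, key=lambda c: c.extent)
        # C(12,6)=924 > 200 -> sampled null; minimum attainable p
        assert top.fwe_p == pytest.approx(1.0 / 201)

    def test_null_data_gives_large_p(self, rng):
        shape = (6, 6, 6)
        A = _maps(rng.standard_normal((5,) + shape))
        B = _maps(rng.standard_normal((5,) + shape))
        clusters = cluster_fwe(A, B, _mask(shape), min_extent=1, n_perm=150, seed=1)
        assert all(c.fwe_p > 0.05 for c in clusters)

    def test_fwe_p_monotone_in_extent(self, rng):
        shape = (10, 10, 10)
        A = rng.standard_normal((6,) + shape) * 0.4
        B = rng.standard_normal((6,) + shape) * 0.4
        A[:, 1:5, 1:5, 1:5] += 3.0     # large blob
        A[:, 7:9, 7:9, 7:9] += 3.0     # small blob
        clusters = cluster_fwe(_maps(A), _maps(B), _mask(shape),
                               min_extent=2, n_perm=100, seed=2)
        pos = sorted((c for c in clusters if c.sign == "positive"),
                     key=lambda c: -c.extent)
        assert len(pos) >= 2
        for big, small in zip(pos, pos[1:]):
            assert big.fwe_p <= small.fwe_p

    def test_exact_enumeration_for_tiny_groups(self, rng):
        shape = (5, 5, 5)
        A = rng.standard_normal((3,) + shape) * 0.2
        B = rng.standard_normal((3,) + shape) * 0.2
        A[:, 1:4, 1:4, 1:4] += 4.0
        # C(6,3) = 20 distinct relabelings <= n_perm -> exact enumeration.
        # The two-sided max statistic ties the observed value at both the
        # identity and the complement relabeling, so the exact minimum p is 2/20.
        clusters = cluster_fwe(_maps(A), _maps(B), _mask(shape),
                               min_extent=2, n_perm=1000, seed=3)
        top = max(clusters, key=lambda c: c.extent)
        assert top.fwe_p == pytest.approx(2.0 / 20)


class TestRoiMean:
    def test_constant_map(self):
        rmap = ReHoMap(data=np.full((4, 4, 4), 3.3), affine=np.eye(4))
        roi = np.zeros((4, 4, 4), bool); roi[1:3, 1:3, 1:3] = True
        assert roi_mean(rmap, roi) == pytest.approx(3.3)

    def test_single_voxel_and_index_array(self, rng):
        data = rng.random((4, 4, 4))
        rmap = ReHoMap(data=data, affine=np.eye(4))
        assert roi_mean(rmap, np.array([[1, 2, 3]])) == data[1, 2, 3]

    def test_checkerboard_half(self):
        data = np.indices((4, 4, 4)).sum(axis=0) % 2
        rmap = ReHoMap(data=data.astype(float), affine=np.eye(4))
        roi = np.ones((4, 4, 4), bool)
        assert roi_mean(rmap, roi) == pytest.approx(0.5)

    def test_empty_roi_rejected(self):
        rmap = ReHoMap(data=np.zeros((3, 3, 3)), affine=np.eye(4))
        with pytest.raises(ValueError):
            roi_mean(rmap, np.zeros((3, 3, 3), bool))


class TestPearson:
    @pytest.mark.parametrize("r, n, expected_p", [
        (0.241, 88, 0.024),
        (0.224, 88, 0.036),
    ])
    def test_p_from_printed_r_and_n(self, r, n, expected_p):
        assert round(pearson_p_from_r(r, n), 3) == expected_p

    def test_perfect_linear_relation(self, rng):
        x = rng.standard_normal(30)
        res = pearson_with_p(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p_two_tailed < 1e-20

    def test_matches_scipy(self, rng):
        x, y = rng.standard_normal((2, 25))
        res = pearson_with_p(x, y)
        sp = stats.pearsonr(x, y)
        assert res.r == pytest.approx(sp.statistic, abs=1e-12)
        assert res.p_two_tailed == pytest.approx(sp.pvalue, rel=1e-9)

    def test_matches_permutation_p_on_small_sample(self, rng):
        """The t-transform p agrees with a brute-force permutation p at n=12."""
        x = rng.standard_normal(12)
        y = 0.8 * x + rng.standard_normal(12)
        res = pearson_with_p(x, y)
        n_perm = 3000
        perm_rs = np.empty(n_perm)
        for i in range(n_perm):
            perm_rs[i] = np.corrcoef(x, rng.permutation(y))[0, 1]
        perm_p = (1 + (np.abs(perm_rs) >= abs(res.r)).sum()) / (n_perm + 1)
        assert res.p_two_tailed == pytest.approx(perm_p, abs=0.02)

    def test_missing_pairs_dropped(self):
        x = np.array([1.0, 2, 3, 4, np.nan])
        y = np.array([2.0, 4, 6, 8, 10])
        res = pearson_with_p(x, y)
        assert res.n == 4 and res.r == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_p([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson_with_p([1, 2], [1, 2])


class TestDemographics:
    def test_gender_table_matched_groups(self):
        chi2, p = chi2_gender(56, 32, 56, 32)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_age_from_summary_stats(self):
        t, p = ttest_from_summary(29.16, 8.71, 88, 27.88, 10.58, 88)
        assert t == pytest.approx(0.879, abs=0.005)
        assert p == pytest.approx(0.381, abs=0.005)

    def test_identical_groups_null(self):
        table = pd.DataFrame({
            "id": [f"s{i}" for i in range(8)],
            "group": ["patient"] * 4 + ["control"] * 4,
            "gender": ["M", "M", "F", "F"] * 2,
            "age": [20.0, 30, 40, 50] * 2,
        })
        res = demographics(table)
        assert res.gender_chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.age_t == pytest.approx(0.0, abs=1e-12)
        assert res.age_p == pytest.approx(1.0)

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError):
            chi2_gender(0, 0, 3, 4)


class TestClinicalCorrelations:
    def test_links_roi_values_to_patient_scores(self, rng):
        n = 40
        table = pd.DataFrame({
            "id": [f"p{i}" for i in range(n)],
            "group": ["patient"] * n,
            "ybocs_total": rng.standard_normal(n),
            "hamd": rng.standard_normal(n),
        })
        roi_vals = table["ybocs_total"].to_numpy() * 0.9 + rng.standard_normal(n) * 0.1
        out = clinical_correlations(roi_vals, table, roi_name="sfg")
        row = out[out["score"] == "ybocs_total"].iloc[0]
        assert row["r"] > 0.9 and row["p"] < 1e-6
        assert set(out["score"]) == {"ybocs_total", "hamd"}


def test_cluster_table_columns(rng):
    shape = (6, 6, 6)
    A = rng.standard_normal((4,) + shape) * 0.3
    A[:, 1:4, 1:4, 1:4] += 3.0
    B = rng.standard_normal((4,) + shape) * 0.3
    clusters = cluster_fwe(_maps(A), _maps(B), _mask(shape), min_extent=3,
                           n_perm=100, seed=0)
    table = clusters_to_table(clusters)
    assert list(table.columns) == ["sign", "extent", "peak_t", "peak_x_mm",
                                   "peak_y_mm", "peak_z_mm", "fwe_p"]
    assert (table["extent"] >= 3).all()
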