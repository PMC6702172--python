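"""Group maps, cluster statistics, laterality indices and the permutation test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnparc.group import (
    build_group_maps, build_mpm, cluster_volume_cog, compute_li, compute_sdi,
    overlap_consistency, permutation_test_tmax, resample_labels_to_common,
    threshold_mpm,
)
from rnparc.imaging import GeometryError, VolumeImage, VoxelGrid


def _img(values, affine=None):
    values = np.asarray(values, dtype=float)
    return VolumeImage(VoxelGrid(values.shape, affine if affine is not None
                                 else np.eye(4)), values)


class TestResample:
    def test_identity(self):
        rng = np.random.default_rng(0)
        labels = _img(rng.integers(0, 4, size=(8, 8, 8)))
        out = resample_labels_to_common(labels, np.eye(4), labels.grid)
        assert np.array_equal(out.values, labels.values)

    def test_one_voxel_translation(self):
        vals = np.zeros((8, 8, 8))
        vals[3, 3, 3] = 2.0
        labels = _img(vals)
        t = np.eye(4)
        t[:3, 3] = [1.0, 0.0, 0.0]  # subject -> common shifts +x by one voxel
        out = resample_labels_to_common(labels, t, labels.grid)
        assert out.values[4, 3, 3] == 2.0
        assert out.values.sum() == 2.0

    def test_labels_never_interpolated(self):
        rng = np.random.default_rng(1)
        labels = _img(rng.integers(0, 5, size=(9, 9, 9)))
        t = np.eye(4)
        t[:3, 3] = rng.normal(0, 0.3, size=3)
        out = resample_labels_to_common(labels, t, labels.grid)
        assert set(np.unique(out.values)) <= set(np.unique(labels.values))

    def test_phantom_transform_roundtrip_exact(self, default_cohort):
        from rnparc.phantom import PhantomSpec
        common = PhantomSpec().grid()
        for sub in default_cohort:
            out = resample_labels_to_common(sub.ground_truth, sub.to_common, common)
            assert np.array_equal(out.values, sub.ground_truth.values)

    def test_singular_transform_rejected(self):
        labels = _img(np.zeros((4, 4, 4)))
        with pytest.raises(GeometryError):
            resample_labels_to_common(labels, np.zeros((4, 4)), labels.grid)


class TestMpm:
    def test_percent_overlap(self):
        masks = [_img(np.zeros((2, 2, 2))) for _ in range(4)]
        for m in masks[:3]:
            m.values[0, 0, 0] = 1.0
        mpm = build_mpm(masks)
        assert mpm.values[0, 0, 0] == 75.0
        assert mpm.values[1, 1, 1] == 0.0

    def test_identical_masks_binary_map(self):
        m = _img((np.random.default_rng(2).random((4, 4, 4)) < 0.5).astype(float))
        mpm = build_mpm([m, m, m])
        assert set(np.unique(mpm.values)) <= {0.0, 100.0}

    def test_threshold_inclusive_and_nested(self):
        rng = np.random.default_rng(3)
        masks = [_img((rng.random((6, 6, 6)) < 0.6).astype(float)) for _ in range(4)]
        mpm = build_mpm(masks)
        assert threshold_mpm(_img(np.full((1, 1, 1), 75.0)), 75).values[0, 0, 0] == 1
        m25, m50, m75 = (threshold_mpm(mpm, p).as_bool() for p in (25, 50, 75))
        assert (m75 <= m50).all() and (m50 <= m25).all()
        with pytest.raises(ValueError):
            threshold_mpm(mpm, 0)


class TestClusterStats:
    def test_symmetric_block(self):
        vals = np.zeros((4, 4, 4))
        vals[0:2, 0:2, 0:2] = 1.0
        st_ = cluster_volume_cog(_img(vals))
        assert st_.volume_vox == 8 and st_.volume_mm3 == 8.0
        assert np.allclose(st_.cog_voxel, (0.5, 0.5, 0.5))

    def test_single_voxel_and_empty(self):
        vals = np.zeros((6, 6, 6))
        vals[3, 4, 5] = 1.0
        assert cluster_volume_cog(_img(vals)).cog_voxel == (3.0, 4.0, 5.0)
        empty = cluster_volume_cog(_img(np.zeros((2, 2, 2))))
        assert empty.volume_vox == 0 and empty.cog_voxel is None

    def test_cog_matches_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            vals = (rng.random((7, 7, 7)) < 0.2).astype(float)
            if not vals.any():
                continue
            st_ = cluster_volume_cog(_img(vals))
            idx = [(i, j, k) for i in range(7) for j in range(7) for k in range(7)
                   if vals[i, j, k]]
            brute = np.mean(np.asarray(idx, dtype=float), axis=0)
            assert np.allclose(st_.cog_voxel, brute)
            assert st_.volume_vox == len(idx)


class TestIndices:
    def test_sdi_arithmetic_and_limits(self):
        assert compute_sdi(40, 100) == 40.0
        assert compute_sdi(100, 100) == 100.0
        assert compute_sdi(0, 50) == 0.0
        with pytest.raises(ValueError):
            compute_sdi(5, 0)
        with pytest.raises(ValueError):
            compute_sdi(11, 10)

    def test_li_symmetry_and_bounds(self):
        assert compute_li(7.0, 7.0) == 0.0
        assert compute_li(1.0, 0.0) == 1.0
        # formula check on printed hemispheric mRN map volumes (135 vs 75)
        assert compute_li(135.0, 75.0) == pytest.approx(0.2857, abs=5e-5)
        with pytest.raises(ValueError):
            compute_li(0.0, 0.0)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(0.001, 1e6), st.floats(0.001, 1e6))
    def test_li_antisymmetric(self, a, b):
        assert compute_li(a, b) == pytest.approx(-compute_li(b, a), abs=1e-12)
        assert abs(compute_li(a, b)) <= 1.0


class TestPermutation:
    def test_all_zero_differences_give_p_one(self):
        x = np.ones((6, 3))
        res = permutation_test_tmax(x, x.copy(), n_perm=500, seed=0)
        assert (res.p_corrected == 1.0).all()
        assert (res.t_obs == 0.0).all()

    def test_exhaustive_minimal_p_matches_enumeration_oracle(self):
        """8 subjects, one cluster, all-positive differences: the two-sided
        exhaustive p is 2/2^8 (identity and full sign flip both reach |t_obs|),
        verified against an independent brute-force enumeration."""
        import itertools

        rng = np.random.default_rng(8)
        d = 1.0 + rng.uniform(-0.1, 0.1, size=(8, 1))  # all same sign
        res = permutation_test_tmax(d, np.zeros_like(d), exhaustive=True)
        assert res.n_perm == 256

        def t_of(x):
            return x.mean() / (x.std(ddof=1) / np.sqrt(len(x)))

        t_obs = abs(t_of(d[:, 0]))
        count = sum(abs(t_of(np.asarray(signs) * d[:, 0])) >= t_obs
                    for signs in itertools.product((-1, 1), repeat=8))
        assert count == 2
        assert res.p_corrected[0] == pytest.approx(count / 256)

    def test_corrected_never_below_uncorrected(self):
        rng = np.random.default_rng(9)
        left = rng.normal(size=(12, 4))
        right = rng.normal(size=(12, 4))
        res = permutation_test_tmax(left, right, n_perm=4000, seed=1)
        assert (res.p_corrected >= res.p_uncorrected - 1e-12).all()
        assert ((res.p_corrected > 0) & (res.p_corrected <= 1)).all()

    def test_seed_determinism(self):
        rng = np.random.default_rng(10)
        left = rng.normal(size=(10, 3))
        right = rng.normal(size=(10, 3))
        r1 = permutation_test_tmax(left, right, n_perm=2000, seed=42)
        r2 = permutation_test_tmax(left, right, n_perm=2000, seed=42)
        assert np.array_equal(r1.p_corrected, r2.p_corrected)

    def test_sampled_matches_exhaustive(self):
        rng = np.random.default_rng(11)
        left = rng.normal(size=(10, 3))
        right = rng.normal(size=(10, 3))
        ex = permutation_test_tmax(left, right, exhaustive=True)
        sa = permutation_test_tmax(left, right, n_perm=50_000, seed=3)
        assert np.abs(ex.p_corrected - sa.p_corrected).max() < 0.015

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            permutation_test_tmax(np.ones((1, 2)), np.zeros((1, 2)))

    def test_li_matrix_recorded(self):
        left = np.array([[2.0, 1.0], [3.0, 1.0]])
        right = np.array([[1.0, 1.0], [1.0, 3.0]])
        res = permutation_test_tmax(left, right, n_perm=100, seed=0)
        assert res.li_per_subject[0, 0] == pytest.approx(1 / 3)
        assert res.li_per_subject[1, 1] == pytest.approx(-0.5)


class TestGroupMaps:
    def test_nestedness_and_overlap_report(self, default_cohort, default_parcs):
        from rnparc.group import resample_labels_to_common
        from rnparc.phantom import PhantomSpec
        common = PhantomSpec().grid()
        labels = [resample_labels_to_common(p.label_map, s.to_common, common)
                  for s, p in zip(default_cohort, default_parcs)]
        g = build_group_maps(labels, default_parcs[0].label_codes)
        for name in default_parcs[0].label_codes:
            m25 = g.masks_at[(name, 25)].as_bool()
            m50 = g.masks_at[(name, 50)].as_bool()
            m75 = g.masks_at[(name, 75)].as_bool()
            assert (m75 <= m50).all() and (m50 <= m25).all()
        rep = overlap_consistency(g)
        # compartment clusters are stable across subjects: nonempty 75% core
        for name in ("cortex", "olive", "interposed"):
            assert rep[name]["has_core"]

    def test_empty_cluster_flagged_not_crashed(self):
        labels = [_img(np.zeros((4, 4, 4))) for _ in range(3)]
        g = build_group_maps(labels, {"ghost": 9})
        rep = overlap_consistency(g)
        assert not rep["ghost"]["has_core"]
        assert cluster_volume_cog(g.masks_at[("ghost", 75)]).volume_vox == 0
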