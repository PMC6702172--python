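"""Subject-level pipeline: selection, thresholding, normalization, WTA, merging."""

import numpy as np
import pytest

from rnparc.density import DensityMap
from rnparc.imaging import GeometryError, StreamlineSet, VolumeImage, VoxelGrid
from rnparc.parcellation import (
    DegenerateClusterError, TargetSpec, merge_clusters, normalize_by_mean,
    parcellate_subject, select_streamlines, target_density_in_roi,
    threshold_relative, winner_takes_all,
)
from rnparc.phantom import PhantomSpec, generate_cohort

from conftest import parcellate_phantom_subject, recovery_fraction


def _mask(grid, voxels):
    vals = np.zeros(grid.shape)
    for v in voxels:
        vals[v] = 1.0
    return VolumeImage(grid, vals)


@pytest.fixture
def tiny():
    grid = VoxelGrid((10, 10, 10), np.eye(4))
    seed = _mask(grid, [(2, 2, 2)])
    target = TargetSpec("t", [_mask(grid, [(8, 2, 2)])])
    roa = _mask(grid, [(5, 2, 2)])
    return grid, seed, target, roa


class TestSelect:
    def test_seed_and_target_hit_kept(self, tiny):
        grid, seed, target, roa = tiny
        # detours around the ROA voxel, touching seed and target
        sl_clear = np.array([[2.0, 2.0, 2.0], [2.0, 6.0, 2.0], [8.0, 2.0, 2.0]])
        kept = select_streamlines(StreamlineSet([sl_clear]), seed, target, [roa], grid)
        assert len(kept) == 1

    def test_roa_hit_removed(self, tiny):
        grid, seed, target, roa = tiny
        sl = np.array([[2.0, 2.0, 2.0], [8.0, 2.0, 2.0]])  # straight through the ROA
        kept = select_streamlines(StreamlineSet([sl]), seed, target, [roa], grid)
        assert len(kept) == 0

    def test_missing_seed_or_target_removed(self, tiny):
        grid, seed, target, roa = tiny
        no_seed = np.array([[0.0, 8.0, 8.0], [8.0, 2.0, 2.0]])
        no_target = np.array([[2.0, 2.0, 2.0], [2.0, 8.0, 8.0]])
        kept = select_streamlines(StreamlineSet([no_seed, no_target]),
                                  seed, target, [roa], grid)
        assert len(kept) == 0

    def test_grid_mismatch_rejected(self, tiny):
        grid, seed, target, roa = tiny
        other = VoxelGrid((10, 10, 10), np.diag([2.0, 2.0, 2.0, 1.0]))
        bad_seed = VolumeImage(other, seed.values)
        with pytest.raises(GeometryError):
            select_streamlines(StreamlineSet([]), bad_seed, target, [roa], grid)

    def test_phantom_roa_spurious_fully_filtered(self):
        """With all spurious streamlines routed through ROAs, selection
        recovers exactly the clean bundle of every target."""
        spec = PhantomSpec(n_subjects=1, seed=13, spurious_mode="roa",
                           spurious_fraction=0.2)
        sub = generate_cohort(spec)[0]
        grid = sub.nucleus_mask.grid
        for name, tmask in sub.target_masks.items():
            kept = select_streamlines(sub.streamlines, sub.nucleus_mask,
                                      TargetSpec(name, [tmask]), sub.roa_masks, grid)
            assert len(kept) == sum(t == name for t in sub.streamline_tags)


class TestDensityInRoi:
    def test_zero_streamlines(self, tiny):
        grid, seed, *_ = tiny
        d = target_density_in_roi(StreamlineSet([]), seed, grid)
        assert d.values.sum() == 0

    def test_masked_outside_seed(self, tiny):
        grid, seed, *_ = tiny
        sl = np.array([[2.0, 2.0, 2.0], [8.0, 2.0, 2.0]])
        d = target_density_in_roi(StreamlineSet([sl] * 10), seed, grid)
        assert d.values[2, 2, 2] == 10
        assert d.values.sum() == 10  # all other voxels 0 even though traversed

    def test_empty_seed_rejected(self, tiny):
        grid, *_ = tiny
        empty = VolumeImage(grid, np.zeros(grid.shape))
        with pytest.raises(ValueError):
            target_density_in_roi(StreamlineSet([]), empty, grid)


def _dmap(values):
    grid = VoxelGrid(values.shape, np.eye(4))
    return DensityMap(VolumeImage(grid, values.astype(float)), 0)


class TestThresholdRelative:
    def test_quarter_of_max_inclusive(self):
        d = _dmap(np.array([8.0, 2.0, 1.0]).reshape(3, 1, 1))
        out = threshold_relative(d, 0.25)
        assert out.values.ravel().tolist() == [8.0, 2.0, 0.0]

    def test_limits(self):
        vals = np.array([5.0, 3.0, 1.0]).reshape(3, 1, 1)
        assert np.array_equal(threshold_relative(_dmap(vals), 0.0).values, vals)
        top = threshold_relative(_dmap(vals), 1.0).values
        assert top.ravel().tolist() == [5.0, 0.0, 0.0]

    def test_all_zero_unchanged_and_bad_fraction(self):
        z = _dmap(np.zeros((2, 2, 2)))
        assert threshold_relative(z, 0.25).values.sum() == 0
        with pytest.raises(ValueError):
            threshold_relative(z, 1.5)


class TestNormalizeByMean:
    def test_two_point_case(self):
        out = normalize_by_mean(_dmap(np.array([2.0, 4.0, 0.0]).reshape(3, 1, 1)))
        assert np.allclose(out.values.ravel(), [2 / 3, 4 / 3, 0.0])

    def test_positive_mean_is_one(self):
        rng = np.random.default_rng(4)
        vals = rng.random((6, 6, 6)) * (rng.random((6, 6, 6)) < 0.4)
        out = normalize_by_mean(_dmap(vals))
        pos = out.values[out.values > 0]
        assert abs(pos.mean() - 1.0) < 1e-12

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateClusterError):
            normalize_by_mean(_dmap(np.zeros((2, 2, 2))))


class TestWinnerTakesAll:
    def _setup(self, a, b):
        grid = VoxelGrid((1, 1, 1), np.eye(4))
        seed = VolumeImage(grid, np.ones((1, 1, 1)))
        maps = {"A": _dmap(np.full((1, 1, 1), a)), "B": _dmap(np.full((1, 1, 1), b))}
        return winner_takes_all(maps, seed, order=["A", "B"])

    def test_highest_wins(self):
        labels, codes, ties = self._setup(1.2, 0.8)
        assert labels.values[0, 0, 0] == codes["A"] and ties == 0

    def test_all_zero_unassigned(self):
        labels, codes, ties = self._setup(0.0, 0.0)
        assert labels.values[0, 0, 0] == 0

    def test_tie_goes_to_configured_order_and_is_counted(self):
        labels, codes, ties = self._setup(1.0, 1.0)
        assert labels.values[0, 0, 0] == codes["A"]
        assert ties == 1

    def test_empty_collection_rejected(self):
        grid = VoxelGrid((1, 1, 1), np.eye(4))
        with pytest.raises(ValueError):
            winner_takes_all({}, VolumeImage(grid, np.ones((1, 1, 1))))


class TestMerge:
    def test_grouping_and_exclusion(self):
        grid = VoxelGrid((4, 1, 1), np.eye(4))
        labels = VolumeImage(grid, np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1))
        codes = {"cortex": 1, "olive": 2, "interposed": 3, "dentate": 4}
        merged, mcodes = merge_clusters(
            labels, {"cortex": "pRN", "olive": "pRN", "interposed": "mRN"},
            codes, merged_order=["pRN", "mRN"])
        out = merged.values.ravel().tolist()
        assert out == [mcodes["pRN"], mcodes["pRN"], mcodes["mRN"], 0.0]

    def test_unknown_label_rejected(self):
        grid = VoxelGrid((1, 1, 1), np.eye(4))
        labels = VolumeImage(grid, np.zeros((1, 1, 1)))
        with pytest.raises(KeyError):
            merge_clusters(labels, {"nope": "pRN"}, {"cortex": 1})

    def test_merged_volume_is_exact_union(self, default_parcs):
        for p in default_parcs:
            n_prn = (p.merged_label_map.values == p.merged_codes["pRN"]).sum()
            n_c = (p.label_map.values == p.label_codes["cortex"]).sum()
            n_o = (p.label_map.values == p.label_codes["olive"]).sum()
            assert n_prn == n_c + n_o


class TestPipeline:
    def test_noiseless_exact_recovery(self, noiseless_subject):
        p = parcellate_phantom_subject(noiseless_subject)
        assert recovery_fraction(noiseless_subject, p) == 1.0

    def test_hard_segmentation_inside_seed_only(self, default_cohort, default_parcs):
        for sub, p in zip(default_cohort, default_parcs):
            outside = ~sub.nucleus_mask.as_bool()
            assert (p.label_map.values[outside] == 0).all()
            assert set(np.unique(p.label_map.values)) <= {0.0} | set(
                float(c) for c in p.label_codes.values())

    def test_streamline_order_invariance(self, noiseless_subject):
        sub = noiseless_subject
        p1 = parcellate_phantom_subject(sub)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(sub.streamlines))
        shuffled = sub.streamlines.subset(list(perm))
        targets = [TargetSpec(n, [sub.target_masks[n]])
                   for n in ("cortex", "olive", "interposed", "dentate")]
        p2 = parcellate_subject(shuffled, sub.nucleus_mask, targets, sub.roa_masks)
        assert np.array_equal(p1.label_map.values, p2.label_map.values)

    def test_removing_target_yields_superset_labels(self, noiseless_subject):
        sub = noiseless_subject
        full = parcellate_phantom_subject(sub)
        targets = [TargetSpec(n, [sub.target_masks[n]])
                   for n in ("cortex", "olive", "dentate")]  # drop interposed
        reduced = parcellate_subject(sub.streamlines, sub.nucleus_mask, targets,
                                     sub.roa_masks, grouping={"cortex": "pRN",
                                                              "olive": "pRN"})
        assert "interposed" not in reduced.label_codes
        for name in ("cortex", "olive", "dentate"):
            before = full.label_map.values == full.label_codes[name]
            after = reduced.label_map.values == reduced.label_codes[name]
            # label sets can only grow when a competitor is removed
            assert (before & ~after).sum() == 0
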