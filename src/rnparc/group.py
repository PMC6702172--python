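"""Group-level analysis: common-space label maps, maximum probability maps,
cluster volumes/centres of gravity, the streamline density index (SDI), the
lateralization index (LI), and a paired permutation test with t-max
familywise correction.

Definitions
-----------
MPM
    Per cluster, the per-voxel percentage of subjects whose (binarized)
    label includes the voxel; thresholded at 25/50/75% (inclusive), the
    masks are nested by construction.
SDI
    100 * cluster voxel count / seed-ROI voxel count.
LI
    (Left - Right) / (Left + Right) of a cluster's hemispheric volumes;
    positive means left-lateralized.
t-max permutation test
    Paired differences d = left - right per subject; the null is built by
    random per-subject sign flips shared across clusters within a
    permutation; per permutation the maximum |t| across clusters is
    recorded, which makes the corrected p-values familywise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import GeometryError, VolumeImage, VoxelGrid, world_to_voxel, voxel_to_world


@dataclass
class ClusterStats:
    volume_vox: int
    volume_mm3: float
    cog_voxel: tuple[float, float, float] | None  # None for an empty mask
    cog_world: tuple[float, float, float] | None
    sdi_pct: float | None = None


@dataclass
class GroupMaps:
    overlap_pct: dict[str, VolumeImage]
    masks_at: dict[tuple[str, int], VolumeImage]
    n_subjects: int


@dataclass
class PermutationResult:
    cluster_names: list[str]
    li_per_subject: np.ndarray       # (n_subjects, n_clusters)
    t_obs: np.ndarray                # (n_clusters,)
    p_corrected: np.ndarray          # t-max familywise-corrected, two-sided
    p_uncorrected: np.ndarray
    n_perm: int
    alpha: float
    seed: int | None
    exhaustive: bool

    @property
    def significant(self) -> np.ndarray:
        return self.p_corrected < self.alpha


def resample_labels_to_common(labels: VolumeImage, transform: np.ndarray,
                              common: VoxelGrid) -> VolumeImage:
    """Nearest-neighbour resampling of an integer label map onto ``common``.

    ``transform`` maps subject world mm to common world mm. Labels are
    gathered, never interpolated; out-of-field voxels become 0.
    """
    transform = np.asarray(transform, dtype=float)
    if transform.shape != (4, 4) or abs(np.linalg.det(transform)) < 1e-12:
        raise GeometryError("transform must be an invertible 4x4 affine")
    idx = np.indices(common.shape).reshape(3, -1).T.astype(float)
    world_common = voxel_to_world(idx, common)
    inv = np.linalg.inv(transform)
    world_subj = world_common @ inv[:3, :3].T + inv[:3, 3]
    cont = world_to_voxel(world_subj, labels.grid)
    vox = np.floor(cont + 0.5).astype(np.int64)
    shape = labels.grid.shape
    inside = ((vox >= 0) & (vox < np.asarray(shape))).all(axis=1)
    out = np.zeros(len(vox), dtype=np.float64)
    v = vox[inside]
    out[inside] = labels.values[v[:, 0], v[:, 1], v[:, 2]]
    return VolumeImage(common, out.reshape(common.shape))


def build_mpm(per_subject_masks: list[VolumeImage]) -> VolumeImage:
    """Percent-overlap map: 100 x (subjects with mask=1) / n_subjects."""
    if not per_subject_masks:
        raise ValueError("need at least one subject mask")
    grid = per_subject_masks[0].grid
    for m in per_subject_masks[1:]:
        if m.grid != grid:
            raise GeometryError("subject masks do not share a grid")
    stack = np.stack([m.as_bool() for m in per_subject_masks])
    return VolumeImage(grid, 100.0 * stack.sum(axis=0) / len(per_subject_masks))


def threshold_mpm(mpm: VolumeImage, pct: float) -> VolumeImage:
    """Binary mask of voxels with overlap >= pct (inclusive)."""
    if not (0.0 < pct <= 100.0):
        raise ValueError(f"pct must be in (0, 100], got {pct}")
    return VolumeImage(mpm.grid, (mpm.values >= pct).astype(np.float64))


def cluster_volume_cog(mask: VolumeImage) -> ClusterStats:
    """Voxel/mm^3 volume and unweighted centre of gravity of a binary mask.

    An empty mask yields volume 0 and COG ``None`` (flagged degenerate, not
    an error).
    """
    vox = np.argwhere(mask.as_bool())
    n = len(vox)
    vol_mm3 = n * mask.grid.voxel_volume
    if n == 0:
        return ClusterStats(0, 0.0, None, None)
    cog_vox = vox.mean(axis=0)
    cog_world = voxel_to_world(cog_vox, mask.grid)[0]
    return ClusterStats(n, float(vol_mm3), tuple(cog_vox), tuple(cog_world))


def compute_sdi(cluster_vox: int, roi_vox: int) -> float:
    """Streamline density index: 100 * cluster voxels / seed-ROI voxels."""
    if roi_vox <= 0:
        raise ValueError("seed ROI has no voxels")
    if not (0 <= cluster_vox <= roi_vox):
        raise ValueError(f"cluster size {cluster_vox} outside [0, {roi_vox}]")
    return 100.0 * cluster_vox / roi_vox


def compute_li(left_vol: float, right_vol: float) -> float:
    """Lateralization index (L - R)/(L + R); positive = left-lateralized."""
    if left_vol < 0 or right_vol < 0:
        raise ValueError("volumes must be non-negative")
    total = left_vol + right_vol
    if total == 0:
        raise ValueError("cannot compute LI of two empty clusters")
    return (left_vol - right_vol) / total


def _paired_t(d: np.ndarray) -> np.ndarray:
    """One-sample t on columns of d; 0/0 (all-zero column) defined as t=0."""
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        t = np.where(sd == 0, np.where(mean == 0, 0.0, np.inf * np.sign(mean)), t)
    return t


def permutation_test_tmax(left: np.ndarray, right: np.ndarray, n_perm: int = 50_000,
                          alpha: float = 0.05, seed: int | None = 0,
                          exhaustive: bool = False,
                          cluster_names: list[str] | None = None) -> PermutationResult:
    """Paired sign-flip permutation test with t-max familywise correction.

    Per subject and cluster, d = left - right; the observed statistic is the
    one-sample t of d per cluster. The null flips the sign of each subject's
    whole difference vector (flips shared across clusters), records the max
    |t| over clusters per permutation, and the two-sided corrected p-value is
    ``(1 + #{t_max >= |t_obs|}) / (n_perm + 1)`` (add-one estimator, p > 0).
    With ``exhaustive=True`` all 2^n sign patterns are enumerated and the
    p-value is the exact proportion ``#{t_max >= |t_obs|} / 2^n``.
    """
    left = np.atleast_2d(np.asarray(left, dtype=float))
    right = np.atleast_2d(np.asarray(right, dtype=float))
    if left.shape != right.shape:
        raise ValueError("left and right must have the same shape")
    n, k = left.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    d = left - right
    t_obs = _paired_t(d)
    abs_t_obs = np.abs(t_obs)

    # Under sign flips s (n,), column means are (s @ d)/n while sum of squares
    # is invariant, so the whole null is two matmuls.
    sumsq = (d ** 2).sum(axis=0)

    def t_null(signs: np.ndarray) -> np.ndarray:
        mean = signs @ d / n                          # (m, k)
        var = (sumsq - n * mean ** 2) / (n - 1)
        var = np.maximum(var, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / np.sqrt(var / n)
            t = np.where(var == 0, np.where(mean == 0, 0.0, np.inf * np.sign(mean)), t)
        return t

    if exhaustive:
        if n > 20:
            raise ValueError("exhaustive enumeration limited to n <= 20 subjects")
        m = 2 ** n
        signs = 1 - 2 * ((np.arange(m)[:, None] >> np.arange(n)[None, :]) & 1)
        t = t_null(signs.astype(float))
        tmax = np.abs(t).max(axis=1)
        p_corr = (tmax[:, None] >= abs_t_obs[None, :]).mean(axis=0)
        p_unc = (np.abs(t) >= abs_t_obs[None, :]).mean(axis=0)
        n_perm_eff = m
    else:
        rng = np.random.default_rng(seed)
        p_corr_cnt = np.zeros(k)
        p_unc_cnt = np.zeros(k)
        done = 0
        while done < n_perm:
            m = min(n_perm - done, 20_000)
            signs = rng.choice((-1.0, 1.0), size=(m, n))
            t = t_null(signs)
            abs_t = np.abs(t)
            tmax = abs_t.max(axis=1)
            p_corr_cnt += (tmax[:, None] >= abs_t_obs[None, :]).sum(axis=0)
            p_unc_cnt += (abs_t >= abs_t_obs[None, :]).sum(axis=0)
            done += m
        p_corr = (1.0 + p_corr_cnt) / (n_perm + 1.0)
        p_unc = (1.0 + p_unc_cnt) / (n_perm + 1.0)
        n_perm_eff = n_perm
    # all-zero clusters carry no evidence in either direction
    zero = (d == 0).all(axis=0)
    p_corr = np.where(zero, 1.0, p_corr)
    p_unc = np.where(zero, 1.0, p_unc)
    names = cluster_names or [f"cluster_{i}" for i in range(k)]
    return PermutationResult(
        cluster_names=list(names), li_per_subject=_li_matrix(left, right),
        t_obs=t_obs, p_corrected=p_corr, p_uncorrected=p_unc,
        n_perm=n_perm_eff, alpha=alpha, seed=seed, exhaustive=exhaustive,
    )


def _li_matrix(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    total = left + right
    with np.errstate(divide="ignore", invalid="ignore"):
        li = (left - right) / total
    return np.where(total == 0, np.nan, li)


def overlap_consistency(group: GroupMaps, core_pct: float = 75.0) -> dict[str, dict]:
    """Per cluster: does a nonempty core exist at ``core_pct`` overlap?"""
    report = {}
    for name, mpm in group.overlap_pct.items():
        core = int((mpm.values >= core_pct).sum())
        report[name] = {
            "core_pct": core_pct,
            "core_voxels": core,
            "has_core": core > 0,
            "max_overlap_pct": float(mpm.values.max()),
        }
    return report


def build_group_maps(per_subject_labels: list[VolumeImage], codes: dict[str, int],
                     thresholds: tuple[int, ...] = (25, 50, 75)) -> GroupMaps:
    """Binarize each cluster per subject, build its MPM, threshold it."""
    overlap: dict[str, VolumeImage] = {}
    masks: dict[tuple[str, int], VolumeImage] = {}
    for name, code in codes.items():
        bin_masks = [VolumeImage(lm.grid, (lm.values == code).astype(np.float64))
                     for lm in per_subject_labels]
        mpm = build_mpm(bin_masks)
        overlap[name] = mpm
        for pct in thresholds:
            masks[(name, pct)] = threshold_mpm(mpm, pct)
    return GroupMaps(overlap_pct=overlap, masks_at=masks,
                     n_subjects=len(per_subject_labels))
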