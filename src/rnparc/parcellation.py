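"""Subject-level connectivity-based parcellation of the seed nucleus.

Pipeline, in fixed order: select target-wise streamlines from the whole
tractogram (seed AND target hit, no exclusion-mask hit), rasterize each
selection to a track-density image restricted to the seed ROI, threshold each
cluster at a fraction (default 25%) of its maximum intensity, normalize each
cluster by the mean of its suprathreshold voxels (so density values are
comparable across differently-sized bundles), then hard-segment the seed by
winner-takes-all: each voxel goes to the target with the highest normalized
density. A second, hypothesis-driven level merges first-level clusters into
putative subdivisions (by default cortex+olive -> parvocellular "pRN",
interposed -> magnocellular "mRN", dentate excluded: its fibres may traverse
the nucleus without synapsing).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .density import DensityMap, compute_tdi, traversal_cells_array
from .imaging import GeometryError, StreamlineSet, VolumeImage, VoxelGrid

logger = logging.getLogger(__name__)


class DegenerateClusterError(ValueError):
    """Raised when a density cluster has no positive voxels."""


@dataclass
class TargetSpec:
    """A named connectivity target: one or more include masks.

    A streamline is attributed to the target when its voxel traversal hits
    the seed AND at least one include mask (bilateral targets pool the
    ipsilateral and contralateral masks here) AND no exclusion mask.
    """

    name: str
    include_masks: list[VolumeImage]
    laterality_group: str | None = None

    def __post_init__(self):
        if not self.include_masks:
            raise ValueError(f"target {self.name!r} needs at least one include mask")
        for m in self.include_masks:
            if not m.as_bool().any():
                raise ValueError(f"target {self.name!r} has an empty include mask")


@dataclass
class SubjectParcellation:
    subject_id: str
    density_by_target: dict[str, DensityMap]        # raw ROI-restricted TDIs
    thresholded_by_target: dict[str, DensityMap]    # after relative threshold
    normalized_by_target: dict[str, DensityMap]     # after mean normalization
    label_map: VolumeImage                          # first-level codes, 0 = unassigned
    merged_label_map: VolumeImage                   # merged codes, 0 = unassigned/excluded
    label_codes: dict[str, int]                     # target name -> first-level code
    merged_codes: dict[str, int]                    # merged name -> code
    tie_count: int
    n_selected: dict[str, int]                      # streamlines kept per target
    dropped_targets: list[str] = field(default_factory=list)
    config_fingerprint: str = ""


def _check_same_grid(grid: VoxelGrid, *imgs: VolumeImage):
    for img in imgs:
        if img.grid != grid:
            raise GeometryError("masks do not share the reference grid")


def select_streamlines(s: StreamlineSet, seed: VolumeImage, target: TargetSpec,
                       roas: list[VolumeImage], grid: VoxelGrid) -> StreamlineSet:
    """Keep streamlines traversing the seed AND an include mask AND no ROA.

    Intersection is traversal-based (any voxel of the streamline's path in
    the mask), not endpoint-based; point data are returned unmodified.
    """
    _check_same_grid(grid, seed, *target.include_masks, *roas)
    seed_b = seed.as_bool()
    inc_b = [m.as_bool() for m in target.include_masks]
    roa_b = [m.as_bool() for m in roas]
    kept = []
    for i, sl in enumerate(s):
        cells = traversal_cells_array(sl, grid)
        if len(cells) == 0:
            continue
        idx = (cells[:, 0], cells[:, 1], cells[:, 2])
        if not seed_b[idx].any():
            continue
        if not any(m[idx].any() for m in inc_b):
            continue
        if any(m[idx].any() for m in roa_b):
            continue
        kept.append(i)
    return s.subset(kept, provenance=f"{s.provenance}|{target.name}")


def target_density_in_roi(selected: StreamlineSet, seed: VolumeImage,
                          grid: VoxelGrid) -> DensityMap:
    """TDI of the selected streamlines, zeroed outside the seed ROI."""
    _check_same_grid(grid, seed)
    if not seed.as_bool().any():
        raise ValueError("seed mask is empty")
    tdi = compute_tdi(selected, grid)
    vals = tdi.values * seed.as_bool()
    return DensityMap(VolumeImage(grid, vals), tdi.n_streamlines_mapped)


def threshold_relative(d: DensityMap, fraction: float) -> DensityMap:
    """Zero voxels below ``fraction`` x max intensity (inclusive keep)."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    vals = d.values
    mx = vals.max()
    if mx <= 0:
        return DensityMap(d.image.like(vals.copy()), d.n_streamlines_mapped)
    out = np.where(vals >= fraction * mx, vals, 0.0)
    return DensityMap(d.image.like(out), d.n_streamlines_mapped)


def normalize_by_mean(d: DensityMap) -> DensityMap:
    """Divide by the mean over the positive (suprathreshold) voxels.

    The mean is over positive voxels only, so the normalizer does not depend
    on ROI size; positive voxels of the result have mean exactly 1.
    """
    vals = d.values
    pos = vals > 0
    if not pos.any():
        raise DegenerateClusterError("cannot normalize an all-zero density map")
    return DensityMap(d.image.like(vals / vals[pos].mean()), d.n_streamlines_mapped)


def winner_takes_all(normalized: dict[str, DensityMap], seed: VolumeImage,
                     order: list[str] | None = None):
    """Hard segmentation: each seed voxel to the target with highest density.

    Returns ``(label_map, label_codes, tie_count)``. Voxels where every
    target is zero stay 0 (unassigned). Exact ties go to the earliest target
    in the configured order; every tie event is counted.
    """
    if not normalized:
        raise ValueError("winner_takes_all needs at least one target map")
    names = list(normalized) if order is None else [n for n in order if n in normalized]
    grid = seed.grid
    _check_same_grid(grid, seed, *(normalized[n].image for n in names))
    stack = np.stack([normalized[n].values for n in names])  # (k, x, y, z)
    seed_b = seed.as_bool()
    best = np.argmax(stack, axis=0)  # argmax returns the FIRST max: order tie-break
    maxval = np.take_along_axis(stack, best[None], axis=0)[0]
    labels = np.where(seed_b & (maxval > 0), best + 1, 0).astype(np.int16)
    n_max = (stack == maxval[None]).sum(axis=0)
    tie_count = int(((n_max > 1) & seed_b & (maxval > 0)).sum())
    codes = {n: i + 1 for i, n in enumerate(names)}
    return VolumeImage(grid, labels.astype(np.float64)), codes, tie_count


def merge_clusters(labels: VolumeImage, grouping: dict[str, str],
                   label_codes: dict[str, int],
                   merged_order: list[str] | None = None):
    """Relabel first-level clusters into merged subdivisions.

    ``grouping`` maps first-level target names to merged names; targets
    absent from it (e.g. the dentate) map to 0 (excluded). Returns
    ``(merged_map, merged_codes)``.
    """
    unknown = set(grouping) - set(label_codes)
    if unknown:
        raise KeyError(f"grouping references unknown targets: {sorted(unknown)}")
    merged_names = merged_order or sorted(set(grouping.values()))
    merged_codes = {n: i + 1 for i, n in enumerate(merged_names)}
    lut = np.zeros(max(label_codes.values()) + 1, dtype=np.int16)
    for tname, mname in grouping.items():
        lut[label_codes[tname]] = merged_codes[mname]
    vals = lut[labels.values.astype(np.int64)]
    return VolumeImage(labels.grid, vals.astype(np.float64)), merged_codes


DEFAULT_GROUPING = {"cortex": "pRN", "olive": "pRN", "interposed": "mRN"}
DEFAULT_MERGED_ORDER = ["pRN", "mRN"]


def parcellate_subject(streamlines: StreamlineSet, seed: VolumeImage,
                       targets: list[TargetSpec], roas: list[VolumeImage],
                       subject_id: str = "",
                       cluster_threshold_fraction: float = 0.25,
                       grouping: dict[str, str] | None = None,
                       merged_order: list[str] | None = None) -> SubjectParcellation:
    """Run the full subject-level pipeline in its fixed order.

    Targets whose thresholded cluster is empty are dropped with a warning
    (they simply contribute no label); every intermediate map is retained.
    """
    grid = seed.grid
    grouping = DEFAULT_GROUPING if grouping is None else grouping
    merged_order = DEFAULT_MERGED_ORDER if merged_order is None else merged_order
    raw: dict[str, DensityMap] = {}
    thr: dict[str, DensityMap] = {}
    norm: dict[str, DensityMap] = {}
    n_selected: dict[str, int] = {}
    dropped: list[str] = []
    for t in targets:
        try:
            sel = select_streamlines(streamlines, seed, t, roas, grid)
            n_selected[t.name] = len(sel)
            d = target_density_in_roi(sel, seed, grid)
            raw[t.name] = d
            dthr = threshold_relative(d, cluster_threshold_fraction)
            thr[t.name] = dthr
            norm[t.name] = normalize_by_mean(dthr)
        except DegenerateClusterError:
            dropped.append(t.name)
            warnings.warn(f"target {t.name!r}: empty density cluster, dropped "
                          f"from winner-takes-all", stacklevel=2)
            logger.warning("subject %s: target %s dropped (empty cluster)",
                           subject_id, t.name)
        except Exception as e:
            raise type(e)(f"[stage: {t.name}] {e}") from e
    order = [t.name for t in targets if t.name in norm]
    label_map, codes, ties = winner_takes_all(norm, seed, order=order)
    grouping_eff = {k: v for k, v in grouping.items() if k in codes}
    merged, merged_codes = merge_clusters(label_map, grouping_eff, codes, merged_order)
    config = {
        "targets": [t.name for t in targets],
        "cluster_threshold_fraction": cluster_threshold_fraction,
        "grouping": grouping, "merged_order": merged_order,
    }
    fp = hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]
    return SubjectParcellation(
        subject_id=subject_id, density_by_target=raw, thresholded_by_target=thr,
        normalized_by_target=norm, label_map=label_map, merged_label_map=merged,
        label_codes=codes, merged_codes=merged_codes, tie_count=ties,
        n_selected=n_selected, dropped_targets=dropped, config_fingerprint=fp,
    )
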