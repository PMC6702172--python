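"""Synthetic multi-subject streamline phantoms with a planted nucleus topography.

The phantom emulates the study design end-to-end without any real data: a
compact ellipsoidal seed nucleus whose voxels are partitioned into planted
target-specific territories (a small dorsomedial territory for the interposed
nucleus, the remaining ventrolateral volume split between a cortical and an
olivary territory), plus a diffuse non-compartmentalized territory for the
dentate target, modelling fibres that merely pass through the nucleus.
Streamlines are jittered straight bundles from a territory voxel to the
target mask, so selection/counting oracles are exact. A configurable fraction
of spurious streamlines connects mismatched territory/target pairs or is
routed through an exclusion (ROA) mask. Mild per-subject rigid affine
perturbations stand in for native-space variability; each subject carries the
exact inverse as its transform to the common grid, so group alignment error
is zero by construction unless deliberately degraded.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .imaging import (
    StreamlineSet,
    VolumeImage,
    VoxelGrid,
    read_streamlines,
    read_volume,
    voxel_to_world,
    write_streamlines,
    write_volume,
)


class PhantomSpecError(ValueError):
    """Raised for inconsistent phantom specifications."""


@dataclass(frozen=True)
class TargetPhantomSpec:
    """One connectivity target: its mask ellipsoid and planted territory.

    ``fraction`` is the share of nucleus voxels planted for this target;
    ``None`` marks a diffuse (non-compartmentalized) target whose streamlines
    seed uniformly across the whole nucleus. ``pole`` is the direction (voxel
    units, from the nucleus centre) along which the territory is carved.
    ``exit_axis``/``exit_sign`` give the axis-aligned direction along which
    the target's bundle leaves the nucleus; it must point "up" the territory's
    own pole and "down" the poles of territories carved before it, so that a
    column of voxels along the exit direction never leaves its own territory
    while inside the nucleus.
    """

    name: str
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    fraction: float | None
    pole: tuple[float, float, float] = (0.0, 0.0, 0.0)
    exit_axis: int = 1
    exit_sign: int = 1


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (40, 40, 40)
    voxel_size_mm: float = 1.0
    origin_mm: tuple[float, float, float] = (-20.0, -20.0, -20.0)
    nucleus_center: tuple[float, float, float] = (20.0, 20.0, 20.0)
    nucleus_radii: tuple[float, float, float] = (6.0, 7.0, 5.0)
    targets: tuple[TargetPhantomSpec, ...] = ()
    roa_boxes: tuple[tuple[tuple[int, int], tuple[int, int], tuple[int, int]], ...] = (
        ((4, 9), (18, 25), (16, 23)),
    )
    n_streamlines_per_target: int | None = None  # None: auto (see generate_cohort)
    column_multiplicity: int = 6  # auto streamlines per exit column
    buffer_fraction: float = 0.30  # unplanted nucleus share absorbing pass-through
    buffer_pole: tuple[float, float, float] = (0.0, -1.0, 0.0)
    step_mm: float = 0.5
    jitter_sd: float = 0.5
    spurious_fraction: float = 0.1
    spurious_mode: str = "mixed"  # "mixed" | "roa" | "mismatch"
    n_subjects: int = 5
    subject_affine_sd: float = 0.5  # mm translation scale; rotations ~0.02 rad
    subject_rotation_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise PhantomSpecError("n_subjects must be >= 1")
        if self.n_streamlines_per_target is not None and self.n_streamlines_per_target < 1:
            raise PhantomSpecError("n_streamlines_per_target must be >= 1 or None")
        if not (0.0 <= self.spurious_fraction < 1.0):
            raise PhantomSpecError("spurious_fraction must be in [0, 1)")
        if self.spurious_mode not in ("mixed", "roa", "mismatch"):
            raise PhantomSpecError(f"unknown spurious_mode {self.spurious_mode!r}")
        if not self.targets:
            object.__setattr__(self, "targets", _default_targets())

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] *= self.voxel_size_mm
        aff[:3, 3] = self.origin_mm
        return aff

    def grid(self) -> VoxelGrid:
        return VoxelGrid(self.grid_shape, self.affine)


def _default_targets() -> tuple[TargetPhantomSpec, ...]:
    """Default 4-target layout mirroring the hypothesis-driven design.

    The interposed territory is ~20% of the nucleus (dorsomedial pole), the
    cortical territory 30% (lateral pole) and the olivary territory the
    remaining 20% (ventral pole); together with the 30% unplanted anterior
    buffer cap they tile the nucleus. The dentate target is diffuse: its
    convergent bundle seeds every nucleus voxel and funnels into the buffer.
    """
    return (
        TargetPhantomSpec("interposed", (10.0, 30.0, 11.0), (3.0, 3.0, 3.0),
                          fraction=0.20, pole=(-0.5, 0.6, 0.62),
                          exit_axis=1, exit_sign=1),
        TargetPhantomSpec("cortex", (32.0, 20.0, 30.0), (4.0, 4.0, 4.0),
                          fraction=0.30, pole=(1.0, 0.0, 0.3),
                          exit_axis=0, exit_sign=1),
        TargetPhantomSpec("olive", (20.0, 20.0, 7.0), (3.0, 3.0, 4.0),
                          fraction=0.20, pole=(0.0, 0.0, -1.0),
                          exit_axis=2, exit_sign=-1),
        TargetPhantomSpec("dentate", (20.0, 8.0, 18.0), (3.0, 2.5, 3.0),
                          fraction=None, exit_axis=1, exit_sign=-1),
    )


@dataclass
class SyntheticSubject:
    id: str
    streamlines: StreamlineSet
    nucleus_mask: VolumeImage
    target_masks: dict[str, VolumeImage]
    roa_masks: list[VolumeImage]
    to_common: np.ndarray  # 4x4: subject world mm -> common world mm
    ground_truth: VolumeImage  # planted labels over the nucleus (subject grid)
    label_names: dict[int, str]  # ground-truth code -> target name
    streamline_tags: list[str]  # target name, "spurious:roa" or "spurious:mismatch"


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    d = sum(((idx[a] - center[a]) / radii[a]) ** 2 for a in range(3))
    return d <= 1.0


def _partition_nucleus(spec: PhantomSpec, nucleus: np.ndarray):
    """Carve planted territories: greedy pole-directed quantile split.

    An unplanted buffer cap (``buffer_fraction`` of the nucleus along
    ``buffer_pole``) is carved first and keeps label 0: it is the region that
    absorbs the dense pass-through funnel of the diffuse target's bundle.
    Non-diffuse targets are then processed in list order; each takes its
    highest-scoring unassigned voxels along its pole direction, the last one
    absorbs the remainder. Every carve is a halfspace cut of a convex set, so
    all territories are convex. Returns (labels array, code->name map).
    """
    vox = np.argwhere(nucleus)
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    names: dict[int, str] = {}
    compartmental = [t for t in spec.targets if t.fraction is not None]
    if not compartmental:
        return labels, names
    total_frac = sum(t.fraction for t in compartmental) + spec.buffer_fraction
    if not np.isclose(total_frac, 1.0):
        raise PhantomSpecError(
            f"compartment + buffer fractions must sum to 1, got {total_frac}")
    center = np.asarray(spec.nucleus_center)
    unassigned = np.ones(len(vox), dtype=bool)

    def carve(pool: np.ndarray, pole, n_take: int) -> np.ndarray:
        score = (vox[pool] - center) @ np.asarray(pole, dtype=float)
        order = np.lexsort((np.arange(len(pool)), -score))  # stable tie-break
        return pool[order[:n_take]]

    if spec.buffer_fraction > 0:
        take = carve(np.flatnonzero(unassigned), spec.buffer_pole,
                     int(round(spec.buffer_fraction * len(vox))))
        unassigned[take] = False
    code = 0
    for k, t in enumerate(compartmental):
        code += 1
        names[code] = t.name
        pool = np.flatnonzero(unassigned)
        if k == len(compartmental) - 1:
            take = pool
        else:
            take = carve(pool, t.pole, int(round(t.fraction * len(vox))))
        if take.size == 0:
            raise PhantomSpecError(f"planted territory for {t.name!r} is empty")
        labels[tuple(vox[take].T)] = code
        unassigned[take] = False
    return labels, names


def _interpolate(points: list[np.ndarray], step_mm: float) -> np.ndarray:
    """Piecewise-linear waypoint chain densified to <= step_mm spacing."""
    out = [np.asarray(points[0], dtype=float)]
    for a, b in zip(points[:-1], points[1:]):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        n = max(1, int(np.ceil(np.linalg.norm(b - a) / step_mm)))
        for i in range(1, n + 1):
            out.append(a + (b - a) * (i / n))
    return np.asarray(out)


def _rigid_perturbation(rng: np.random.Generator, rot_sd: float, trans_sd: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.normal(0.0, rot_sd)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    P = np.eye(4)
    P[:3, :3] = R
    P[:3, 3] = rng.normal(0.0, trans_sd, size=3)
    return P


def generate_cohort(spec: PhantomSpec) -> list[SyntheticSubject]:
    """Deterministically generate ``spec.n_subjects`` phantom subjects."""
    rng = np.random.default_rng(spec.seed)
    grid0 = spec.grid()
    nucleus = _ellipsoid_mask(spec.grid_shape, spec.nucleus_center, spec.nucleus_radii)
    target_arrays: dict[str, np.ndarray] = {}
    for t in spec.targets:
        m = _ellipsoid_mask(spec.grid_shape, t.center, t.radii)
        if (m & nucleus).any():
            raise PhantomSpecError(f"target mask {t.name!r} overlaps the nucleus")
        target_arrays[t.name] = m
    roa_arrays = []
    for (x0, x1), (y0, y1), (z0, z1) in spec.roa_boxes:
        box = np.zeros(spec.grid_shape, dtype=bool)
        box[x0:x1, y0:y1, z0:z1] = True
        roa_arrays.append(box)
    labels, names = _partition_nucleus(spec, nucleus)
    nucleus_vox = np.argwhere(nucleus)
    territory_vox = {name: np.argwhere(labels == code) for code, name in names.items()}
    target_vox = {t.name: np.argwhere(target_arrays[t.name]) for t in spec.targets}
    roa_vox = [np.argwhere(r) for r in roa_arrays]

    def seed_voxels_for(tname: str) -> np.ndarray:
        return territory_vox.get(tname, nucleus_vox)  # diffuse -> whole nucleus

    # Exit columns: group a territory's voxels by the two coordinates
    # perpendicular to the target's exit axis. Convexity of every territory
    # (ellipsoid cut by halfspaces) makes each column a contiguous run, and
    # the pole/exit-direction compatibility keeps a column inside its own
    # territory all the way to the nucleus surface.
    columns_by_target: dict[str, list[tuple[np.ndarray, float]]] = {}
    for t in spec.targets:
        if t.fraction is None:
            continue  # diffuse targets seed per-voxel, not per-column
        vox = seed_voxels_for(t.name)
        a, sign = t.exit_axis, t.exit_sign
        perp = [ax for ax in range(3) if ax != a]
        cols: dict[tuple[int, int], list[int]] = {}
        for v in vox:
            cols.setdefault((int(v[perp[0]]), int(v[perp[1]])), []).append(int(v[a]))
        nuc_lo, nuc_hi = nucleus_vox[:, a].min(), nucleus_vox[:, a].max()
        exit_coord = float(nuc_hi + 2 if sign > 0 else nuc_lo - 2)
        col_list = []
        for (p0, p1), coords in sorted(cols.items()):
            entry = min(coords) if sign > 0 else max(coords)
            start = np.zeros(3)
            start[perp[0]], start[perp[1]], start[a] = p0, p1, entry
            col_list.append((start, exit_coord))
        columns_by_target[t.name] = col_list

    n_targets = len(spec.targets)

    def n_for(t: TargetPhantomSpec) -> int:
        if spec.n_streamlines_per_target is not None:
            return spec.n_streamlines_per_target
        if t.fraction is None:
            return len(nucleus_vox)  # diffuse: one per nucleus voxel
        return spec.column_multiplicity * len(columns_by_target[t.name])

    n_clean_total = sum(n_for(t) for t in spec.targets)
    n_spurious = int(round(spec.spurious_fraction * n_clean_total))
    subjects = []
    for s in range(spec.n_subjects):
        P = _rigid_perturbation(rng, spec.subject_rotation_sd, spec.subject_affine_sd)
        sl_list: list[np.ndarray] = []
        tags: list[str] = []

        def draw(start_pool: np.ndarray, end_pool: np.ndarray,
                 via: np.ndarray | None = None) -> np.ndarray:
            start = voxel_to_world(start_pool[rng.integers(len(start_pool))], grid0)[0]
            end = voxel_to_world(end_pool[rng.integers(len(end_pool))], grid0)[0]
            waypoints = [start, end] if via is None else [start, via, end]
            pts = _interpolate(waypoints, spec.step_mm)
            if spec.jitter_sd > 0 and len(pts) > 2:
                jit = rng.normal(0.0, spec.jitter_sd, size=(len(pts) - 2, 3))
                if via is not None:
                    # the via waypoint stays exact (it pins an ROA crossing)
                    via_idx = int(np.argmin(np.linalg.norm(pts - via, axis=1)))
                    if 1 <= via_idx <= len(pts) - 2:
                        jit[via_idx - 1] = 0.0
                pts[1:-1] += jit
            return pts

        for t in spec.targets:
            n_t = n_for(t)
            tv = target_vox[t.name]
            if t.fraction is None:
                # diffuse: straight convergent rays from every nucleus voxel
                # (shuffled, cycling) to the target; their pass-through piles
                # up in the unplanted buffer cap near the exit face
                pool = nucleus_vox
                order = rng.permutation(len(pool))
                for i in range(n_t):
                    start = voxel_to_world(pool[order[i % len(pool)]], grid0)[0]
                    end = voxel_to_world(tv[rng.integers(len(tv))], grid0)[0]
                    pts = _interpolate([start, end], spec.step_mm)
                    if spec.jitter_sd > 0 and len(pts) > 2:
                        pts[1:-1] += rng.normal(0.0, spec.jitter_sd,
                                                size=(len(pts) - 2, 3))
                    sl_list.append(pts)
                    tags.append(t.name)
                continue
            cols = columns_by_target[t.name]
            if not cols:
                raise PhantomSpecError(f"no seed voxels for target {t.name!r}")
            # round-robin over a shuffled column order: per-column counts
            # differ by at most 1, and are exactly equal at the default
            # (column_multiplicity per column), making in-ROI density constant
            order = rng.permutation(len(cols))
            for i in range(n_t):
                start_vox, exit_coord = cols[order[i % len(cols)]]
                start = voxel_to_world(start_vox, grid0)[0]
                mid_vox = start_vox.copy()
                mid_vox[t.exit_axis] = exit_coord
                mid = voxel_to_world(mid_vox, grid0)[0]
                end = voxel_to_world(tv[rng.integers(len(tv))], grid0)[0]
                pts = _interpolate([start, mid, end], spec.step_mm)
                if spec.jitter_sd > 0 and len(pts) > 2:
                    pts[1:-1] += rng.normal(0.0, spec.jitter_sd, size=(len(pts) - 2, 3))
                sl_list.append(pts)
                tags.append(t.name)
        for i in range(n_spurious):
            if spec.spurious_mode == "roa" or (spec.spurious_mode == "mixed" and i % 2 == 0):
                src = spec.targets[rng.integers(n_targets)]
                dst = spec.targets[rng.integers(n_targets)]
                rv = roa_vox[rng.integers(len(roa_vox))] if roa_vox else None
                if rv is None:
                    raise PhantomSpecError("ROA-routed spurious streamlines need an ROA box")
                via = voxel_to_world(rv[rng.integers(len(rv))], grid0)[0]
                sl_list.append(draw(seed_voxels_for(src.name), target_vox[dst.name], via=via))
                tags.append("spurious:roa")
            else:
                src_i = int(rng.integers(n_targets))
                dst_i = int((src_i + 1 + rng.integers(n_targets - 1)) % n_targets)
                src, dst = spec.targets[src_i], spec.targets[dst_i]
                sl_list.append(draw(seed_voxels_for(src.name), target_vox[dst.name]))
                tags.append("spurious:mismatch")

        # map generated (common-space) geometry into the perturbed subject space
        R, tr = P[:3, :3], P[:3, 3]
        sl_subj = [pts @ R.T + tr for pts in sl_list]
        affine_s = P @ spec.affine
        grid_s = VoxelGrid(spec.grid_shape, affine_s)
        subjects.append(SyntheticSubject(
            id=f"sub-{s:02d}",
            streamlines=StreamlineSet(sl_subj, provenance=f"phantom seed={spec.seed} subject={s}"),
            nucleus_mask=VolumeImage(grid_s, nucleus.astype(np.float64)),
            target_masks={n: VolumeImage(grid_s, a.astype(np.float64))
                          for n, a in target_arrays.items()},
            roa_masks=[VolumeImage(grid_s, a.astype(np.float64)) for a in roa_arrays],
            to_common=np.linalg.inv(P),
            ground_truth=VolumeImage(grid_s, labels.astype(np.float64)),
            label_names=dict(names),
            streamline_tags=tags,
        ))
    return subjects


def planted_label_volume(subject: SyntheticSubject) -> VolumeImage:
    """The planted ground-truth labels, restricted to the nucleus mask."""
    vals = subject.ground_truth.values * subject.nucleus_mask.as_bool()
    return VolumeImage(subject.ground_truth.grid, vals)


# ---------------------------------------------------------------------------
# Persistence: one directory per subject, NIfTI masks + TCK tracks + JSON


def save_cohort(subjects: list[SyntheticSubject], out_dir, spec: PhantomSpec | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if spec is not None:
        d = asdict(spec)
        (out_dir / "spec.json").write_text(json.dumps(d, indent=2, sort_keys=True))
    for sub in subjects:
        sd = out_dir / sub.id
        sd.mkdir(exist_ok=True)
        write_volume(sub.nucleus_mask, sd / "nucleus.nii.gz")
        for name, m in sub.target_masks.items():
            write_volume(m, sd / f"target_{name}.nii.gz")
        for i, m in enumerate(sub.roa_masks):
            write_volume(m, sd / f"roa_{i}.nii.gz")
        write_volume(sub.ground_truth, sd / "ground_truth.nii.gz")
        write_streamlines(sub.streamlines, sd / "tracks.tck")
        meta = {
            "id": sub.id,
            "to_common": np.asarray(sub.to_common).tolist(),
            "label_names": {str(k): v for k, v in sub.label_names.items()},
            "streamline_tags": sub.streamline_tags,
        }
        (sd / "subject.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return out_dir


def load_cohort(cohort_dir) -> list[SyntheticSubject]:
    cohort_dir = Path(cohort_dir)
    subjects = []
    for sd in sorted(p for p in cohort_dir.iterdir() if p.is_dir()):
        meta = json.loads((sd / "subject.json").read_text())
        target_masks = {p.name[len("target_"):-len(".nii.gz")]: read_volume(p)
                        for p in sorted(sd.glob("target_*.nii.gz"))}
        roa_masks = [read_volume(p) for p in sorted(sd.glob("roa_*.nii.gz"))]
        subjects.append(SyntheticSubject(
            id=meta["id"],
            streamlines=read_streamlines(sd / "tracks.tck"),
            nucleus_mask=read_volume(sd / "nucleus.nii.gz"),
            target_masks=target_masks,
            roa_masks=roa_masks,
            to_common=np.asarray(meta["to_common"], dtype=float),
            ground_truth=read_volume(sd / "ground_truth.nii.gz"),
            label_names={int(k): v for k, v in meta["label_names"].items()},
            streamline_tags=list(meta["streamline_tags"]),
        ))
    return subjects
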