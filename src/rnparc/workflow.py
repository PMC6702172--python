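"""End-to-end orchestration: simulate a cohort, parcellate every subject,
build group maps and laterality statistics, and emit a reproducible report.

A cohort directory holds one sub-directory per hemisphere (``left/``,
``right/``) each with one directory per subject (NIfTI masks + TCK tracks +
JSON sidecars); a directory without hemisphere sub-directories is treated as
a single unilateral cohort (no laterality statistics). Every run logs its
thresholds, tie counts and seed, and the report is byte-reproducible from the
persisted config + seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import group as grp
from . import parcellation as parc
from . import phantom
from .imaging import VolumeImage, VoxelGrid, write_volume

logger = logging.getLogger(__name__)

MERGED_GROUPING = dict(parc.DEFAULT_GROUPING)
MERGED_ORDER = list(parc.DEFAULT_MERGED_ORDER)


@dataclass
class PipelineConfig:
    target_order: list[str] = field(
        default_factory=lambda: ["cortex", "olive", "interposed", "dentate"])
    grouping: dict[str, str] = field(default_factory=lambda: dict(MERGED_GROUPING))
    merged_order: list[str] = field(default_factory=lambda: list(MERGED_ORDER))
    cluster_threshold_fraction: float = 0.25
    mpm_thresholds: list[int] = field(default_factory=lambda: [25, 50, 75])
    n_perm: int = 50_000
    alpha: float = 0.05
    seed: int = 0
    supersample: int = 1
    n_subjects: int = 5
    jitter_sd: float = 0.5
    spurious_fraction: float = 0.1

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def run_simulate(config: PipelineConfig, out_dir, hemispheres: bool = True,
                 force: bool = False) -> Path:
    """Generate and persist a seeded phantom cohort (optionally bilateral).

    Left and right hemispheres are independent cohorts sharing one spec but
    distinct sub-seeds derived from ``config.seed``; subjects are paired by
    index.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} exists and is not empty (use force)")
    out_dir.mkdir(parents=True, exist_ok=True)
    sides = ("left", "right") if hemispheres else ("",)
    for i, side in enumerate(sides):
        spec = phantom.PhantomSpec(
            n_subjects=config.n_subjects, jitter_sd=config.jitter_sd,
            spurious_fraction=config.spurious_fraction,
            seed=int(config.seed) * 2 + i,
        )
        subjects = phantom.generate_cohort(spec)
        phantom.save_cohort(subjects, out_dir / side if side else out_dir, spec)
        logger.info("simulated %s cohort: %d subjects, seed %d",
                    side or "unilateral", spec.n_subjects, spec.seed)
    config.to_yaml(out_dir / "config.yaml")
    return out_dir


def _target_specs(subject: phantom.SyntheticSubject,
                  order: list[str]) -> list[parc.TargetSpec]:
    return [parc.TargetSpec(name, [subject.target_masks[name]])
            for name in order if name in subject.target_masks]


def parcellate_cohort(subjects: list[phantom.SyntheticSubject],
                      config: PipelineConfig) -> list[parc.SubjectParcellation]:
    out = []
    for sub in subjects:
        t0 = time.perf_counter()
        p = parc.parcellate_subject(
            sub.streamlines, sub.nucleus_mask,
            _target_specs(sub, config.target_order), sub.roa_masks,
            subject_id=sub.id,
            cluster_threshold_fraction=config.cluster_threshold_fraction,
            grouping=config.grouping, merged_order=config.merged_order,
        )
        logger.info("parcellated %s in %.2fs (ties=%d, dropped=%s)",
                    sub.id, time.perf_counter() - t0, p.tie_count, p.dropped_targets)
        out.append(p)
    return out


def _sdi_rows(p: parc.SubjectParcellation, seed_mask: VolumeImage) -> list[dict]:
    roi_vox = int(seed_mask.as_bool().sum())
    rows = []
    for name, code in p.label_codes.items():
        nvox = int((p.label_map.values == code).sum())
        rows.append({"subject": p.subject_id, "cluster": name, "level": "first",
                     "voxels": nvox, "sdi_pct": grp.compute_sdi(nvox, roi_vox)})
    for name, code in p.merged_codes.items():
        nvox = int((p.merged_label_map.values == code).sum())
        rows.append({"subject": p.subject_id, "cluster": name, "level": "merged",
                     "voxels": nvox, "sdi_pct": grp.compute_sdi(nvox, roi_vox)})
    return rows


def analyze_cohort(subjects: list[phantom.SyntheticSubject],
                   parcs: list[parc.SubjectParcellation],
                   config: PipelineConfig, common: VoxelGrid):
    """Common-space group maps + per-subject SDI table for one hemisphere."""
    sdi_rows: list[dict] = []
    labels_common: list[VolumeImage] = []
    merged_common: list[VolumeImage] = []
    for sub, p in zip(subjects, parcs):
        sdi_rows.extend(_sdi_rows(p, sub.nucleus_mask))
        labels_common.append(grp.resample_labels_to_common(p.label_map, sub.to_common, common))
        merged_common.append(grp.resample_labels_to_common(p.merged_label_map, sub.to_common, common))
    codes = parcs[0].label_codes
    merged_codes = parcs[0].merged_codes
    thresholds = tuple(config.mpm_thresholds)
    gmaps = grp.build_group_maps(labels_common, codes, thresholds)
    gmerged = grp.build_group_maps(merged_common, merged_codes, thresholds)
    stats_rows = []
    for (name, pct), mask in {**gmaps.masks_at, **gmerged.masks_at}.items():
        st = grp.cluster_volume_cog(mask)
        stats_rows.append({
            "cluster": name, "mpm_threshold_pct": pct,
            "volume_vox": st.volume_vox, "volume_mm3": st.volume_mm3,
            "cog_voxel": list(st.cog_voxel) if st.cog_voxel else None,
            "cog_world_mm": list(st.cog_world) if st.cog_world else None,
        })
    return {
        "sdi": pd.DataFrame(sdi_rows),
        "group_first": gmaps,
        "group_merged": gmerged,
        "cluster_stats": pd.DataFrame(stats_rows),
        "overlap_report": grp.overlap_consistency(gmaps),
        "tie_counts": {p.subject_id: p.tie_count for p in parcs},
    }


def laterality_analysis(left_sdi: pd.DataFrame, right_sdi: pd.DataFrame,
                        config: PipelineConfig, voxel_volume: float = 1.0):
    """LI per subject/cluster from hemispheric volumes + t-max permutation test."""
    def vol_matrix(df: pd.DataFrame):
        sub = df[df.level == "first"].pivot(index="subject", columns="cluster",
                                            values="voxels")
        return sub.sort_index(), list(sub.columns)
    lv, names = vol_matrix(left_sdi)
    rv, names_r = vol_matrix(right_sdi)
    if names != names_r:
        raise ValueError("left/right cluster sets differ")
    left = lv.to_numpy(dtype=float) * voxel_volume
    right = rv.to_numpy(dtype=float) * voxel_volume
    return grp.permutation_test_tmax(
        left, right, n_perm=config.n_perm, alpha=config.alpha,
        seed=config.seed, cluster_names=names)


def _qc_figure(gmaps: grp.GroupMaps, path: Path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(gmaps.overlap_pct)
    fig, axes = plt.subplots(1, len(names), figsize=(3 * len(names), 3))
    axes = np.atleast_1d(axes)
    for ax, name in zip(axes, names):
        vol = gmaps.overlap_pct[name].values
        z = int(np.argmax(vol.sum(axis=(0, 1))))
        ax.imshow(vol[:, :, z].T, origin="lower", cmap="viridis", vmin=0, vmax=100)
        ax.set_title(f"{name} (z={z})")
        ax.axis("off")
    fig.suptitle("cluster MPM overlap (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=90)
    plt.close(fig)


def run_end_to_end(cohort_dir, out_dir, config: PipelineConfig | None = None,
                   qc_figures: bool = True) -> dict:
    """Parcellate every subject, run group + laterality analysis, write the
    report bundle (JSON + CSV + config + QC figure)."""
    cohort_dir = Path(cohort_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config is None:
        cfg_path = cohort_dir / "config.yaml"
        config = PipelineConfig.from_yaml(cfg_path) if cfg_path.exists() else PipelineConfig()
    sides = [s for s in ("left", "right") if (cohort_dir / s).is_dir()]
    unilateral = not sides
    if unilateral:
        sides = [""]
    report: dict = {"config": dataclasses.asdict(config), "hemispheres": {}}
    per_side: dict[str, dict] = {}
    for side in sides:
        subjects = phantom.load_cohort(cohort_dir / side if side else cohort_dir)
        # common grid: the canonical unperturbed phantom grid (subject affines
        # are rigid perturbations of it); fall back to the first subject's grid
        if subjects[0].nucleus_mask.grid.shape == phantom.PhantomSpec().grid_shape:
            common = VoxelGrid(subjects[0].nucleus_mask.grid.shape, phantom.PhantomSpec().affine)
        else:
            common = subjects[0].nucleus_mask.grid
        parcs = parcellate_cohort(subjects, config)
        res = analyze_cohort(subjects, parcs, config, common)
        per_side[side] = res
        tag = side or "cohort"
        res["sdi"].to_csv(out_dir / f"sdi_{tag}.csv", index=False)
        res["cluster_stats"].to_csv(out_dir / f"cluster_stats_{tag}.csv", index=False)
        for (name, pct), mask in res["group_first"].masks_at.items():
            write_volume(mask, out_dir / f"mpm_{tag}_{name}_{pct}.nii.gz")
        report["hemispheres"][tag] = {
            "n_subjects": len(subjects),
            "tie_counts": res["tie_counts"],
            "overlap_report": res["overlap_report"],
            "sdi_mean": {f"{lvl}:{cl}": round(float(v), 6)
                         for (lvl, cl), v in res["sdi"]
                         .groupby(["level", "cluster"])["sdi_pct"].mean().items()},
        }
        if qc_figures:
            _qc_figure(res["group_first"], out_dir / f"qc_mpm_{tag}.png")
    if not unilateral:
        voxvol = phantom.PhantomSpec().grid().voxel_volume
        perm = laterality_analysis(per_side["left"]["sdi"], per_side["right"]["sdi"],
                                   config, voxel_volume=voxvol)
        li_df = pd.DataFrame(perm.li_per_subject, columns=perm.cluster_names)
        li_df.to_csv(out_dir / "li_per_subject.csv", index=False)
        report["laterality"] = {
            "clusters": perm.cluster_names,
            "t_obs": [round(float(t), 10) for t in perm.t_obs],
            "p_corrected": [round(float(p), 10) for p in perm.p_corrected],
            "p_uncorrected": [round(float(p), 10) for p in perm.p_uncorrected],
            "n_perm": perm.n_perm, "alpha": perm.alpha, "seed": perm.seed,
        }
    config.to_yaml(out_dir / "config.yaml")
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("report written to %s", out_dir / "report.json")
    return report
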