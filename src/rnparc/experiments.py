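"""Reproducible validation experiments over the whole pipeline.

Each function runs a self-contained, seeded experiment at desk scale and
returns plain numbers: geometric agreement of the rasterizer with brute-force
oracles, recovery of the planted phantom topography, exactness of the
index arithmetic, nestedness of group maps, and frequentist calibration of
the t-max permutation test. The analysis drivers, the test suite and the
acceptance script all call these.
"""

from __future__ import annotations

import json
import numpy as np

from . import oracles
from .density import voxel_traversal
from .group import (build_group_maps, compute_sdi, overlap_consistency,
                    permutation_test_tmax, resample_labels_to_common)
from .imaging import VoxelGrid, voxel_to_world
from .parcellation import SubjectParcellation, TargetSpec, parcellate_subject
from .phantom import PhantomSpec, SyntheticSubject, generate_cohort

TARGET_ORDER = ("cortex", "olive", "interposed", "dentate")


# ---------------------------------------------------------------------------
# Rasterizer vs oracles


def _random_grid(rng: np.random.Generator) -> VoxelGrid:
    shape = tuple(int(s) for s in rng.integers(12, 30, size=3))
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = rng.uniform(0, 2 * np.pi)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
    aff = np.eye(4)
    aff[:3, :3] = R @ np.diag(rng.uniform(0.6, 2.2, size=3))
    aff[:3, 3] = rng.uniform(-10, 10, size=3)
    return VoxelGrid(shape, aff)


def traversal_validation(seed: int, n_polylines: int = 100, n_grids: int = 5,
                         sampling_step: float = 0.01) -> dict:
    """Compare voxel_traversal with the exact slab oracle and the dense
    point-sampling oracle on random polylines over random grids.

    Returns per-polyline exact-match and sampling-subset percentages, and the
    largest chord among cells the sampling oracle missed (all of which must
    be shorter than the sampling step for the two oracles to be consistent).
    """
    rng = np.random.default_rng(seed)
    grids = [_random_grid(rng) for _ in range(n_grids)]
    exact_match = subset_ok = 0
    n_cells = 0
    max_missed_chord = 0.0
    for i in range(n_polylines):
        grid = grids[i % n_grids]
        cont = rng.uniform(-1.0, np.asarray(grid.shape) - 0.5, size=(4, 3))
        pl = voxel_to_world(cont, grid)
        trav = set(voxel_traversal(pl, grid))
        exact = oracles.polyline_slab_cells(pl, grid)
        sampled = oracles.polyline_sampling_cells(pl, grid, step=sampling_step)
        n_cells += len(exact)
        exact_match += trav == exact
        subset_ok += sampled <= trav
        for cell in trav - sampled:
            max_missed_chord = max(max_missed_chord,
                                   oracles.polyline_chord(cell, pl, grid))
    return {
        "n_polylines": n_polylines,
        "n_cells": n_cells,
        "exact_match_pct": 100.0 * exact_match / n_polylines,
        "sampling_subset_pct": 100.0 * subset_ok / n_polylines,
        "max_chord_missed_by_sampling_vox": max_missed_chord,
        "sampling_step_vox": sampling_step,
    }


# ---------------------------------------------------------------------------
# Phantom recovery


def parcellate_phantom(sub: SyntheticSubject, **kw) -> SubjectParcellation:
    targets = [TargetSpec(n, [sub.target_masks[n]]) for n in TARGET_ORDER]
    return parcellate_subject(sub.streamlines, sub.nucleus_mask, targets,
                              sub.roa_masks, subject_id=sub.id, **kw)


def recovery_fraction(sub: SyntheticSubject, parc: SubjectParcellation) -> float:
    """Voxel agreement with planted truth over compartmentalized voxels."""
    gt = sub.ground_truth.values
    agree = tot = 0
    for code, name in sub.label_names.items():
        m = gt == code
        tot += int(m.sum())
        agree += int((parc.label_map.values[m] == parc.label_codes[name]).sum())
    return agree / tot


def recovery_experiment(seed: int, n_subjects: int = 5):
    """Parcellate the default noisy cohort and a noiseless subject.

    Returns (summary dict, cohort, parcellations) so downstream group-level
    checks can reuse the computed parcellations.
    """
    noiseless = generate_cohort(PhantomSpec(
        n_subjects=1, jitter_sd=0.0, spurious_fraction=0.0,
        subject_affine_sd=0.0, subject_rotation_sd=0.0, seed=seed))[0]
    r0 = recovery_fraction(noiseless, parcellate_phantom(noiseless))
    cohort = generate_cohort(PhantomSpec(n_subjects=n_subjects, seed=seed))
    parcs = [parcellate_phantom(sub) for sub in cohort]
    rates = [recovery_fraction(s, p) for s, p in zip(cohort, parcs)]
    summary = {
        "n_subjects": n_subjects,
        "noiseless_agreement_pct": 100.0 * r0,
        "default_agreement_pct_per_subject": [100.0 * r for r in rates],
        "default_agreement_pct_mean": 100.0 * float(np.mean(rates)),
        "default_agreement_pct_min": 100.0 * float(np.min(rates)),
    }
    return summary, cohort, parcs


def sdi_summary(cohort, parcs) -> dict:
    """Per-subject SDI table checks: pRN additivity and total coverage."""
    max_add_err = 0.0
    max_sum = 0.0
    mrn = []
    for sub, p in zip(cohort, parcs):
        roi = int(sub.nucleus_mask.as_bool().sum())
        sdi = {n: compute_sdi(int((p.label_map.values == c).sum()), roi)
               for n, c in p.label_codes.items()}
        prn = compute_sdi(int((p.merged_label_map.values ==
                               p.merged_codes["pRN"]).sum()), roi)
        mrn.append(compute_sdi(int((p.merged_label_map.values ==
                                    p.merged_codes["mRN"]).sum()), roi))
        max_add_err = max(max_add_err, abs(prn - (sdi["cortex"] + sdi["olive"])))
        max_sum = max(max_sum, sum(sdi.values()))
    return {
        "sdi_additivity_max_abs_err": max_add_err,
        "sdi_sum_max_pct": max_sum,
        "mrn_sdi_mean_pct": float(np.mean(mrn)),
    }


def mpm_summary(cohort, parcs, thresholds=(25, 50, 75)) -> dict:
    """Group maps in common space: nestedness violations and 75% cores."""
    common = PhantomSpec().grid()
    labels = [resample_labels_to_common(p.label_map, s.to_common, common)
              for s, p in zip(cohort, parcs)]
    g = build_group_maps(labels, parcs[0].label_codes, tuple(thresholds))
    violations = 0
    for name in parcs[0].label_codes:
        prev = None
        for pct in sorted(thresholds):
            mask = g.masks_at[(name, pct)].as_bool()
            if prev is not None:
                violations += int((mask & ~prev).sum())
            prev = mask
    rep = overlap_consistency(g)
    compart = [n for n in ("cortex", "olive", "interposed") if n in rep]
    return {
        "nestedness_violations": violations,
        "clusters_with_75pct_core_pct": 100.0 * np.mean(
            [rep[n]["has_core"] for n in compart]),
    }


# ---------------------------------------------------------------------------
# Permutation-test calibration


def fwer_calibration(seed: int, n_datasets: int = 1000, n_subjects: int = 20,
                     n_clusters: int = 4, n_perm: int = 2000,
                     alpha: float = 0.05, effect: float = 0.0) -> dict:
    """Monte-Carlo calibration of the t-max test on simulated paired data.

    Each dataset draws standard-normal per-subject differences (plus
    ``effect`` on the first cluster) and runs the package's own permutation
    test. With effect 0 the familywise rejection rate estimates the FWER;
    with a planted effect, rejections of the first cluster estimate power.
    """
    rng = np.random.default_rng(seed)
    fw_reject = 0
    first_reject = 0
    for i in range(n_datasets):
        d = rng.normal(size=(n_subjects, n_clusters))
        d[:, 0] += effect
        res = permutation_test_tmax(d, np.zeros_like(d), n_perm=n_perm,
                                    alpha=alpha,
                                    seed=int(rng.integers(2 ** 31)))
        rej = res.p_corrected < alpha
        fw_reject += bool(rej.any())
        first_reject += bool(rej[0])
    return {
        "n_datasets": n_datasets, "n_perm": n_perm, "alpha": alpha,
        "effect": effect,
        "familywise_rejection_pct": 100.0 * fw_reject / n_datasets,
        "first_cluster_rejection_pct": 100.0 * first_reject / n_datasets,
    }


def exhaustive_vs_sampled(seed: int, n_subjects: int = 10, n_clusters: int = 4,
                          n_perm: int = 50_000) -> dict:
    """Sampled t-max p-values against the exact 2^n enumeration."""
    rng = np.random.default_rng(seed)
    left = rng.normal(size=(n_subjects, n_clusters))
    right = rng.normal(size=(n_subjects, n_clusters))
    ex = permutation_test_tmax(left, right, exhaustive=True)
    sa = permutation_test_tmax(left, right, n_perm=n_perm,
                               seed=int(rng.integers(2 ** 31)))
    return {
        "n_subjects": n_subjects, "n_perm": n_perm,
        "p_exhaustive": ex.p_corrected.tolist(),
        "p_sampled": sa.p_corrected.tolist(),
        "max_abs_diff": float(np.abs(ex.p_corrected - sa.p_corrected).max()),
    }


# ---------------------------------------------------------------------------
# End-to-end determinism


def determinism_check(seed: int, tmp_dir, n_subjects: int = 3,
                      n_perm: int = 2000) -> dict:
    """Simulate once, run the full pipeline twice, compare report bytes."""
    from pathlib import Path

    from .workflow import PipelineConfig, run_end_to_end, run_simulate

    tmp_dir = Path(tmp_dir)
    cfg = PipelineConfig(seed=seed, n_subjects=n_subjects, n_perm=n_perm)
    run_simulate(cfg, tmp_dir / "cohort", force=True)
    run_end_to_end(tmp_dir / "cohort", tmp_dir / "r1", cfg, qc_figures=False)
    run_end_to_end(tmp_dir / "cohort", tmp_dir / "r2", cfg, qc_figures=False)
    t1 = (tmp_dir / "r1" / "report.json").read_text()
    t2 = (tmp_dir / "r2" / "report.json").read_text()
    return {
        "identical": t1 == t2,
        "report": json.loads(t1),
        "n_subjects": n_subjects,
    }
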