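"""Shared fixtures: phantom subjects/cohorts and independent geometry oracles."""

from __future__ import annotations

import numpy as np
import pytest

from rnparc.parcellation import TargetSpec, parcellate_subject
from rnparc.phantom import PhantomSpec, generate_cohort

TARGET_ORDER = ("cortex", "olive", "interposed", "dentate")


def parcellate_phantom_subject(sub, **kw):
    targets = [TargetSpec(n, [sub.target_masks[n]]) for n in TARGET_ORDER]
    return parcellate_subject(sub.streamlines, sub.nucleus_mask, targets,
                              sub.roa_masks, subject_id=sub.id, **kw)


def recovery_fraction(sub, parc) -> float:
    """Voxel agreement between winner-takes-all labels and planted truth,
    over the compartmentalized (non-buffer, non-diffuse) nucleus voxels."""
    gt = sub.ground_truth.values
    agree = tot = 0
    for code, name in sub.label_names.items():
        m = gt == code
        tot += int(m.sum())
        agree += int((parc.label_map.values[m] == parc.label_codes[name]).sum())
    return agree / tot


@pytest.fixture(scope="session")
def noiseless_subject():
    spec = PhantomSpec(n_subjects=1, jitter_sd=0.0, spurious_fraction=0.0,
                       subject_affine_sd=0.0, subject_rotation_sd=0.0, seed=3)
    return generate_cohort(spec)[0]


@pytest.fixture(scope="session")
def default_cohort():
    """The canonical noisy study cohort: 5 subjects, 0.5 mm jitter, 10% spurious."""
    return generate_cohort(PhantomSpec(n_subjects=5, seed=7))


@pytest.fixture(scope="session")
def default_parcs(default_cohort):
    return [parcellate_phantom_subject(sub) for sub in default_cohort]


# ---------------------------------------------------------------------------
# Geometry oracles: brute-force references, independent of the event-based
# rasterizer they validate

from rnparc.oracles import (  # noqa: F401  (re-exported for test modules)
    polyline_sampling_cells, polyline_slab_cells, slab_cells, slab_chord,
)


def random_grid(rng: np.random.Generator):
    """A random, mildly anisotropic, rotated grid for traversal tests."""
    from rnparc.imaging import VoxelGrid

    shape = tuple(int(s) for s in rng.integers(12, 30, size=3))
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = rng.uniform(0, 2 * np.pi)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
    aff = np.eye(4)
    aff[:3, :3] = R @ np.diag(rng.uniform(0.6, 2.2, size=3))
    aff[:3, 3] = rng.uniform(-10, 10, size=3)
    return VoxelGrid(shape, aff)


def random_polyline_in(grid, rng: np.random.Generator, n_pts: int = 4) -> np.ndarray:
    from rnparc.imaging import voxel_to_world

    cont = rng.uniform(-1.0, np.asarray(grid.shape) - 0.5, size=(n_pts, 3))
    return voxel_to_world(cont, grid)
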