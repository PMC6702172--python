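"""Deliberately naive brute-force references for validating the fast paths.

These functions trade speed for transparency: per-cell slab clipping over a
segment's full bounding box, and dense point sampling along segments. They
share no code with the production event-based rasterizer in
:mod:`rnparc.density` and exist solely as independent checks.
"""

from __future__ import annotations

import itertools

import numpy as np

from .imaging import VoxelGrid, world_to_voxel


def slab_cells(u0: np.ndarray, u1: np.ndarray) -> set[tuple[int, int, int]]:
    """Exact cells intersected by one segment (shifted voxel coordinates;
    cell i owns [i, i+1)), by Liang-Barsky slab clipping per candidate cell."""
    d = u1 - u0
    lo = np.floor(np.minimum(u0, u1)).astype(int)
    hi = np.floor(np.maximum(u0, u1)).astype(int)
    out = set()
    for c in itertools.product(*(range(lo[a], hi[a] + 1) for a in range(3))):
        t0, t1 = 0.0, 1.0
        ok = True
        for a in range(3):
            if d[a] == 0:
                if not (c[a] <= u0[a] <= c[a] + 1):
                    ok = False
                    break
            else:
                ta = (c[a] - u0[a]) / d[a]
                tb = (c[a] + 1 - u0[a]) / d[a]
                t0 = max(t0, min(ta, tb))
                t1 = min(t1, max(ta, tb))
        if ok and t0 <= t1:
            out.add(c)
    return out


def slab_chord(cell, u0: np.ndarray, u1: np.ndarray) -> float:
    """Chord length (voxel units) of the segment inside one cell; 0 if disjoint."""
    d = u1 - u0
    t0, t1 = 0.0, 1.0
    for a in range(3):
        if d[a] == 0:
            if not (cell[a] <= u0[a] <= cell[a] + 1):
                return 0.0
        else:
            ta = (cell[a] - u0[a]) / d[a]
            tb = (cell[a] + 1 - u0[a]) / d[a]
            t0 = max(t0, min(ta, tb))
            t1 = min(t1, max(ta, tb))
    return max(0.0, t1 - t0) * float(np.linalg.norm(d))


def polyline_slab_cells(polyline: np.ndarray, grid: VoxelGrid) -> set[tuple[int, int, int]]:
    """Exact traversal set of a polyline by the brute-force slab oracle."""
    u = world_to_voxel(np.atleast_2d(polyline), grid) + 0.5
    cells: set[tuple[int, int, int]] = set()
    if len(u) == 1:
        cells.add(tuple(np.floor(u[0]).astype(int)))
    for k in range(len(u) - 1):
        cells |= slab_cells(u[k], u[k + 1])
    nx, ny, nz = grid.shape
    return {c for c in cells if 0 <= c[0] < nx and 0 <= c[1] < ny and 0 <= c[2] < nz}


def polyline_chord(cell, polyline: np.ndarray, grid: VoxelGrid) -> float:
    """Total chord length of a polyline inside one cell (voxel units)."""
    u = world_to_voxel(np.atleast_2d(polyline), grid) + 0.5
    return sum(slab_chord(cell, u[k], u[k + 1]) for k in range(len(u) - 1))


def polyline_sampling_cells(polyline: np.ndarray, grid: VoxelGrid,
                            step: float = 0.01) -> set[tuple[int, int, int]]:
    """Dense point-sampling oracle at ``step`` voxel units along each segment.

    A lower bound on the true traversal: it can miss cells whose chord is
    shorter than the sampling step (corner-cutting segments).
    """
    u = world_to_voxel(np.atleast_2d(polyline), grid) + 0.5
    cells: set[tuple[int, int, int]] = set()
    if len(u) == 1:
        cells.add(tuple(np.floor(u[0]).astype(int)))
    for k in range(len(u) - 1):
        seg = u[k + 1] - u[k]
        n = max(1, int(np.ceil(np.linalg.norm(seg) / step)))
        t = np.linspace(0.0, 1.0, n + 1)[:, None]
        pts = u[k][None] + t * seg[None]
        cells |= set(map(tuple, np.floor(pts).astype(int)))
    nx, ny, nz = grid.shape
    return {c for c in cells if 0 <= c[0] < nx and 0 <= c[1] < ny and 0 <= c[2] < nz}
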