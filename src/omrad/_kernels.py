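"""Numba inner loops for the gray-level texture matrices.

Level arrays are int32 volumes with 0 outside the region and 1..G
inside.  The kernels iterate over a precomputed list of in-region voxel
coordinates, so their cost scales with the region size rather than its
bounding box (margin bands are thin shells in comparatively large
boxes).  Pure-Python brute-force reference implementations used as
oracles live in the test suite, not here.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: The 13 unique 3D directions at Chebyshev distance 1 (half of the 26
#: neighbours; the other half is covered by symmetrization).
GLCM_OFFSETS = np.array(
    [
        (0, 0, 1),
        (0, 1, -1),
        (0, 1, 0),
        (0, 1, 1),
        (1, -1, -1),
        (1, -1, 0),
        (1, -1, 1),
        (1, 0, -1),
        (1, 0, 0),
        (1, 0, 1),
        (1, 1, -1),
        (1, 1, 0),
        (1, 1, 1),
    ],
    dtype=np.int64,
)


@njit(cache=True)
def glcm_counts(levels: np.ndarray, coords: np.ndarray, n_levels: int, offsets: np.ndarray) -> np.ndarray:
    """Symmetrized co-occurrence counts per direction: (13, G, G).

    ``coords`` holds the (x, y, z) indices of every in-region voxel.
    Each ordered pair is visited once from its lower endpoint and
    entered twice (symmetrization).
    """
    nx, ny, nz = levels.shape
    n_dir = offsets.shape[0]
    counts = np.zeros((n_dir, n_levels, n_levels), dtype=np.float64)
    for c in range(coords.shape[0]):
        x, y, z = coords[c, 0], coords[c, 1], coords[c, 2]
        i = levels[x, y, z]
        for d in range(n_dir):
            x2 = x + offsets[d, 0]
            y2 = y + offsets[d, 1]
            z2 = z + offsets[d, 2]
            if x2 < 0 or x2 >= nx or y2 < 0 or y2 >= ny or z2 < 0 or z2 >= nz:
                continue
            j = levels[x2, y2, z2]
            if j == 0:
                continue
            counts[d, i - 1, j - 1] += 1.0
            counts[d, j - 1, i - 1] += 1.0
    return counts


@njit(cache=True)
def discretize_coords(vals: np.ndarray, coords: np.ndarray, bin_width: float) -> tuple[np.ndarray, int]:
    """Min-anchored fixed-bin-width levels at the given coordinates.

    Returns a level volume (0 outside the coordinate set) and the level
    count G = floor((max - min) / bin_width) + 1.
    """
    n = coords.shape[0]
    lo = vals[coords[0, 0], coords[0, 1], coords[0, 2]]
    hi = lo
    for c in range(1, n):
        v = vals[coords[c, 0], coords[c, 1], coords[c, 2]]
        if v < lo:
            lo = v
        elif v > hi:
            hi = v
    n_levels = int(np.floor((hi - lo) / bin_width)) + 1
    levels = np.zeros(vals.shape, dtype=np.int32)
    for c in range(n):
        x, y, z = coords[c, 0], coords[c, 1], coords[c, 2]
        lv = int(np.floor((vals[x, y, z] - lo) / bin_width)) + 1
        if lv > n_levels:
            lv = n_levels
        elif lv < 1:
            lv = 1
        levels[x, y, z] = lv
    return levels, n_levels


@njit(cache=True)
def glcm_counts_multi(
    levels_stack: np.ndarray, coords: np.ndarray, n_levels_max: int, offsets: np.ndarray
) -> np.ndarray:
    """Co-occurrence counts for several level volumes sharing one region.

    ``levels_stack`` is (F, X, Y, Z); the result is (F, 13, G, G) with
    G = n_levels_max (each filter uses its leading sub-block).
    """
    n_f = levels_stack.shape[0]
    nx, ny, nz = levels_stack.shape[1:]
    n_dir = offsets.shape[0]
    counts = np.zeros((n_f, n_dir, n_levels_max, n_levels_max), dtype=np.float64)
    for c in range(coords.shape[0]):
        x, y, z = coords[c, 0], coords[c, 1], coords[c, 2]
        for d in range(n_dir):
            x2 = x + offsets[d, 0]
            y2 = y + offsets[d, 1]
            z2 = z + offsets[d, 2]
            if x2 < 0 or x2 >= nx or y2 < 0 or y2 >= ny or z2 < 0 or z2 >= nz:
                continue
            if levels_stack[0, x2, y2, z2] == 0:  # outside the shared region
                continue
            for f in range(n_f):
                i = levels_stack[f, x, y, z]
                j = levels_stack[f, x2, y2, z2]
                counts[f, d, i - 1, j - 1] += 1.0
                counts[f, d, j - 1, i - 1] += 1.0
    return counts


@njit(cache=True)
def ngtdm_sums(levels: np.ndarray, coords: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """NGTDM accumulators: per level, |i - neighbourhood mean| sum and voxel count.

    A neighbour is valid when it lies inside the region (26-connectivity);
    voxels with no valid neighbour contribute 0 to ``s``.
    """
    nx, ny, nz = levels.shape
    s = np.zeros(n_levels, dtype=np.float64)
    n = np.zeros(n_levels, dtype=np.int64)
    for c in range(coords.shape[0]):
        x, y, z = coords[c, 0], coords[c, 1], coords[c, 2]
        i = levels[x, y, z]
        n[i - 1] += 1
        total = 0.0
        cnt = 0
        for dx in range(-1, 2):
            x2 = x + dx
            if x2 < 0 or x2 >= nx:
                continue
            for dy in range(-1, 2):
                y2 = y + dy
                if y2 < 0 or y2 >= ny:
                    continue
                for dz in range(-1, 2):
                    if dx == 0 and dy == 0 and dz == 0:
                        continue
                    z2 = z + dz
                    if z2 < 0 or z2 >= nz:
                        continue
                    j = levels[x2, y2, z2]
                    if j > 0:
                        total += j
                        cnt += 1
        if cnt > 0:
            s[i - 1] += abs(i - total / cnt)
    return s, n
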