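"""Independent reference implementations used as test oracles.

These deliberately share no code with the package: the peak-detector
reference recomputes segment extrema exhaustively (O(n^2)), segmentation
uses a BFS flood fill, and the rank-sum oracle enumerates every group
assignment.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import numpy as np


def delta_extrema_reference(y, delta):
    """Exhaustive alternating-extrema scan.

    At each step the candidate extremum of the current segment is
    recomputed from scratch; a maximum is confirmed at the first sample
    more than ``delta`` below it (symmetrically for minima).  The scan
    starts looking for a significant rise, and endpoint peaks are
    discarded.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    peaks, minima = [], []
    seg = 0
    looking_max = False
    while seg < n:
        advanced = False
        for j in range(seg, n):
            window = y[seg : j + 1]
            if looking_max:
                m = window.max()
                mi = seg + int(np.argmax(window))
                if y[j] < m - delta:
                    peaks.append(mi)
                    seg = j
                    looking_max = False
                    advanced = True
                    break
            else:
                m = window.min()
                mi = seg + int(np.argmin(window))
                if y[j] > m + delta:
                    minima.append(mi)
                    seg = j
                    looking_max = True
                    advanced = True
                    break
        if not advanced:
            break
    peaks = [p for p in peaks if 0 < p < n - 1]
    return peaks, minima


def flood_fill_components(grid, threshold, min_voxels):
    """BFS flood fill over 26-connected supra-threshold voxels.

    Returns a list of (voxel_count, intensity_sum, weighted_centroid_zyx)
    tuples, one per component with at least ``min_voxels`` voxels.
    """
    grid = np.asarray(grid, dtype=float)
    mask = grid > threshold
    visited = np.zeros_like(mask, dtype=bool)
    neighbors = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    out = []
    nz, ny, nx = grid.shape
    for z0 in range(nz):
        for y0 in range(ny):
            for x0 in range(nx):
                if not mask[z0, y0, x0] or visited[z0, y0, x0]:
                    continue
                queue = deque([(z0, y0, x0)])
                visited[z0, y0, x0] = True
                members = []
                while queue:
                    z, y, x = queue.popleft()
                    members.append((z, y, x))
                    for dz, dy, dx in neighbors:
                        zz, yy, xx = z + dz, y + dy, x + dx
                        if (
                            0 <= zz < nz
                            and 0 <= yy < ny
                            and 0 <= xx < nx
                            and mask[zz, yy, xx]
                            and not visited[zz, yy, xx]
                        ):
                            visited[zz, yy, xx] = True
                            queue.append((zz, yy, xx))
                if len(members) < min_voxels:
                    continue
                vals = np.array([grid[m] for m in members])
                coords = np.array(members, dtype=float)
                centroid = (coords * vals[:, None]).sum(axis=0) / vals.sum()
                out.append((len(members), float(vals.sum()), tuple(centroid)))
    return out


def rank_sum_u(a, b):
    """Mann–Whitney U statistic of sample ``a`` (midranks on ties)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def rank_sum_permutation_p(a, b):
    """Exact two-sided permutation p-value for the Mann–Whitney U."""
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)
    mu = n1 * len(b) / 2.0
    observed = abs(rank_sum_u(a, b) - mu)
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if abs(rank_sum_u(ga, gb) - mu) >= observed - 1e-12:
            count += 1
        total += 1
    return count / total
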