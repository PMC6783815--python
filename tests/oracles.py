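"""Independent brute-force oracles used to validate the package's fast paths.

These deliberately avoid the library calls used by the implementation:
the hull oracle enumerates all facet planes, the component oracle is a
plain breadth-first search, and volumes are checked by Monte-Carlo
hit counting.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations, product

import numpy as np


def brute_hull(points: np.ndarray, tol: float = 1e-9):
    """Convex hull by testing all C(n,3) candidate facet planes.

    Returns (vertex_indices, normals, offsets): the sorted indices of hull
    vertices, and the supporting planes (normal . x <= offset for all
    points) of every one-sided triple.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    scale = np.linalg.norm(pts.max(0) - pts.min(0))
    eps = tol * max(scale, 1.0)
    triples = np.array(list(combinations(range(n), 3)))
    a, b, c = pts[triples[:, 0]], pts[triples[:, 1]], pts[triples[:, 2]]
    normals = np.cross(b - a, c - a)
    norms = np.linalg.norm(normals, axis=1)
    ok = norms > eps
    triples, a, normals, norms = triples[ok], a[ok], normals[ok], norms[ok]
    normals = normals / norms[:, None]
    d = pts @ normals.T - np.einsum("ij,ij->i", normals, a)  # (n, m)
    below = (d <= eps).all(axis=0)
    above = (d >= -eps).all(axis=0)
    onesided = below | above
    # flip planes that are one-sided from above so normals point outward
    normals = np.where(above[:, None] & ~below[:, None], -normals, normals)[onesided]
    offsets = np.einsum("ij,ij->i", normals, a[onesided])
    on_plane = np.abs(d[:, onesided]) <= eps
    vertex_idx = np.flatnonzero(on_plane.any(axis=1))
    return sorted(int(i) for i in vertex_idx), normals, offsets


def points_in_planes(samples: np.ndarray, normals: np.ndarray,
                     offsets: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Boolean mask of samples inside the intersection of half-spaces."""
    return (samples @ normals.T - offsets <= tol).all(axis=1)


_OFFSETS = {
    6: [o for o in product((-1, 0, 1), repeat=3)
        if sum(abs(v) for v in o) == 1],
    18: [o for o in product((-1, 0, 1), repeat=3)
         if 1 <= sum(abs(v) for v in o) <= 2],
    26: [o for o in product((-1, 0, 1), repeat=3)
         if any(o)],
}


def bfs_label(grid: np.ndarray, connectivity: int) -> np.ndarray:
    """Connected-component labels by breadth-first search (0 = background)."""
    grid = np.asarray(grid, dtype=bool)
    labels = np.zeros(grid.shape, dtype=int)
    next_label = 0
    offsets = _OFFSETS[connectivity]
    for start in zip(*np.nonzero(grid)):
        if labels[start]:
            continue
        next_label += 1
        labels[start] = next_label
        queue = deque([start])
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in offsets:
                p = (z + dz, y + dy, x + dx)
                if (0 <= p[0] < grid.shape[0] and 0 <= p[1] < grid.shape[1]
                        and 0 <= p[2] < grid.shape[2]
                        and grid[p] and not labels[p]):
                    labels[p] = next_label
                    queue.append(p)
    return labels


def components_as_sets(labels: np.ndarray) -> set[frozenset]:
    """Label array -> set of components, each a frozenset of voxel indices."""
    out = set()
    for lab in np.unique(labels):
        if lab == 0:
            continue
        out.add(frozenset(zip(*np.nonzero(labels == lab))))
    return out


def monte_carlo_volume(normals: np.ndarray, offsets: np.ndarray,
                       lo: np.ndarray, hi: np.ndarray,
                       n_samples: int, rng: np.random.Generator):
    """Monte-Carlo volume of a half-space intersection inside box [lo, hi].

    Returns (estimate, standard_error).
    """
    lo, hi = np.asarray(lo, float), np.asarray(hi, float)
    box = float(np.prod(hi - lo))
    samples = rng.uniform(lo, hi, size=(n_samples, 3))
    hits = points_in_planes(samples, normals, offsets)
    p = hits.mean()
    return box * p, box * np.sqrt(p * (1 - p) / n_samples)


def pooled_t(a, b):
    """Hand-rolled pooled-variance two-sample t (statistic, df)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return t, df
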