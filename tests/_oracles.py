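"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library paths they check: the hull oracle
enumerates candidate facets exhaustively, the MSD oracle is a naive double
loop, and the particle oracle does its own BFS labelling and explicit
distance computation.
"""

from itertools import combinations

import numpy as np


def hull_volume_bruteforce(points: np.ndarray, eps: float = 1e-12) -> float:
    """Convex-hull volume by exhaustive facet enumeration.

    Every point triple whose plane has all points on one side is a hull
    facet; the volume is the sum of tetrahedra from an interior point
    (the centroid) to each facet. Assumes points in general position.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if n < 4:
        return 0.0
    triples = np.array(list(combinations(range(n), 3)))
    p0 = pts[triples[:, 0]]
    normals = np.cross(pts[triples[:, 1]] - p0, pts[triples[:, 2]] - p0)
    # signed distance of every point from every candidate plane
    d = pts @ normals.T - np.einsum("ij,ij->i", normals, p0)
    scale = np.linalg.norm(normals, axis=1) + eps
    above = (d > eps * scale).any(axis=0)
    below = (d < -eps * scale).any(axis=0)
    facet = ~(above & below) & (scale > 10 * eps)
    c = pts.mean(axis=0)
    vol = 0.0
    for idx in np.flatnonzero(facet):
        i, j, k = triples[idx]
        vol += abs(np.linalg.det(np.stack([pts[i] - c, pts[j] - c,
                                           pts[k] - c]))) / 6.0
    return vol


def msd_double_loop(xyz: np.ndarray) -> np.ndarray:
    """Naive time-averaged MSD over all ordered pairs at each lag."""
    n = xyz.shape[0]
    out = np.zeros(n)
    for m in range(1, n):
        acc, cnt = 0.0, 0
        for i in range(n - m):
            acc += float(np.sum((xyz[i + m] - xyz[i]) ** 2))
            cnt += 1
        out[m] = acc / cnt
    return out


def _bfs_label(mask: np.ndarray) -> list[np.ndarray]:
    """4-connected components of a boolean mask, by explicit BFS."""
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    h, w = mask.shape
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx] or seen[sy, sx]:
                continue
            stack = [(sy, sx)]
            seen[sy, sx] = True
            pix = []
            while stack:
                y, x = stack.pop()
                pix.append((y, x))
                for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ny, nx = y + dy, x + dx
                    if (0 <= ny < h and 0 <= nx < w and mask[ny, nx]
                            and not seen[ny, nx]):
                        seen[ny, nx] = True
                        stack.append((ny, nx))
            comps.append(np.array(pix))
    return comps


def count_particles_bruteforce(candidate: np.ndarray, nucleus: np.ndarray,
                               pixel_size: float, rim: float,
                               area_bounds: tuple[float, float]) -> int:
    """Particle count by explicit labelling and distance computation.

    ``candidate`` is the thresholded structure mask restricted to the
    nucleus; the centroid of each 4-connected component (rounded to the
    nearest pixel, as in the analysis convention) must be farther than
    ``rim`` um from the nearest background pixel, and its area within
    ``area_bounds`` um^2.
    """
    bg = np.argwhere(~nucleus)
    count = 0
    for pix in _bfs_label(candidate & nucleus):
        area = pix.shape[0] * pixel_size**2
        cy, cx = pix.mean(axis=0)
        p = np.array([round(cy), round(cx)])
        dist = np.sqrt(((bg - p) ** 2).sum(axis=1)).min() * pixel_size
        if area_bounds[0] <= area <= area_bounds[1] and dist > rim:
            count += 1
    return count
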