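"""Independent brute-force oracles used only by the tests."""

from itertools import combinations

import numpy as np


def brute_force_delaunay_edges(points: np.ndarray) -> set[tuple[int, int]]:
    """O(n^4) Delaunay edge set by the empty-circumcircle definition.

    A triangle belongs to the Delaunay triangulation iff its circumcircle
    contains no other point; the edge set is the union of such triangles'
    edges.  Assumes points in general position (no 4 cocircular).
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    sq = (pts**2).sum(axis=1)
    edges: set[tuple[int, int]] = set()
    for i, j, k in combinations(range(n), 3):
        a, b, c = pts[i], pts[j], pts[k]
        d = 2.0 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
        if abs(d) < 1e-12:
            continue  # collinear triple: no circumcircle
        ux = (sq[i] * (b[1] - c[1]) + sq[j] * (c[1] - a[1]) + sq[k] * (a[1] - b[1])) / d
        uy = (sq[i] * (c[0] - b[0]) + sq[j] * (a[0] - c[0]) + sq[k] * (b[0] - a[0])) / d
        r2 = (a[0] - ux) ** 2 + (a[1] - uy) ** 2
        others = np.ones(n, dtype=bool)
        others[[i, j, k]] = False
        d2 = (pts[others, 0] - ux) ** 2 + (pts[others, 1] - uy) ** 2
        if np.all(d2 > r2 * (1.0 + 1e-12)):
            edges.update(
                {tuple(sorted(p)) for p in ((i, j), (j, k), (i, k))}
            )
    return edges


def grid_circle_overlap(r1: float, r2: float, d: float, cell: float = 0.05) -> float:
    """Overlap area of two disks by dense grid rasterization."""
    x0, x1 = -r1, max(r1, d + r2)
    y = np.arange(-max(r1, r2), max(r1, r2) + cell, cell)
    x = np.arange(x0, x1 + cell, cell)
    xg, yg = np.meshgrid(x, y)
    in1 = xg**2 + yg**2 <= r1**2
    in2 = (xg - d) ** 2 + yg**2 <= r2**2
    return float((in1 & in2).sum()) * cell**2


def ztp_mean(lam: float) -> float:
    """Closed-form mean of the zero-truncated Poisson: λ / (1 - e^-λ)."""
    return lam / (1.0 - np.exp(-lam))


def circle_lens_area(r: float, d: float) -> float:
    """Closed-form intersection area of two equal circles of radius r."""
    if d >= 2 * r:
        return 0.0
    return 2 * r**2 * np.arccos(d / (2 * r)) - (d / 2) * np.sqrt(4 * r**2 - d**2)
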