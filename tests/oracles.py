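"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (nested loops, exhaustive
enumeration) and shares no code with the library paths it validates.
"""

import itertools

import numpy as np


def block_max_oracle(grid: np.ndarray, factor: int) -> np.ndarray:
    """Triple-loop non-overlapping block max."""
    side = grid.shape[0]
    out = np.zeros((side // factor,) * 3, dtype=grid.dtype)
    for i in range(side // factor):
        for j in range(side // factor):
            for k in range(side // factor):
                out[i, j, k] = grid[
                    i * factor : (i + 1) * factor,
                    j * factor : (j + 1) * factor,
                    k * factor : (k + 1) * factor,
                ].max()
    return out


def halfspace_vertex_oracle(
    normals: np.ndarray, distances: np.ndarray, tol: float = 1e-9
) -> np.ndarray:
    """Enumerate all normal triples, solve the 3x3 systems, keep feasible
    intersection points, and deduplicate."""
    candidates = []
    for i, j, k in itertools.combinations(range(len(normals)), 3):
        A = normals[[i, j, k]]
        if abs(np.linalg.det(A)) < tol:
            continue
        x = np.linalg.solve(A, distances[[i, j, k]])
        if np.all(normals @ x <= distances + 1e-7):
            candidates.append(x)
    pts = np.array(candidates)
    scale = max(np.abs(pts).max(), 1.0)
    keys = np.round(pts / (1e-7 * scale)).astype(np.int64)
    _, idx = np.unique(keys, axis=0, return_index=True)
    return pts[np.sort(idx)]


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Two-pass Pearson correlation of two 1-D samples."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / np.sqrt(sxx * syy)


def tetra_fan_volume_oracle(points: np.ndarray, hull_simplices, hull_vertices) -> float:
    """Hull volume by summing unsigned fan tetrahedra from an interior point."""
    apex = points[hull_vertices].mean(axis=0)
    total = 0.0
    for tri in hull_simplices:
        a, b, c = points[tri] - apex
        total += abs(np.dot(np.cross(a, b), c)) / 6.0
    return total


def sphere_quadrature_integral(f, n: int = 200) -> float:
    """Dense trapezoid-free quadrature of f(theta, phi) over the sphere
    using Gauss-Legendre nodes in cos(theta) and a uniform phi grid."""
    x, w = np.polynomial.legendre.leggauss(n)
    theta = np.arccos(x)
    phi = 2 * np.pi * np.arange(2 * n) / (2 * n)
    th, ph = np.meshgrid(theta, phi, indexing="ij")
    wt = np.repeat(w[:, None], 2 * n, axis=1) * (2 * np.pi / (2 * n))
    return float(np.sum(wt * f(th, ph)))
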