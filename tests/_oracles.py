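"""Independent brute-force oracles shared by the unit and acceptance tests.

Each function recomputes a quantity from first principles by a route
deliberately different from the package implementation.
"""

import numpy as np


def hull_area_oracle(pts: np.ndarray) -> float:
    """Convex-hull area by O(n³) edge testing plus the shoelace formula.

    A directed pair (i, j) is a hull edge iff every other point lies on or
    to the left of the line i→j; boundary points are then ordered by angle
    around their centroid (a ray from an interior point meets a convex
    boundary exactly once, so the ordering is unambiguous). Collinear
    points on an edge only add zero-area shoelace terms.
    """
    pts = np.unique(np.asarray(pts, dtype=float), axis=0)
    n = len(pts)
    if n < 3:
        return 0.0
    on_hull: set[int] = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = pts[j] - pts[i]
            rel = pts - pts[i]
            cross = d[0] * rel[:, 1] - d[1] * rel[:, 0]
            mask = np.ones(n, dtype=bool)
            mask[[i, j]] = False
            if np.all(cross[mask] >= 0):
                on_hull.update((i, j))
    boundary = pts[sorted(on_hull)]
    if len(boundary) < 3:
        return 0.0
    center = boundary.mean(axis=0)
    order = np.argsort(np.arctan2(boundary[:, 1] - center[1],
                                  boundary[:, 0] - center[0]))
    b = boundary[order]
    x, y = b[:, 0], b[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2)


def circle_lens_area(d: float, r: float = 1.0) -> float:
    """Closed-form intersection area of two radius-r circles d apart."""
    if d >= 2 * r:
        return 0.0
    return float(2 * r**2 * np.arccos(d / (2 * r)) - (d / 2) * np.sqrt(4 * r**2 - d**2))


def shannon_decomposition_oracle(arr: np.ndarray) -> tuple[float, float, float]:
    """Term-by-term TNW/WIC/BIC from a (n_individuals, n_taxa) amount matrix."""
    totals = arr.sum(axis=1)
    p_i = totals / totals.sum()
    q = arr.sum(axis=0) / arr.sum()
    tnw = -sum(qk * np.log(qk) for qk in q if qk > 0)
    wic = 0.0
    bic = 0.0
    for i in range(arr.shape[0]):
        pik = arr[i] / totals[i]
        for k in range(arr.shape[1]):
            if pik[k] > 0:
                wic -= p_i[i] * pik[k] * np.log(pik[k])
                bic += p_i[i] * pik[k] * np.log(pik[k] / q[k])
    return float(tnw), float(wic), float(bic)


def hotelling_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """T² assembled element by element from the textbook definition."""
    n1, n2 = len(a), len(b)
    xbar = a.mean(axis=0)
    ybar = b.mean(axis=0)
    s1 = sum(np.outer(r - xbar, r - xbar) for r in a) / (n1 - 1)
    s2 = sum(np.outer(r - ybar, r - ybar) for r in b) / (n2 - 1)
    sp = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    d = xbar - ybar
    return float((n1 * n2) / (n1 + n2) * d @ np.linalg.inv(sp) @ d)


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Σ(x−x̄)(y−ȳ) / √(Σ(x−x̄)² Σ(y−ȳ)²), written out."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xd, yd = x - x.mean(), y - y.mean()
    return float((xd * yd).sum() / np.sqrt((xd**2).sum() * (yd**2).sum()))
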