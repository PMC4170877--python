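"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (loops, enumeration, Monte Carlo) and
shares no code with the package internals it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_upgma(points: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """O(q^3) UPGMA: recompute every average inter-cluster distance each step."""
    pts = np.asarray(points, dtype=float)
    q = pts.shape[0]
    clusters: list[frozenset] = [frozenset([i]) for i in range(q)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            dsum = 0.0
            for i in clusters[a]:
                for j in clusters[b]:
                    dsum += float(np.linalg.norm(pts[i] - pts[j]))
            d = dsum / (len(clusters[a]) * len(clusters[b]))
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merges.append((clusters[a], clusters[b], d))
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return merges


def mc_polygon_area(
    vertices: np.ndarray, n_samples: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Monte-Carlo hit-count area over the bounding box; returns (area, SE)."""
    v = np.asarray(vertices, dtype=float)
    lo, hi = v.min(axis=0), v.max(axis=0)
    box_area = float(np.prod(hi - lo))
    pts = rng.uniform(lo, hi, size=(n_samples, 2))
    # winding-free inside test: point in convex polygon iff on one side of
    # every edge after orienting CCW by signed area
    x, y = v[:, 0], v[:, 1]
    s = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    vv = v if s > 0 else v[::-1]
    inside = np.ones(n_samples, dtype=bool)
    for k in range(len(vv)):
        a, b = vv[k], vv[(k + 1) % len(vv)]
        cross = (b[0] - a[0]) * (pts[:, 1] - a[1]) - (b[1] - a[1]) * (pts[:, 0] - a[0])
        inside &= cross >= 0
    p_hat = inside.mean()
    area = box_area * p_hat
    se = box_area * np.sqrt(p_hat * (1 - p_hat) / n_samples)
    return float(area), float(se)


def fan_triangulation_centroid(vertices: np.ndarray) -> tuple[float, float]:
    """Area-weighted mean of fan-triangle centroids (independent of the
    signed-area formula)."""
    v = np.asarray(vertices, dtype=float)
    total = 0.0
    acc = np.zeros(2)
    for k in range(1, len(v) - 1):
        a, b, c = v[0], v[k], v[k + 1]
        t_area = 0.5 * ((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))
        t_centroid = (a + b + c) / 3.0
        total += t_area
        acc += t_area * t_centroid
    return tuple(acc / total)


def pairwise_rand_index(a: dict, b: dict) -> float:
    """Rand index by explicit O(q^2) pair enumeration."""
    keys = sorted(a)
    agree = total = 0
    for i, j in itertools.combinations(keys, 2):
        total += 1
        if (a[i] == a[j]) == (b[i] == b[j]):
            agree += 1
    return agree / total


def random_convex_polygon(
    rng: np.random.Generator, n_points: int = 30, scale: float = 1.0
) -> np.ndarray:
    """Convex hull vertices of random Gaussian points (CCW by angle sort)."""
    from scipy.spatial import ConvexHull

    pts = rng.normal(scale=scale, size=(n_points, 2)) + rng.uniform(-5, 5, size=2)
    hull = ConvexHull(pts)
    return pts[hull.vertices]
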