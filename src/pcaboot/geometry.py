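"""Confidence polygons: convex hulls, trimming, shoelace areas, centroids.

Each object's bootstrap cloud is summarized by the convex hull of its points
(its "confidence polygon"). The polygon's area, computed with the shoelace
formula

    S = 1/2 * sum_i (x_i * y_{i+1} - x_{i+1} * y_i),

measures the sampling variability of the object's score, and its
signed-area-weighted centroid

    x_c = 1/(6S) * sum_i (x_i + x_{i+1}) (x_i y_{i+1} - x_{i+1} y_i)
    y_c = 1/(6S) * sum_i (y_i + y_{i+1}) (x_i y_{i+1} - x_{i+1} y_i)

serves as a bootstrap-validated estimate of the score itself. Overlap between
two objects' polygons suggests the objects are not distinguishable.

An optional trim level ``alpha`` discards the most extreme cloud points
before hulling (``alpha = 0`` keeps everything, which makes outliers visible
through long hull edges). Trimming is done by convex-hull peeling by default:
repeatedly delete the current hull's vertices while at least
``ceil((1 - alpha) * M)`` points would survive. A Mahalanobis-distance
alternative is available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "ConfidencePolygon",
    "convex_hull",
    "trim_cloud",
    "polygon_area",
    "signed_polygon_area",
    "polygon_centroid",
    "polygons_overlap",
    "cloud_polygons",
]

_DEGENERATE_AREA = 1e-12


@dataclass
class ConfidencePolygon:
    """Ordered hull vertices (counter-clockwise) around one object's cloud."""

    object_id: str
    vertices: np.ndarray  # (l, 2)
    area: float
    centroid: tuple[float, float]
    alpha: float
    n_points_in: int
    degenerate: bool = False

    def contains(self, pts: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Vectorized inside-or-on test via half-planes (CCW vertices)."""
        pts = np.atleast_2d(pts)
        if self.degenerate:
            poly = _shapely_geom(self.vertices)
            return np.array(
                [poly.distance(Point(*q)) <= tol for q in pts], dtype=bool
            )
        v = self.vertices
        nxt = np.roll(v, -1, axis=0)
        e = nxt - v  # edge vectors
        inside = np.ones(pts.shape[0], dtype=bool)
        for (vx, vy), (ex, ey) in zip(v, e):
            cross = ex * (pts[:, 1] - vy) - ey * (pts[:, 0] - vx)
            inside &= cross >= -tol
        return inside


def convex_hull(points: np.ndarray) -> tuple[np.ndarray, bool]:
    """Minimal convex vertex set of a 2-D point cloud, counter-clockwise.

    Returns ``(vertices, degenerate)``. Fewer than 3 distinct points, or a
    collinear cloud, yields a degenerate result (the extreme points, flagged)
    rather than an error; fewer than 1 point is an error.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 1:
        raise ValueError("need at least one point")
    if pts.shape[1] != 2:
        raise ValueError("points must be 2-D")
    uniq = np.unique(pts, axis=0)
    if uniq.shape[0] >= 3:
        try:
            hull = ConvexHull(uniq)
            return uniq[hull.vertices], False  # Qhull returns CCW order in 2-D
        except QhullError:
            pass  # collinear — fall through to the degenerate path
    # degenerate: point or segment; report extreme points along the spread
    if uniq.shape[0] == 1:
        return uniq, True
    d = uniq - uniq.mean(axis=0)
    direction = d[np.argmax(np.einsum("ij,ij->i", d, d))]
    t = uniq @ direction
    ends = uniq[[int(np.argmin(t)), int(np.argmax(t))]]
    # canonical order: lexicographically smaller endpoint first
    if tuple(ends[1]) < tuple(ends[0]):
        ends = ends[::-1]
    return ends, True


def trim_cloud(
    points: np.ndarray, alpha: float, method: str = "peel"
) -> np.ndarray:
    """Retain at least ``ceil((1 - alpha) * M)`` central points of a cloud.

    ``method="peel"``: convex-hull peeling — delete the current hull's
    vertices while doing so leaves at least the target count (standard
    nonparametric bivariate trimming, no distributional assumption).
    ``method="mahalanobis"``: keep the target count of points with smallest
    Mahalanobis distance from the cloud mean.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    M = pts.shape[0]
    target = int(np.ceil((1 - alpha) * M))
    if alpha == 0 or M <= 3:
        return pts
    if method == "peel":
        current = pts
        while current.shape[0] > target:
            verts, degen = convex_hull(current)
            if degen:
                break
            mask = np.ones(current.shape[0], dtype=bool)
            vset = {tuple(v) for v in verts}
            for i, q in enumerate(current):
                if tuple(q) in vset:
                    mask[i] = False
            if current.shape[0] - (~mask).sum() < target:
                break
            current = current[mask]
        return current
    if method == "mahalanobis":
        mu = pts.mean(axis=0)
        cov = np.cov(pts.T)
        try:
            cov_inv = np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            return pts
        d = np.einsum("ij,jk,ik->i", pts - mu, cov_inv, pts - mu)
        keep = np.argsort(d, kind="stable")[:target]
        return pts[np.sort(keep)]
    raise ValueError(f"unknown trim method: {method}")


def signed_polygon_area(vertices: np.ndarray) -> float:
    """Shoelace sum of consecutive 2x2 determinants, halved (sign = winding)."""
    v = np.asarray(vertices, dtype=float)
    if v.shape[0] < 3:
        raise ValueError("a polygon needs at least 3 vertices")
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return float(0.5 * np.sum(x * yn - xn * y))


def polygon_area(vertices: np.ndarray) -> float:
    """Absolute shoelace area: invariant to winding and cyclic rotation."""
    return abs(signed_polygon_area(vertices))


def polygon_centroid(vertices: np.ndarray) -> tuple[float, float]:
    """Signed-area-weighted polygon centroid.

    For polygons with area below ``1e-12`` (degenerate) the arithmetic mean
    of the vertices is returned instead of dividing by ~zero.
    """
    v = np.asarray(vertices, dtype=float)
    if v.shape[0] < 3:
        return tuple(v.mean(axis=0))
    S = signed_polygon_area(v)
    if abs(S) < _DEGENERATE_AREA:
        return tuple(v.mean(axis=0))
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    cx = np.sum((x + xn) * cross) / (6.0 * S)
    cy = np.sum((y + yn) * cross) / (6.0 * S)
    return float(cx), float(cy)


def _shapely_geom(vertices: np.ndarray):
    v = np.atleast_2d(vertices)
    if v.shape[0] >= 3:
        poly = Polygon(v)
        if poly.area > 0:
            return poly
    if v.shape[0] >= 2 and not np.allclose(v[0], v[-1]):
        return LineString(v)
    return Point(v[0])


def polygons_overlap(
    A: ConfidencePolygon, B: ConfidencePolygon
) -> tuple[bool, float]:
    """Do two confidence polygons overlap, and with what intersection area?

    Returns ``(flag, area)``: the flag is true when the regions intersect at
    all (touching boundaries count); the area is the area of the
    intersection (0 for touch-only or degenerate geometry).
    """
    ga, gb = _shapely_geom(A.vertices), _shapely_geom(B.vertices)
    inter = ga.intersection(gb)
    return (not inter.is_empty) or ga.touches(gb), float(inter.area)


def cloud_polygons(
    cloud, alpha: float = 0.0, method: str = "peel"
) -> list[ConfidencePolygon]:
    """Build each object's confidence polygon from a bootstrap cloud.

    Uses the first two cloud dimensions (the principal plane). Points beyond
    the trim level are discarded by ``trim_cloud`` before hulling.
    """
    if cloud.m < 2:
        raise ValueError("confidence polygons need at least 2 cloud dimensions")
    out: list[ConfidencePolygon] = []
    for oid in cloud.row_ids:
        pts = cloud.object_points(oid)[:, :2]
        kept = trim_cloud(pts, alpha, method=method)
        verts, degen = convex_hull(kept)
        if degen:
            area = 0.0
            centroid = tuple(verts.mean(axis=0))
        else:
            area = polygon_area(verts)
            centroid = polygon_centroid(verts)
        out.append(
            ConfidencePolygon(
                object_id=oid,
                vertices=verts,
                area=area,
                centroid=centroid,
                alpha=alpha,
                n_points_in=kept.shape[0],
                degenerate=degen,
            )
        )
    return out


def polygons_table(polygons: list[ConfidencePolygon]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "object_id": [pg.object_id for pg in polygons],
            "alpha": [pg.alpha for pg in polygons],
            "area": [pg.area for pg in polygons],
            "centroid_x": [pg.centroid[0] for pg in polygons],
            "centroid_y": [pg.centroid[1] for pg in polygons],
            "n_vertices": [pg.vertices.shape[0] for pg in polygons],
            "degenerate": [pg.degenerate for pg in polygons],
        }
    )


def polygons_to_json(polygons: list[ConfidencePolygon], path: str | Path) -> None:
    payload = {
        pg.object_id: {
            "alpha": pg.alpha,
            "area": pg.area,
            "centroid": list(pg.centroid),
            "vertices": pg.vertices.tolist(),
            "degenerate": pg.degenerate,
        }
        for pg in polygons
    }
    Path(path).write_text(json.dumps(payload, indent=2))
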