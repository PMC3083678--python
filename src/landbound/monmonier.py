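"""Monmonier's maximum-difference barrier tracing.

A Delaunay triangulation connects sampled individuals; each edge carries the
genetic distance between its endpoints (raw, or the residual after
regressing genetic on geographic distance to remove an isolation-by-distance
trend).  A barrier starts at the edge with the largest distance and grows
from both ends across the triangulation: at each step it crosses the
adjacent same-triangle edge with the largest distance, stopping when it
reaches the convex hull, closes a loop, or meets an already-traced barrier.
Geometrically a barrier is the chain of Voronoi segments dual to the crossed
Delaunay edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import Delaunay, QhullError

from .sumstats import GENETIC_DISTANCES

logger = logging.getLogger(__name__)

Edge = tuple[int, int]


class GeometryError(ValueError):
    pass


def _circumcenter(p1, p2, p3):
    ax, ay = p1
    bx, by = p2
    cx, cy = p3
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if d == 0:
        # degenerate (collinear) triangle: fall back to centroid
        return ((ax + bx + cx) / 3.0, (ay + by + cy) / 3.0)
    ux = ((ax * ax + ay * ay) * (by - cy) + (bx * bx + by * by) * (cy - ay)
          + (cx * cx + cy * cy) * (ay - by)) / d
    uy = ((ax * ax + ay * ay) * (cx - bx) + (bx * bx + by * by) * (ax - cx)
          + (cx * cx + cy * cy) * (bx - ax)) / d
    return (ux, uy)


@dataclass
class DelaunayGraph:
    """Delaunay triangulation of sample coordinates with genetic-distance
    edge weights and the dual Voronoi geometry needed for tracing."""

    points: np.ndarray
    simplices: np.ndarray
    weights: dict[Edge, float]
    edge_triangles: dict[Edge, tuple[int, int]]  # second = -1 on the hull
    circumcenters: np.ndarray

    @property
    def edges(self) -> list[Edge]:
        return list(self.weights)

    def hull_edges(self) -> set[Edge]:
        return {e for e, (t1, t2) in self.edge_triangles.items() if t2 == -1}

    def voronoi_segment(self, edge: Edge) -> tuple[tuple[float, float],
                                                   tuple[float, float]]:
        """Voronoi segment dual to a Delaunay edge.

        Internal edges connect the circumcenters of their two adjacent
        triangles; hull edges yield a finite ray from the circumcenter
        outward, perpendicular to the edge, with length of the point-set
        diameter (callers clip to their region of interest).
        """
        t1, t2 = self.edge_triangles[edge]
        c1 = self.circumcenters[t1]
        if t2 != -1:
            return (tuple(c1), tuple(self.circumcenters[t2]))
        i, j = edge
        pi, pj = self.points[i], self.points[j]
        mid = (pi + pj) / 2.0
        d = pj - pi
        n = np.array([-d[1], d[0]])
        nn = np.linalg.norm(n)
        if nn == 0:
            return (tuple(c1), tuple(c1))
        n = n / nn
        # point away from the triangle's third vertex
        tri = self.simplices[t1]
        other = [v for v in tri if v != i and v != j][0]
        if np.dot(n, mid - self.points[other]) < 0:
            n = -n
        span = float(np.linalg.norm(self.points.max(axis=0)
                                    - self.points.min(axis=0)))
        return (tuple(c1), tuple(mid + n * span))


@dataclass
class BoundaryPath:
    """One traced barrier: ordered crossed Delaunay edges and the dual
    Voronoi segments; rank 1 is the first-traced (strongest) barrier."""

    crossed_edges: list[Edge]
    segments: list[tuple[tuple[float, float], tuple[float, float]]]
    rank: int
    stop_reasons: tuple[str, str] = ("", "")

    def length(self) -> float:
        tot = 0.0
        for (x1, y1), (x2, y2) in self.segments:
            tot += float(np.hypot(x2 - x1, y2 - y1))
        return tot


def build_graph(coords: np.ndarray, genotypes: np.ndarray | None = None,
                distance: str = "raw", metric: str = "allele_sharing",
                distance_matrix: np.ndarray | None = None) -> DelaunayGraph:
    """Triangulate sample coordinates and weight edges by genetic distance.

    ``distance='raw'`` uses the pairwise metric directly
    (``allele_sharing``: 1 - proportion of shared alleles, or ``rousset``);
    ``distance='residual'`` replaces each edge weight with the residual of
    genetic distance regressed on Euclidean geographic distance over the
    graph's edges, removing an isolation-by-distance trend.  A precomputed
    ``distance_matrix`` overrides ``genotypes``.  Duplicate coordinates are
    jittered with a warning; a fully collinear point set is a geometry
    error.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 3:
        raise GeometryError("need at least 3 points")
    if distance_matrix is None:
        if genotypes is None:
            raise ValueError("need genotypes or a distance_matrix")
        distance_matrix = GENETIC_DISTANCES[metric](genotypes)
    distance_matrix = np.asarray(distance_matrix, dtype=float)

    _, counts = np.unique(coords, axis=0, return_counts=True)
    if (counts > 1).any():
        logger.warning("jittering %d duplicate coordinates",
                       int(counts[counts > 1].sum() - (counts > 1).sum()))
        rng = np.random.default_rng(0)
        seen: set[tuple[float, float]] = set()
        for k in range(len(coords)):
            key = tuple(coords[k])
            while key in seen:
                coords[k] = coords[k] + rng.normal(0, 1e-6, 2)
                key = tuple(coords[k])
            seen.add(key)
    try:
        tri = Delaunay(coords)
    except QhullError as exc:
        raise GeometryError(f"triangulation failed: {exc}") from exc
    if tri.simplices.shape[0] == 0:
        raise GeometryError("all points collinear")

    edge_triangles: dict[Edge, tuple[int, int]] = {}
    for t, simplex in enumerate(tri.simplices):
        for a in range(3):
            i, j = sorted((simplex[a], simplex[(a + 1) % 3]))
            e = (int(i), int(j))
            if e in edge_triangles:
                edge_triangles[e] = (edge_triangles[e][0], t)
            else:
                edge_triangles[e] = (t, -1)

    weights = {e: float(distance_matrix[e[0], e[1]]) for e in edge_triangles}
    if distance == "residual":
        edges = list(weights)
        geo = np.array([np.linalg.norm(coords[i] - coords[j])
                        for i, j in edges])
        gen = np.array([weights[e] for e in edges])
        if np.ptp(geo) == 0 or np.ptp(gen) == 0:
            resid = gen - gen.mean()
        else:
            fit = stats.linregress(geo, gen)
            resid = gen - (fit.intercept + fit.slope * geo)
        weights = {e: float(rv) for e, rv in zip(edges, resid)}
    elif distance != "raw":
        raise ValueError(f"unknown distance mode {distance!r}")

    centers = np.array([_circumcenter(coords[s[0]], coords[s[1]],
                                      coords[s[2]])
                        for s in tri.simplices])
    return DelaunayGraph(points=coords, simplices=tri.simplices,
                         weights=weights, edge_triangles=edge_triangles,
                         circumcenters=centers)


def _triangle_edges(graph: DelaunayGraph, t: int) -> list[Edge]:
    s = graph.simplices[t]
    return [tuple(sorted((int(s[a]), int(s[(a + 1) % 3]))))
            for a in range(3)]


def _other_triangle(graph: DelaunayGraph, edge: Edge, t: int) -> int:
    t1, t2 = graph.edge_triangles[edge]
    return t2 if t1 == t else t1


def _grow_end(graph: DelaunayGraph, start_tri: int, crossed: set[Edge],
              visited: set[int]) -> tuple[list[Edge], str]:
    """Grow one barrier end from the triangle just entered.

    Returns the edges crossed by this end, in crossing order, and the stop
    reason: 'hull' (exited the triangulation), 'loop' (revisited a Voronoi
    vertex), or 'blocked' (every candidate edge already crossed).
    """
    out: list[Edge] = []
    t = start_tri
    while True:
        if t == -1:
            return out, "hull"
        if t in visited:
            return out, "loop"
        visited.add(t)
        candidates = [e for e in _triangle_edges(graph, t)
                      if e not in crossed]
        if not candidates:
            return out, "blocked"
        # largest weight; ties broken by lowest (i, j) pair
        best = min(candidates, key=lambda e: (-graph.weights[e], e))
        crossed.add(best)
        out.append(best)
        t = _other_triangle(graph, best, t)


def trace_barriers(graph: DelaunayGraph, n_barriers: int = 4,
                   _crossed: set[Edge] | None = None) -> list[BoundaryPath]:
    """Trace up to ``n_barriers`` maximum-difference barriers.

    Each barrier seeds at the largest-weight edge not yet crossed by any
    barrier and grows from both ends.  Edges crossed by earlier barriers are
    never recrossed, so paths of different rank are edge-disjoint.  Fewer
    paths are returned, with a warning, when no admissible seed remains.
    """
    if n_barriers < 1:
        raise ValueError("n_barriers must be >= 1")
    crossed: set[Edge] = set() if _crossed is None else _crossed
    paths: list[BoundaryPath] = []
    for rank in range(1, n_barriers + 1):
        available = [e for e in graph.weights if e not in crossed]
        if not available:
            logger.warning("no admissible seed edges left after %d barriers",
                           len(paths))
            break
        seed = min(available, key=lambda e: (-graph.weights[e], e))
        crossed.add(seed)
        t1, t2 = graph.edge_triangles[seed]
        visited: set[int] = set()
        left, reason_l = _grow_end(graph, t1, crossed, visited)
        right, reason_r = (([], "hull") if t2 == -1
                           else _grow_end(graph, t2, crossed, visited))
        edges = list(reversed(left)) + [seed] + right
        segments = [graph.voronoi_segment(e) for e in edges]
        paths.append(BoundaryPath(crossed_edges=edges, segments=segments,
                                  rank=rank,
                                  stop_reasons=(reason_l, reason_r)))
    return paths
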