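"""Monmonier's maximum-difference barrier algorithm.

Cell centroids are joined by a Delaunay triangulation whose dual is the
Voronoi (Thiessen) tessellation; each Delaunay edge carries the compositional
dissimilarity of the two cells it joins and is crossed by exactly one Voronoi
segment. A barrier starts on the dual of the most dissimilar uncrossed edge
and grows from both ends, always crossing the adjacent uncrossed Delaunay edge
of greatest dissimilarity, until it reaches the network boundary, an existing
barrier, or itself. Ranked barriers trace the strongest breaks in composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, Voronoi

from .composition import DissimilarityMatrix


@dataclass
class SpatialNetwork:
    points: np.ndarray  # (n, 2) lon/lat cell centroids
    edges: list[tuple[int, int]]  # Delaunay edges as (i, j), i < j
    edge_dissimilarity: np.ndarray
    dual_segments: list[tuple[np.ndarray, np.ndarray, bool]]  # (p0, p1, p1_is_boundary)
    ridge_vertices: list[tuple[int, int]]  # Voronoi vertex ids, -1 = infinite
    voronoi_vertices: np.ndarray
    cell_ids: np.ndarray | None = None


@dataclass
class Barrier:
    rank: int
    path: list[tuple[np.ndarray, np.ndarray]]  # ordered Voronoi segments
    crossed_edges: list[tuple[int, int]]
    crossed_dissimilarities: list[float]
    seed_edge: tuple[int, int] = (0, 0)

    @property
    def total_strength(self) -> float:
        return float(sum(self.crossed_dissimilarities))


def build_network(centroids: np.ndarray, dmat: DissimilarityMatrix) -> SpatialNetwork:
    """Delaunay network over cell centroids with dissimilarities on the edges.

    The Voronoi dual is computed with scipy; infinite ridges are clipped to the
    centroid bounding box inflated by one typical cell spacing, and their outer
    endpoint is flagged as a boundary terminus for the barrier tracing.
    """
    pts = np.asarray(centroids, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 centroids")
    try:
        vor = Voronoi(pts)
        tri = Delaunay(pts)
    except Exception as exc:
        raise ValueError(f"degenerate triangulation: {exc}") from exc
    if len(vor.vertices) == 0:
        raise ValueError("degenerate triangulation: all points collinear")

    span = pts.max(axis=0) - pts.min(axis=0)
    pad = max(span.max() / max(np.sqrt(len(pts)) - 1, 1), 1e-6)
    center = pts.mean(axis=0)
    radius = float(np.hypot(*span)) + 2 * pad

    # Delaunay edge list; most have a Voronoi ridge, but edges of co-circular
    # quads are dual to a single degenerate (zero-length) vertex
    del_edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            del_edges.add((i, j) if i < j else (j, i))
    ridge_of = {}
    for (p, q), rv in zip(vor.ridge_points, vor.ridge_vertices):
        key = (int(p), int(q)) if p < q else (int(q), int(p))
        ridge_of[key] = tuple(rv)

    edges: list[tuple[int, int]] = []
    duals: list[tuple[np.ndarray, np.ndarray, bool]] = []
    rverts: list[tuple[int, int]] = []
    for i, j in sorted(del_edges):
        if (i, j) in ridge_of:
            v0, v1 = ridge_of[(i, j)]
        else:
            shared = set(vor.regions[vor.point_region[i]]) & set(
                vor.regions[vor.point_region[j]]
            ) - {-1}
            if not shared:  # pragma: no cover - no dual at all
                continue
            v = min(shared)
            edges.append((i, j))
            duals.append((vor.vertices[v].copy(), vor.vertices[v].copy(), False))
            rverts.append((v, v))
            continue
        if v0 == -1 and v1 == -1:  # pragma: no cover - degenerate double-infinite ridge
            continue
        if v0 == -1 or v1 == -1:
            vfin = v1 if v0 == -1 else v0
            a = vor.vertices[vfin]
            # direction of the infinite ridge: perpendicular to the point pair,
            # oriented away from the centroid cloud (scipy's own construction)
            t = pts[j] - pts[i]
            t /= np.linalg.norm(t)
            nrm = np.array([-t[1], t[0]])
            mid = (pts[i] + pts[j]) / 2.0
            if np.dot(mid - center, nrm) < 0:
                nrm = -nrm
            b = a + nrm * radius
            duals.append((a.copy(), b, True))
            rverts.append((int(vfin), -1))
        else:
            duals.append((vor.vertices[v0].copy(), vor.vertices[v1].copy(), False))
            rverts.append((int(v0), int(v1)))
        edges.append((i, j))
    # point order is assumed to match dmat.cell_ids order
    d = dmat.d
    dis = [float(d[i, j]) for i, j in edges]
    return SpatialNetwork(
        points=pts, edges=edges, edge_dissimilarity=np.asarray(dis),
        dual_segments=duals, ridge_vertices=rverts, voronoi_vertices=vor.vertices,
        cell_ids=np.asarray(dmat.cell_ids),
    )


def monmonier(network: SpatialNetwork, n_barriers: int = 15) -> list[Barrier]:
    """Trace the top *n_barriers* maximum-difference barriers.

    Ties are broken toward the lexicographically lowest (i, j) cell pair so the
    procedure is deterministic. A tip stops on the network boundary, on a
    Voronoi vertex already used by any barrier (including its own path), or
    when no uncrossed adjacent edge remains.
    """
    n_edges = len(network.edges)
    order = sorted(
        range(n_edges),
        key=lambda k: (-network.edge_dissimilarity[k], network.edges[k]),
    )
    # Voronoi vertex -> incident ridge indices
    incident: dict[int, list[int]] = {}
    for k, (v0, v1) in enumerate(network.ridge_vertices):
        for v in (v0, v1):
            if v != -1:
                incident.setdefault(v, []).append(k)

    crossed = np.zeros(n_edges, dtype=bool)
    used_vertices: set[int] = set()
    barriers: list[Barrier] = []

    def best_candidate(v: int):
        cands = [k for k in incident.get(v, []) if not crossed[k]]
        if not cands:
            return None
        return min(cands, key=lambda k: (-network.edge_dissimilarity[k], network.edges[k]))

    for rank in range(1, n_barriers + 1):
        seed = next((k for k in order if not crossed[k]), None)
        if seed is None:
            warnings.warn(f"only {rank - 1} barriers available; fewer than requested")
            break
        crossed[seed] = True
        p0, p1, p1_boundary = network.dual_segments[seed]
        v0, v1 = network.ridge_vertices[seed]
        path: list[tuple[np.ndarray, np.ndarray]] = [(p0, p1)]
        crossed_edges = [network.edges[seed]]
        crossed_d = [float(network.edge_dissimilarity[seed])]
        barrier_vertices: set[int] = set()

        for tip in (v0, v1):
            while tip != -1:
                if tip in used_vertices or tip in barrier_vertices:
                    break  # hit an existing barrier or looped onto itself
                barrier_vertices.add(tip)
                k = best_candidate(tip)
                if k is None:
                    break
                crossed[k] = True
                w0, w1 = network.ridge_vertices[k]
                seg0, seg1, _ = network.dual_segments[k]
                path.append((seg0, seg1))
                crossed_edges.append(network.edges[k])
                crossed_d.append(float(network.edge_dissimilarity[k]))
                tip = w1 if w0 == tip else w0

        used_vertices |= barrier_vertices
        barriers.append(
            Barrier(
                rank=rank, path=path, crossed_edges=crossed_edges,
                crossed_dissimilarities=crossed_d, seed_edge=network.edges[seed],
            )
        )
    return barriers


def barrier_geojson(barriers: list[Barrier], path) -> None:
    """Write barriers as GeoJSON LineStrings (one MultiLineString per barrier)."""
    import json

    feats = []
    for b in barriers:
        coords = [[[float(x) for x in p0], [float(x) for x in p1]] for p0, p1 in b.path]
        feats.append({
            "type": "Feature",
            "geometry": {"type": "MultiLineString", "coordinates": coords},
            "properties": {"rank": b.rank, "total_strength": b.total_strength},
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
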