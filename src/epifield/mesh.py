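"""Triangulated-surface geometry.

Cortical patches are represented as triangle meshes in millimetre
coordinates.  The quantities needed by the neural-field model and the
SEEG forward model are per-vertex areas (one third of the area of the
incident triangles), per-vertex outward unit normals (area-weighted
average of the incident face normals), and geodesic distances along the
surface.

Geodesic distances are computed on a graph.  The plain mesh edge graph
(``method="graph"``) systematically overestimates distances because
paths are forced through vertices; the metric stretch does not vanish
with refinement.  The default ``method="steiner"`` therefore augments
the graph with evenly spaced points on every edge and connects all
point pairs within each face by straight segments, which brings the
distance error on regular meshes below one percent and keeps the
normalisation of the exponential coupling kernel accurate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph

__all__ = [
    "TriSurface",
    "Electrode",
    "GeodesicField",
    "triangle_areas",
    "triangle_normals",
    "vertex_areas",
    "vertex_normals",
    "unique_edges",
    "triangle_quadrisect",
    "edge_graph",
    "geodesic_distances",
    "geodesic_distance_matrix",
    "extract_patch",
    "shortest_path_vertices",
    "connected_triangle_components",
]


class MeshError(ValueError):
    """Raised for invalid or degenerate mesh input."""


@dataclass
class TriSurface:
    """Triangulated surface patch in mm coordinates.

    Parameters
    ----------
    vertices : (V, 3) float array
        Vertex positions in mm.
    triangles : (T, 3) int array
        Vertex indices of each triangle, consistently oriented
        (counter-clockwise seen from the outward side).
    """

    vertices: np.ndarray
    triangles: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if self.triangles.size:
            if self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices):
                raise MeshError("triangle index out of range")
            areas = triangle_areas(self)
            if np.any(areas <= 0):
                bad = int(np.flatnonzero(areas <= 0)[0])
                raise MeshError(f"degenerate (zero-area) triangle {bad}")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def vertex_areas(self) -> np.ndarray:
        if "vertex_areas" not in self._cache:
            self._cache["vertex_areas"] = vertex_areas(self)
        return self._cache["vertex_areas"]

    @property
    def vertex_normals(self) -> np.ndarray:
        if "vertex_normals" not in self._cache:
            self._cache["vertex_normals"] = vertex_normals(self)
        return self._cache["vertex_normals"]

    @property
    def total_area(self) -> float:
        return float(triangle_areas(self).sum())


@dataclass
class Electrode:
    """Linear depth electrode: ordered contact points along a shaft."""

    contact_positions: np.ndarray
    contact_names: list[str]
    pitch: float = 3.5

    def __post_init__(self):
        self.contact_positions = np.asarray(self.contact_positions, dtype=float).reshape(-1, 3)
        if len(self.contact_names) != len(self.contact_positions):
            raise ValueError("one name per contact required")

    @property
    def n_contacts(self) -> int:
        return len(self.contact_positions)


@dataclass
class GeodesicField:
    """Geodesic distances from a set of source vertices.

    ``distances[v]`` is the minimum over sources of the geodesic distance
    to vertex ``v``; unreachable vertices (different component, or beyond
    the cutoff) hold ``inf`` and are flagged in ``reachable_mask``.
    """

    source_vertex_ids: np.ndarray
    distances: np.ndarray
    reachable_mask: np.ndarray


# ---------------------------------------------------------------------------
# elementary quantities


def triangle_areas(surface: TriSurface) -> np.ndarray:
    v = surface.vertices
    t = surface.triangles
    cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
    return 0.5 * np.linalg.norm(cross, axis=1)


def triangle_normals(surface: TriSurface) -> np.ndarray:
    v = surface.vertices
    t = surface.triangles
    cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
    norm = np.linalg.norm(cross, axis=1)
    return cross / norm[:, None]


def vertex_areas(surface: TriSurface) -> np.ndarray:
    """Per-vertex area: one third of the summed incident triangle areas."""
    areas = triangle_areas(surface)
    out = np.zeros(surface.n_vertices)
    np.add.at(out, surface.triangles.ravel(), np.repeat(areas / 3.0, 3))
    if np.any(out == 0):
        warnings.warn(
            f"{int((out == 0).sum())} isolated vertices carry zero area",
            stacklevel=2,
        )
    return out


def vertex_normals(surface: TriSurface) -> np.ndarray:
    """Per-vertex unit normal: area-weighted mean of incident face normals."""
    areas = triangle_areas(surface)
    fn = triangle_normals(surface) * areas[:, None]
    out = np.zeros_like(surface.vertices)
    np.add.at(out, surface.triangles.ravel(), np.repeat(fn, 3, axis=0))
    norm = np.linalg.norm(out, axis=1)
    bad = np.flatnonzero(norm < 1e-12)
    if bad.size:
        raise MeshError(
            f"vertex {int(bad[0])} has a vanishing resultant normal "
            "(pathological fold or isolated vertex)"
        )
    return out / norm[:, None]


def unique_edges(triangles: np.ndarray) -> np.ndarray:
    """Sorted unique undirected edges, shape (E, 2)."""
    e = np.vstack([triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]])
    e = np.sort(e, axis=1)
    return np.unique(e, axis=0)


def _edge_triangle_counts(triangles: np.ndarray):
    e = np.vstack([triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]])
    e = np.sort(e, axis=1)
    edges, counts = np.unique(e, axis=0, return_counts=True)
    return edges, counts


# ---------------------------------------------------------------------------
# refinement


def triangle_quadrisect(surface: TriSurface) -> TriSurface:
    """Split every triangle into four by its edge midpoints.

    Shared-edge midpoints are deduplicated, so the refined mesh has
    ``V + E`` vertices and ``4 T`` triangles; total area is preserved
    exactly for planar triangles.
    """
    edges, counts = _edge_triangle_counts(surface.triangles)
    if np.any(counts > 2):
        bad = edges[np.argmax(counts > 2)]
        raise MeshError(
            f"non-manifold edge {tuple(int(i) for i in bad)} shared by more than two triangles"
        )
    V = surface.n_vertices
    midpoints = 0.5 * (surface.vertices[edges[:, 0]] + surface.vertices[edges[:, 1]])
    # map each undirected edge to its midpoint vertex index
    edge_id = {(int(a), int(b)): V + i for i, (a, b) in enumerate(edges)}

    t = surface.triangles
    mids = np.empty((len(t), 3), dtype=np.int64)
    for k, (i, j) in enumerate([(0, 1), (1, 2), (2, 0)]):
        a = np.minimum(t[:, i], t[:, j])
        b = np.maximum(t[:, i], t[:, j])
        mids[:, k] = [edge_id[(int(x), int(y))] for x, y in zip(a, b)]

    mab, mbc, mca = mids[:, 0], mids[:, 1], mids[:, 2]
    new_t = np.vstack(
        [
            np.column_stack([t[:, 0], mab, mca]),
            np.column_stack([mab, t[:, 1], mbc]),
            np.column_stack([mca, mbc, t[:, 2]]),
            np.column_stack([mab, mbc, mca]),
        ]
    )
    return TriSurface(np.vstack([surface.vertices, midpoints]), new_t)


# ---------------------------------------------------------------------------
# geodesics


def edge_graph(surface: TriSurface) -> sparse.csr_matrix:
    """Symmetric sparse graph of mesh edges weighted by Euclidean length."""
    edges = unique_edges(surface.triangles)
    w = np.linalg.norm(surface.vertices[edges[:, 0]] - surface.vertices[edges[:, 1]], axis=1)
    n = surface.n_vertices
    g = sparse.coo_matrix(
        (np.concatenate([w, w]), (np.concatenate([edges[:, 0], edges[:, 1]]),
                                  np.concatenate([edges[:, 1], edges[:, 0]]))),
        shape=(n, n),
    )
    return g.tocsr()


def _steiner_graph(surface: TriSurface, k: int):
    """Graph over vertices plus k evenly spaced points per edge.

    Within every face all boundary points (3 corners + 3k edge points)
    are pairwise connected by straight segments.  Vertex nodes occupy
    indices ``0..V-1``.
    """
    key = ("steiner", k)
    if key in surface._cache:
        return surface._cache[key]
    V = surface.n_vertices
    edges = unique_edges(surface.triangles)
    E = len(edges)
    frac = (np.arange(1, k + 1) / (k + 1.0))[None, :, None]  # (1,k,1)
    p0 = surface.vertices[edges[:, 0]][:, None, :]
    p1 = surface.vertices[edges[:, 1]][:, None, :]
    steiner_pts = (1 - frac) * p0 + frac * p1  # (E,k,3)
    nodes = np.vstack([surface.vertices, steiner_pts.reshape(-1, 3)])

    edge_id = {(int(a), int(b)): i for i, (a, b) in enumerate(edges)}
    t = surface.triangles
    rows, cols = [], []
    for tri in range(len(t)):
        ids = [int(t[tri, 0]), int(t[tri, 1]), int(t[tri, 2])]
        face_nodes = list(ids)
        for i, j in [(0, 1), (1, 2), (2, 0)]:
            a, b = sorted((ids[i], ids[j]))
            eid = edge_id[(a, b)]
            face_nodes.extend(V + eid * k + np.arange(k))
        fn = np.asarray(face_nodes)
        ii, jj = np.triu_indices(len(fn), 1)
        rows.append(fn[ii])
        cols.append(fn[jj])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    # the same segment appears in both faces sharing an edge; deduplicate
    pairs = np.unique(
        np.column_stack([np.minimum(rows, cols), np.maximum(rows, cols)]), axis=0
    )
    w = np.linalg.norm(nodes[pairs[:, 0]] - nodes[pairs[:, 1]], axis=1)
    n = len(nodes)
    g = sparse.coo_matrix(
        (
            np.concatenate([w, w]),
            (np.concatenate([pairs[:, 0], pairs[:, 1]]),
             np.concatenate([pairs[:, 1], pairs[:, 0]])),
        ),
        shape=(n, n),
    ).tocsr()
    surface._cache[key] = g
    return g


def geodesic_distances(
    surface: TriSurface,
    sources,
    cutoff: float | None = None,
    method: str = "steiner",
    steiner_per_edge: int = 3,
) -> GeodesicField:
    """Geodesic distance field from one or more source vertices.

    ``method="graph"`` runs Dijkstra on the bare edge graph;
    ``method="steiner"`` (default) uses the edge-subdivided graph which
    is accurate to well under 1 mm at the scales used here.
    Distances beyond ``cutoff`` are marked unreachable.
    """
    sources = np.atleast_1d(np.asarray(sources, dtype=np.int64))
    if sources.min() < 0 or sources.max() >= surface.n_vertices:
        raise MeshError("source vertex id out of range")
    if cutoff is not None and cutoff <= 0:
        raise ValueError("cutoff must be positive")
    limit = np.inf if cutoff is None else cutoff
    if method == "graph":
        g = edge_graph(surface)
    elif method == "steiner":
        g = _steiner_graph(surface, steiner_per_edge)
    else:
        raise ValueError(f"unknown geodesic method {method!r}")
    d = csgraph.dijkstra(g, directed=False, indices=sources, limit=limit)
    d = np.atleast_2d(d)[:, : surface.n_vertices]
    dist = d.min(axis=0)
    return GeodesicField(sources, dist, np.isfinite(dist))


def geodesic_distance_matrix(
    surface: TriSurface,
    cutoff: float,
    method: str = "steiner",
    steiner_per_edge: int = 3,
    chunk: int = 128,
) -> sparse.csr_matrix:
    """All-pairs geodesic distances up to ``cutoff`` as a sparse matrix.

    Entry (i, j) holds d_g(i, j) for 0 < d_g <= cutoff; the zero
    self-distance is implicit.  Used to build the local coupling kernel.
    """
    if method == "graph":
        g = edge_graph(surface)
    elif method == "steiner":
        g = _steiner_graph(surface, steiner_per_edge)
    else:
        raise ValueError(f"unknown geodesic method {method!r}")
    V = surface.n_vertices
    blocks = []
    for start in range(0, V, chunk):
        idx = np.arange(start, min(start + chunk, V))
        d = csgraph.dijkstra(g, directed=False, indices=idx, limit=cutoff)
        d = np.atleast_2d(d)[:, :V]
        d[~np.isfinite(d)] = 0.0
        blocks.append(sparse.csr_matrix(d))
    return sparse.vstack(blocks).tocsr()


# ---------------------------------------------------------------------------
# patch extraction


def connected_triangle_components(surface: TriSurface):
    """Label triangles by edge-connected component."""
    edges, _ = _edge_triangle_counts(surface.triangles)
    # map sorted edge -> triangles containing it
    e = np.vstack(
        [surface.triangles[:, [0, 1]], surface.triangles[:, [1, 2]], surface.triangles[:, [2, 0]]]
    )
    e = np.sort(e, axis=1)
    tri_idx = np.tile(np.arange(surface.n_triangles), 3)
    order = np.lexsort((e[:, 1], e[:, 0]))
    e_sorted = e[order]
    t_sorted = tri_idx[order]
    # consecutive identical edges belong to adjacent triangles
    same = np.all(e_sorted[1:] == e_sorted[:-1], axis=1)
    a = t_sorted[:-1][same]
    b = t_sorted[1:][same]
    n = surface.n_triangles
    g = sparse.coo_matrix((np.ones(len(a)), (a, b)), shape=(n, n))
    ncomp, labels = csgraph.connected_components(g, directed=False)
    return ncomp, labels


def extract_patch(surface: TriSurface, electrode: Electrode, radius: float = 15.0) -> TriSurface:
    """Cut the patch of surface within ``radius`` mm of any contact.

    Vertices whose minimal Euclidean distance to the contacts exceeds
    ``radius`` are discarded together with their triangles; of the
    remaining edge-connected pieces only the largest (by area) is kept,
    removing orphaned islands that the seizure could never reach.
    """
    d = np.linalg.norm(
        surface.vertices[:, None, :] - electrode.contact_positions[None, :, :], axis=2
    ).min(axis=1)
    keep = d <= radius
    if not keep.any():
        raise MeshError(f"no vertex within {radius} mm of the electrode")
    tri_keep = keep[surface.triangles].all(axis=1)
    if not tri_keep.any():
        raise MeshError("no triangle survives the distance cut")
    tris = surface.triangles[tri_keep]
    used = np.unique(tris)
    remap = -np.ones(surface.n_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    sub = TriSurface(surface.vertices[used], remap[tris])

    ncomp, labels = connected_triangle_components(sub)
    if ncomp > 1:
        areas = triangle_areas(sub)
        comp_area = np.bincount(labels, weights=areas, minlength=ncomp)
        main = int(np.argmax(comp_area))
        tris2 = sub.triangles[labels == main]
        used2 = np.unique(tris2)
        remap2 = -np.ones(sub.n_vertices, dtype=np.int64)
        remap2[used2] = np.arange(len(used2))
        sub = TriSurface(sub.vertices[used2], remap2[tris2])
    return sub


# ---------------------------------------------------------------------------
# shortest paths


def shortest_path_vertices(
    surface: TriSurface, start: int, end: int, n_points: int = 30
):
    """Vertex chain of the shortest edge-graph path, subsampled uniformly.

    Returns ``(vertex_ids, cumulative_distances)`` with ``n_points``
    samples spaced uniformly in arc length, the first at ``start`` and
    the last at ``end``.
    """
    if start == end:
        warnings.warn("start equals end; returning degenerate path", stacklevel=2)
        return (np.full(n_points, start, dtype=np.int64), np.zeros(n_points))
    g = edge_graph(surface)
    d, pred = csgraph.dijkstra(
        g, directed=False, indices=start, return_predecessors=True
    )
    if not np.isfinite(d[end]):
        raise MeshError(f"vertex {end} is unreachable from vertex {start}")
    path = [end]
    while path[-1] != start:
        path.append(int(pred[path[-1]]))
    path = np.asarray(path[::-1], dtype=np.int64)
    seg = np.linalg.norm(np.diff(surface.vertices[path], axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, cum[-1], n_points)
    idx = np.abs(cum[None, :] - targets[:, None]).argmin(axis=1)
    idx[0], idx[-1] = 0, len(path) - 1
    idx = np.maximum.accumulate(idx)
    return path[idx], cum[idx]
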