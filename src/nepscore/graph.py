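"""Cellular neighborhood graphs: Delaunay, kNN and fixed-radius.

All builders operate on the cells of a single image and return a
symmetric, self-loop-free :class:`NeighborGraph`.  Graphs are never built
across images: images are independent samples.

Conventions
-----------
* kNN graphs are the union of directed k-nearest relations (symmetrized),
  with distance ties broken by (distance, cell index) lexicographic order.
* Radius graphs use a closed boundary: an edge exists iff
  ``0 < d(s, t) <= r``.
* Delaunay input is deduplicated; co-located cells inherit their
  representative's edges and gain mutual edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.spatial import Delaunay, cKDTree

from .errors import DegenerateGeometryError, ParameterError


@dataclass(frozen=True)
class NeighborGraph:
    """Symmetric cell-cell adjacency over the cells of one image."""

    n_cells: int
    edges: np.ndarray  # (E, 2) intp, each row (s, t) with s < t
    method: str  # "delaunay" | "knn" | "radius"
    param: float | int | None = None

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=np.intp).reshape(-1, 2)
        if len(e):
            if (e[:, 0] == e[:, 1]).any():
                raise ValueError("self-edges are not allowed")
            e = np.sort(e, axis=1)
            e = np.unique(e, axis=0)
        object.__setattr__(self, "edges", e)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> csr_matrix:
        """Boolean symmetric adjacency as CSR (float 0/1 data)."""
        if self.n_edges == 0:
            return csr_matrix((self.n_cells, self.n_cells))
        s, t = self.edges[:, 0], self.edges[:, 1]
        rows = np.concatenate([s, t])
        cols = np.concatenate([t, s])
        data = np.ones(len(rows))
        return coo_matrix(
            (data, (rows, cols)), shape=(self.n_cells, self.n_cells)
        ).tocsr()

    def neighbor_lists(self) -> list[np.ndarray]:
        """Per-cell sorted neighbor index arrays."""
        adj = [[] for _ in range(self.n_cells)]
        for s, t in self.edges:
            adj[s].append(t)
            adj[t].append(s)
        return [np.array(sorted(a), dtype=np.intp) for a in adj]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_cells, dtype=np.intp)
        if self.n_edges:
            np.add.at(deg, self.edges.ravel(), 1)
        return deg


def _coords(cells_or_array) -> np.ndarray:
    if hasattr(cells_or_array, "coordinates"):
        return cells_or_array.coordinates()
    return np.asarray(cells_or_array, dtype=float).reshape(-1, 2)


def build_delaunay(cells) -> NeighborGraph:
    """Delaunay-triangulation adjacency of the cell centroids.

    Exact duplicate coordinates are collapsed for the triangulation; each
    duplicate then inherits its representative's edges plus mutual edges
    among co-located cells.
    """
    pts = _coords(cells)
    n = len(pts)
    if n < 3:
        raise DegenerateGeometryError(f"Delaunay needs >= 3 cells, got {n}")
    uniq, first_idx, inverse = np.unique(
        pts, axis=0, return_index=True, return_inverse=True
    )
    if len(uniq) < 3:
        raise DegenerateGeometryError("fewer than 3 distinct coordinates")
    if len(uniq) == n:
        uniq = pts  # no duplicates: keep original indexing
    try:
        tri = Delaunay(uniq)
    except Exception as exc:  # QhullError on collinear input
        raise DegenerateGeometryError(f"degenerate geometry: {exc}") from exc
    if tri.simplices.size == 0:
        raise DegenerateGeometryError("all cells collinear")
    ii, jj = np.meshgrid([0, 1, 2], [0, 1, 2], indexing="ij")
    keep = ii.ravel() < jj.ravel()
    ue = tri.simplices[:, ii.ravel()[keep]], tri.simplices[:, jj.ravel()[keep]]
    uniq_edges = np.unique(
        np.sort(np.stack([ue[0].ravel(), ue[1].ravel()], axis=1), axis=1), axis=0
    )
    if len(uniq) == n:
        return NeighborGraph(n, uniq_edges, "delaunay")
    # expand to duplicates: members of each representative
    members: dict[int, list[int]] = {}
    for cell, rep in enumerate(inverse):
        members.setdefault(int(rep), []).append(cell)
    edges = []
    for a, b in uniq_edges:
        for s in members[int(a)]:
            for t in members[int(b)]:
                edges.append((s, t))
    for group in members.values():
        for i, s in enumerate(group):
            for t in group[i + 1 :]:
                edges.append((s, t))
    return NeighborGraph(n, np.array(edges, dtype=np.intp), "delaunay")


def build_knn(cells, k: int) -> NeighborGraph:
    """Symmetrized k-nearest-neighbor graph (union of directed relations)."""
    pts = _coords(cells)
    n = len(pts)
    if not (isinstance(k, (int, np.integer)) and k >= 1):
        raise ParameterError(f"k must be a positive integer, got {k!r}")
    if k >= n:
        raise ParameterError(f"k={k} must be smaller than the number of cells ({n})")
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1) if n <= 64 else None
    edges = []
    if d2 is not None:
        # tiny images: explicit (distance, index) lexicographic sort
        for s in range(n):
            order = sorted((d2[s, t], t) for t in range(n) if t != s)
            for _, t in order[:k]:
                edges.append((s, t))
    else:
        tree = cKDTree(pts)
        dist, idx = tree.query(pts, k=k + 1)
        for s in range(n):
            cand = [(dist[s, j], int(idx[s, j])) for j in range(k + 1) if idx[s, j] != s]
            # ties at the k-th distance: re-query a widened shell, then
            # break by (distance, index)
            kth = cand[min(k, len(cand)) - 1][0]
            near = tree.query_ball_point(pts[s], kth * (1 + 1e-12))
            cand = sorted(
                (float(np.hypot(*(pts[t] - pts[s]))), t) for t in near if t != s
            )
            for _, t in cand[:k]:
                edges.append((s, t))
    return NeighborGraph(n, np.array(edges, dtype=np.intp), "knn", param=int(k))


def build_radius(cells, r: float) -> NeighborGraph:
    """Fixed-radius graph: edge iff ``0 < distance <= r`` (closed boundary)."""
    if not r > 0:
        raise ParameterError(f"r must be positive, got {r!r}")
    pts = _coords(cells)
    n = len(pts)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(float(r), output_type="ndarray")  # closed: d <= r
    if len(pairs):
        d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
        pairs = pairs[d > 0]  # co-located cells are not neighbors of themselves
    return NeighborGraph(n, pairs, "radius", param=float(r))


_BUILDERS = {"delaunay": build_delaunay, "knn": build_knn, "radius": build_radius}


def build_graph(cells, method: str, k: int | None = None, r: float | None = None) -> NeighborGraph:
    """Dispatch on ``method`` in {delaunay, knn, radius}."""
    if method == "delaunay":
        return build_delaunay(cells)
    if method == "knn":
        if k is None:
            raise ParameterError("knn graph requires k")
        return build_knn(cells, k)
    if method == "radius":
        if r is None:
            raise ParameterError("radius graph requires r")
        return build_radius(cells, r)
    raise ParameterError(f"unknown graph method {method!r}")


def write_edge_list(graph: NeighborGraph, cell_ids, path) -> None:
    """Two-column delimited edge export (debugging aid)."""
    ids = list(cell_ids)
    with open(path, "w") as fh:
        fh.write("cell_id_a\tcell_id_b\n")
        for s, t in graph.edges:
            fh.write(f"{ids[s]}\t{ids[t]}\n")
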