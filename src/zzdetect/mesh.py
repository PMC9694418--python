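"""Conforming triangulations of the image domain.

An m x n image is identified with the rectangle spanned by its pixel
centers: pixel (i, j) (0-based row/column) sits at coordinate
(x, y) = (j, i), so the domain is [0, n-1] x [0, m-1].  Triangulations are
stored as a node array and a triangle index array.  Every triangle is kept
positively oriented, and by convention its *refinement edge* -- the edge that
newest-vertex bisection splits -- is the edge between its first two vertices.
For the structured grids built here that edge is the cell diagonal (the
longest edge of each right isosceles triangle), which makes the initial mesh
compatible and keeps bisection shape-regular: every descendant of a right
isosceles triangle is again right isosceles, so the minimum angle never drops
below 45 degrees.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict, deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import InputError, MeshError

__all__ = [
    "Triangulation",
    "ShapeQuality",
    "pixel_grid_mesh",
    "coarse_mesh",
    "refine",
    "triangle_areas",
    "triangle_diameters",
    "minimum_angle",
    "audit",
    "write_mesh",
    "read_mesh",
]


@dataclass
class ShapeQuality:
    """Lower bound, in degrees, that refinement must preserve."""

    min_angle: float = 0.0

    def __post_init__(self) -> None:
        if self.min_angle < 0:
            raise InputError("min_angle must be nonnegative")


@dataclass
class Triangulation:
    """Nodes (N, 2) float array of (x, y); triangles (T, 3) int array.

    Triangle rows index into ``nodes``; the refinement edge is
    (row[0], row[1]).
    """

    nodes: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(np.asarray(self.nodes, dtype=np.float64))
        self.triangles = np.ascontiguousarray(np.asarray(self.triangles, dtype=np.int64))
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 2:
            raise MeshError("nodes must be an (N, 2) array")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshError("triangles must be a (T, 3) array")

    @property
    def num_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def num_triangles(self) -> int:
        return self.triangles.shape[0]

    @property
    def h(self) -> float:
        """Maximal element diameter, h = max_T diam(T)."""
        return float(triangle_diameters(self).max())

    def triangle_coords(self) -> np.ndarray:
        """(T, 3, 2) array of vertex coordinates."""
        return self.nodes[self.triangles]


def _signed_areas(nodes: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    p = nodes[triangles]
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    return 0.5 * (e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])


def triangle_areas(mesh: Triangulation) -> np.ndarray:
    """Positive per-triangle areas (shoelace); raises on degenerate elements."""
    areas = _signed_areas(mesh.nodes, mesh.triangles)
    if np.any(areas <= 1e-14):
        raise MeshError("degenerate or negatively oriented triangle")
    return areas


def triangle_diameters(mesh: Triangulation) -> np.ndarray:
    p = mesh.triangle_coords()
    d01 = np.linalg.norm(p[:, 0] - p[:, 1], axis=1)
    d12 = np.linalg.norm(p[:, 1] - p[:, 2], axis=1)
    d20 = np.linalg.norm(p[:, 2] - p[:, 0], axis=1)
    return np.maximum(np.maximum(d01, d12), d20)


def minimum_angle(mesh: Triangulation) -> float:
    """Smallest interior angle in the mesh, in degrees."""
    p = mesh.triangle_coords()
    angles = []
    for k in range(3):
        a = p[:, k]
        b = p[:, (k + 1) % 3]
        c = p[:, (k + 2) % 3]
        u = b - a
        v = c - a
        cosang = np.einsum("ij,ij->i", u, v) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
        )
        angles.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return float(np.min(angles))


def _node_id(i: np.ndarray, j: np.ndarray, m: int) -> np.ndarray:
    # column-major linear index: pixel (row i, col j) -> j*m + i
    return j * m + i


def _structured_mesh(rows: int, cols: int, height: float, width: float) -> Triangulation:
    """Uniform grid of ``rows`` x ``cols`` nodes on [0, width] x [0, height].

    Each cell is split along its (0,0)->(1,1) diagonal; the diagonal is the
    refinement edge of both triangles, so the mesh is NVB-compatible.
    """
    ys = np.linspace(0.0, height, rows)
    xs = np.linspace(0.0, width, cols)
    J, I = np.meshgrid(np.arange(cols), np.arange(rows), indexing="ij")
    nodes = np.column_stack([xs[J.ravel()], ys[I.ravel()]])

    ci, cj = np.meshgrid(np.arange(rows - 1), np.arange(cols - 1), indexing="ij")
    ci = ci.ravel()
    cj = cj.ravel()
    a = _node_id(ci, cj, rows)          # (x0, y0)
    b = _node_id(ci, cj + 1, rows)      # (x0+1, y0)
    c = _node_id(ci + 1, cj + 1, rows)  # (x0+1, y0+1)
    d = _node_id(ci + 1, cj, rows)      # (x0, y0+1)
    lower = np.column_stack([c, a, b])  # refinement edge (c, a) = diagonal
    upper = np.column_stack([a, c, d])  # refinement edge (a, c) = diagonal
    triangles = np.empty((2 * lower.shape[0], 3), dtype=np.int64)
    triangles[0::2] = lower
    triangles[1::2] = upper
    return Triangulation(nodes, triangles)


def pixel_grid_mesh(m: int, n: int) -> Triangulation:
    """Triangulation with one node per pixel of an m x n image.

    Node k carries pixel (i, j) with k = j*m + i (column-major, matching the
    linear pixel indexing used for interpolation); there are 2(m-1)(n-1)
    congruent right isosceles triangles.
    """
    if m < 2 or n < 2:
        raise InputError(f"image must be at least 2x2, got {m}x{n}")
    return _structured_mesh(m, n, float(m - 1), float(n - 1))


def coarse_mesh(m: int, n: int, target_triangles: int) -> Triangulation:
    """Uniform structured triangulation of the image rectangle with the
    largest achievable triangle count <= ``target_triangles``.

    The node grid aspect follows the image aspect; its nodes are generally
    not a subset of the pixel-grid nodes.
    """
    if m < 2 or n < 2:
        raise InputError(f"image must be at least 2x2, got {m}x{n}")
    if target_triangles < 2:
        raise InputError("target_triangles must be >= 2")
    fine_count = 2 * (m - 1) * (n - 1)
    if target_triangles > fine_count:
        warnings.warn(
            "coarse-mesh target exceeds the pixel-grid triangle count; "
            "returning the uniform pixel-resolution grid",
            stacklevel=2,
        )
        return pixel_grid_mesh(m, n)

    max_cells = target_triangles // 2
    aspect = (m - 1) / (n - 1)  # desired cell-row : cell-column ratio
    best = None
    for cells_r in range(1, max_cells + 1):
        cells_c = max_cells // cells_r
        if cells_c < 1:
            break
        count = 2 * cells_r * cells_c
        penalty = abs(math.log(cells_r / cells_c) - math.log(aspect))
        key = (count, -penalty)
        if best is None or key > best[0]:
            best = (key, cells_r, cells_c)
    _, cells_r, cells_c = best
    return _structured_mesh(cells_r + 1, cells_c + 1, float(m - 1), float(n - 1))


def _edge_key(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a < b else (b, a)


def refine(
    mesh: Triangulation,
    marked: Iterable[int] | Sequence[int] | np.ndarray,
    quality: ShapeQuality | None = None,
) -> Triangulation:
    """One pass of newest-vertex bisection of the ``marked`` triangles, with
    recursive conformity closure.

    Every marked triangle is bisected at least once; additional triangles are
    split only as far as needed to avoid hanging nodes.  Refinement edges of
    the children are the two remaining parent edges, which is what keeps the
    similarity classes (and hence the minimum angle) bounded.
    """
    marked = np.unique(np.asarray(list(marked) if not isinstance(marked, np.ndarray) else marked, dtype=np.int64))
    if marked.size == 0:
        return mesh
    if marked.min() < 0 or marked.max() >= mesh.num_triangles:
        raise InputError("marked set contains an out-of-range triangle index")

    tris = mesh.triangles
    ref_edge = [_edge_key(int(t[0]), int(t[1])) for t in tris]

    edge_tris: dict[tuple[int, int], list[int]] = defaultdict(list)
    for idx, (a, b, c) in enumerate(tris):
        a, b, c = int(a), int(b), int(c)
        edge_tris[_edge_key(a, b)].append(idx)
        edge_tris[_edge_key(b, c)].append(idx)
        edge_tris[_edge_key(c, a)].append(idx)

    # Closure: an edge scheduled for splitting forces the refinement edge of
    # every triangle containing it to be scheduled too.
    to_split: set[tuple[int, int]] = set()
    queue: deque[tuple[int, int]] = deque()
    for t in marked:
        e = ref_edge[t]
        if e not in to_split:
            to_split.add(e)
            queue.append(e)
    while queue:
        e = queue.popleft()
        for t in edge_tris[e]:
            re = ref_edge[t]
            if re not in to_split:
                to_split.add(re)
                queue.append(re)

    nodes = mesh.nodes
    mid: dict[tuple[int, int], int] = {}
    new_coords = []
    next_id = mesh.num_nodes
    for e in to_split:
        mid[e] = next_id
        new_coords.append(0.5 * (nodes[e[0]] + nodes[e[1]]))
        next_id += 1
    all_nodes = np.vstack([nodes, np.asarray(new_coords)])

    out: list[tuple[int, int, int]] = []
    for idx in range(mesh.num_triangles):
        a, b, c = (int(v) for v in tris[idx])
        e_ab = _edge_key(a, b)
        M = mid.get(e_ab)
        if M is None:
            out.append((a, b, c))
            continue
        # bisect through the refinement edge; children inherit the two
        # remaining parent edges as their refinement edges
        for (p, q, r) in ((c, a, M), (b, c, M)):
            M2 = mid.get(_edge_key(p, q))
            if M2 is None:
                out.append((p, q, r))
            else:
                out.append((r, p, M2))
                out.append((q, r, M2))

    refined = Triangulation(all_nodes, np.asarray(out, dtype=np.int64))
    if quality is not None and quality.min_angle > 0:
        got = minimum_angle(refined)
        if got < quality.min_angle - 1e-9:
            raise MeshError(
                f"refinement violated the shape bound: min angle {got:.3f} deg "
                f"< required {quality.min_angle:.3f} deg"
            )
    return refined


def audit(mesh: Triangulation) -> dict:
    """Check conformity and orientation; raise MeshError on violation.

    Conformity is verified with an edge hash: every edge must belong to
    exactly one (boundary) or exactly two (interior) triangles, and two
    triangles sharing two vertices must share the full edge by construction
    of the hash.  Returns summary counts for use in tests.
    """
    areas = _signed_areas(mesh.nodes, mesh.triangles)
    if np.any(areas <= 0):
        raise MeshError("non-positive triangle orientation")
    edge_count: dict[tuple[int, int], int] = defaultdict(int)
    for (a, b, c) in mesh.triangles:
        a, b, c = int(a), int(b), int(c)
        if len({a, b, c}) != 3:
            raise MeshError("triangle with repeated vertex")
        edge_count[_edge_key(a, b)] += 1
        edge_count[_edge_key(b, c)] += 1
        edge_count[_edge_key(c, a)] += 1
    boundary = interior = 0
    for e, cnt in edge_count.items():
        if cnt == 1:
            boundary += 1
        elif cnt == 2:
            interior += 1
        else:
            raise MeshError(f"edge {e} shared by {cnt} triangles (hanging node)")
    # no node may sit strictly inside another triangle's edge: covered by the
    # edge hash plus exact area bookkeeping done by callers
    return {
        "triangles": mesh.num_triangles,
        "boundary_edges": boundary,
        "interior_edges": interior,
        "total_area": float(areas.sum()),
        "min_angle_deg": minimum_angle(mesh),
    }


def write_mesh(mesh: Triangulation, path) -> None:
    """Export in a small OFF-like text format (counts, nodes, index triples)."""
    with open(path, "w", encoding="ascii") as fh:
        fh.write(f"{mesh.num_nodes} {mesh.num_triangles}\n")
        for x, y in mesh.nodes:
            fh.write(f"{float(x)!r} {float(y)!r}\n")
        for a, b, c in mesh.triangles:
            fh.write(f"{a} {b} {c}\n")


def read_mesh(path) -> Triangulation:
    with open(path, "r", encoding="ascii") as fh:
        header = fh.readline().split()
        nn, nt = int(header[0]), int(header[1])
        nodes = np.array([[float(v) for v in fh.readline().split()] for _ in range(nn)])
        tris = np.array([[int(v) for v in fh.readline().split()] for _ in range(nt)])
    return Triangulation(nodes, tris)
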