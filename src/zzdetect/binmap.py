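"""Binary map construction: minimal-area triangle selection + rasterization.

After adaptation the smallest triangles sit where the indicator kept firing.
Selecting every triangle whose area is within a relative tolerance of the
minimum and painting the pixels it covers yields the raw anomaly map that
post-processing then cleans up.

Bisection halves areas exactly, so triangle areas live on a discrete ladder
A0 / 2^k.  A tolerance below 1 selects only the deepest generation; the
pipeline default (see ``pipeline``) admits the four deepest -- all of
roughly pixel scale or below once the ladder has bottomed out -- which
makes the map robust to triangles that lag a bisection or two behind their
neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import InputError
from .estimator import TriangleField
from .mesh import Triangulation

__all__ = ["BinaryMask", "minimal_area_triangles", "rasterize"]

_EPS = 1e-9  # inclusive-edge tolerance for point-in-triangle, pixel units
_COVER_PAD = 0.5  # half a pixel: dilation radius approximating square overlap
_BATCH_BBOX = 9  # triangles with bounding boxes up to this many pixels per side are batched


@dataclass
class BinaryMask:
    """m x n array with entries in {0, 1}."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise InputError("mask must be 2-D")
        if not np.isin(self.values, (0, 1)).all():
            raise InputError("mask entries must be 0 or 1")
        self.values = self.values.astype(np.uint8)

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def white_fraction(self) -> float:
        return float(self.values.sum()) / self.values.size

    def to_png_array(self) -> np.ndarray:
        return (self.values * 255).astype(np.uint8)


def minimal_area_triangles(areas: TriangleField | np.ndarray, rel_tol: float = 0.25) -> np.ndarray:
    """Indices of triangles with area <= (1 + rel_tol) * min area."""
    values = areas.values if isinstance(areas, TriangleField) else np.asarray(areas, dtype=np.float64)
    if values.size == 0:
        return np.empty(0, dtype=np.int64)
    if np.any(values <= 0):
        raise InputError("areas must be positive")
    if rel_tol < 0:
        raise InputError("rel_tol must be nonnegative")
    return np.flatnonzero(values <= (1.0 + rel_tol) * values.min())


def _points_in_triangles(coords: np.ndarray, px: np.ndarray, py: np.ndarray, pad: float) -> np.ndarray:
    """Vectorized inclusive point-in-triangle test, one point per triangle.

    ``pad`` > 0 accepts points whose signed distance to every edge line is
    >= -pad, i.e. points inside the triangle dilated by ~pad.
    """
    ax, ay = coords[:, 0, 0], coords[:, 0, 1]
    bx, by = coords[:, 1, 0], coords[:, 1, 1]
    cx, cy = coords[:, 2, 0], coords[:, 2, 1]
    area2 = (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)
    sign = np.where(area2 < 0, -1.0, 1.0)
    tol = _EPS * np.maximum(1.0, np.abs(area2))
    s0 = sign * ((bx - ax) * (py - ay) - (by - ay) * (px - ax))
    s1 = sign * ((cx - bx) * (py - by) - (cy - by) * (px - bx))
    s2 = sign * ((ax - cx) * (py - cy) - (ay - cy) * (px - cx))
    if pad > 0:
        l0 = np.hypot(bx - ax, by - ay)
        l1 = np.hypot(cx - bx, cy - by)
        l2 = np.hypot(ax - cx, ay - cy)
        return (s0 >= -tol - pad * l0) & (s1 >= -tol - pad * l1) & (s2 >= -tol - pad * l2)
    return (s0 >= -tol) & (s1 >= -tol) & (s2 >= -tol)


def _paint_one(mask: np.ndarray, tri: np.ndarray, m: int, n: int, pad: float) -> None:
    """Paint one (large) triangle via a dense bounding-box scan."""
    j0 = max(0, int(np.ceil(tri[:, 0].min() - pad - _EPS)))
    j1 = min(n - 1, int(np.floor(tri[:, 0].max() + pad + _EPS)))
    i0 = max(0, int(np.ceil(tri[:, 1].min() - pad - _EPS)))
    i1 = min(m - 1, int(np.floor(tri[:, 1].max() + pad + _EPS)))
    if j1 < j0 or i1 < i0:
        return
    jj, ii = np.meshgrid(np.arange(j0, j1 + 1), np.arange(i0, i1 + 1))
    jj = jj.ravel()
    ii = ii.ravel()
    reps = np.broadcast_to(tri, (jj.size, 3, 2))
    inside = _points_in_triangles(reps, jj.astype(float), ii.astype(float), pad)
    mask[ii[inside], jj[inside]] = 1


def rasterize(
    mesh: Triangulation,
    selected: Iterable[int] | np.ndarray,
    m: int,
    n: int,
    mode: str = "center",
) -> BinaryMask:
    """Paint the pixels covered by the selected triangles.

    mode="center": pixel (i, j) is white iff its node coordinate (x, y) =
    (j, i) lies inside or on the boundary of a selected triangle (inclusive
    edges, signed-area epsilon).  Enlarging the selected set can only add
    white pixels, and selecting every triangle paints the whole image.

    mode="cover": a pixel is white when its center lies inside a selected
    triangle dilated by half a pixel (signed edge distance >= -0.5).  This
    approximates pixel-square/triangle overlap; with sub-pixel triangles it
    closes the single-pixel gaps that center sampling leaves over a
    bisection ladder.
    """
    if mode not in ("center", "cover"):
        raise InputError("mode must be 'center' or 'cover'")
    selected = np.asarray(
        list(selected) if not isinstance(selected, np.ndarray) else selected, dtype=np.int64
    )
    mask = np.zeros((m, n), dtype=np.uint8)
    if selected.size == 0:
        return BinaryMask(mask)
    if selected.min() < 0 or selected.max() >= mesh.num_triangles:
        raise InputError("selected set contains an out-of-range triangle index")
    pad = _COVER_PAD if mode == "cover" else 0.0
    coords = mesh.nodes[mesh.triangles[selected]]

    j0 = np.clip(np.ceil(coords[:, :, 0].min(axis=1) - pad - _EPS).astype(np.int64), 0, n - 1)
    j1 = np.clip(np.floor(coords[:, :, 0].max(axis=1) + pad + _EPS).astype(np.int64), 0, n - 1)
    i0 = np.clip(np.ceil(coords[:, :, 1].min(axis=1) - pad - _EPS).astype(np.int64), 0, m - 1)
    i1 = np.clip(np.floor(coords[:, :, 1].max(axis=1) + pad + _EPS).astype(np.int64), 0, m - 1)
    w = j1 - j0 + 1
    h = i1 - i0 + 1
    nonempty = (
        (coords[:, :, 0].max(axis=1) >= -pad - _EPS)
        & (coords[:, :, 0].min(axis=1) <= n - 1 + pad + _EPS)
        & (coords[:, :, 1].max(axis=1) >= -pad - _EPS)
        & (coords[:, :, 1].min(axis=1) <= m - 1 + pad + _EPS)
    )

    batch = nonempty & (w <= _BATCH_BBOX) & (h <= _BATCH_BBOX)
    if batch.any():
        bc = coords[batch]
        bj0 = j0[batch]
        bi0 = i0[batch]
        bw = w[batch]
        bh = h[batch]
        for dy in range(int(bh.max())):
            row_ok = dy < bh
            for dx in range(int(bw.max())):
                ok = row_ok & (dx < bw)
                if not ok.any():
                    continue
                px = (bj0[ok] + dx).astype(float)
                py = (bi0[ok] + dy).astype(float)
                inside = _points_in_triangles(bc[ok], px, py, pad)
                mask[py[inside].astype(np.int64), px[inside].astype(np.int64)] = 1
    for tri in coords[nonempty & ~batch]:
        _paint_one(mask, tri, m, n, pad)
    return BinaryMask(mask)
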