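"""Independent brute-force reference implementations used as test oracles.

Everything here deliberately avoids the code paths of the package: plane
coefficients come from solving 3x3 linear systems, the indicator integral
uses a degree-5 seven-point quadrature instead of the midpoint rule, erosion
is a stacked all-neighbors-white sliding test, and rasterization tests every
pixel against every triangle with full barycentric coordinates.
"""

from __future__ import annotations

import numpy as np

# degree-5 exact 7-point triangle quadrature (barycentric points, weights)
_A1 = 0.0597158717897698
_B1 = 0.4701420641051151
_A2 = 0.7974269853530873
_B2 = 0.1012865073234563
QUAD_POINTS = np.array(
    [
        [1 / 3, 1 / 3, 1 / 3],
        [_A1, _B1, _B1],
        [_B1, _A1, _B1],
        [_B1, _B1, _A1],
        [_A2, _B2, _B2],
        [_B2, _A2, _B2],
        [_B2, _B2, _A2],
    ]
)
QUAD_WEIGHTS = np.array(
    [
        0.225,
        0.1323941527885062,
        0.1323941527885062,
        0.1323941527885062,
        0.1259391805448271,
        0.1259391805448271,
        0.1259391805448271,
    ]
)


def plane_gradient(p: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Gradient of the plane through three (x, y, value) samples."""
    A = np.column_stack([p, np.ones(3)])
    coef = np.linalg.solve(A, v)
    return coef[:2]


def triangle_area(p: np.ndarray) -> float:
    return 0.5 * abs(
        (p[1, 0] - p[0, 0]) * (p[2, 1] - p[0, 1]) - (p[1, 1] - p[0, 1]) * (p[2, 0] - p[0, 0])
    )


def z2_brute_force(nodes: np.ndarray, triangles: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Per-triangle Zienkiewicz-Zhu indicators by explicit assembly.

    Element gradients from plane fits, nodal recovery by a python loop over
    incident triangles with area weights, and the L2 norm of the linearly
    interpolated deviation integrated with the degree-5 rule.
    """
    nt = triangles.shape[0]
    nn = nodes.shape[0]
    grads = np.zeros((nt, 2))
    areas = np.zeros(nt)
    for t in range(nt):
        p = nodes[triangles[t]]
        grads[t] = plane_gradient(p, values[triangles[t]])
        areas[t] = triangle_area(p)

    recovered = np.zeros((nn, 2))
    for k in range(nn):
        inc = [t for t in range(nt) if k in triangles[t]]
        w = np.array([areas[t] for t in inc])
        w = w / w.sum()
        recovered[k] = sum(wi * grads[t] for wi, t in zip(w, inc))

    eta = np.zeros(nt)
    for t in range(nt):
        gv = recovered[triangles[t]]  # (3, 2) vertex values of G
        total = 0.0
        for pt, wq in zip(QUAD_POINTS, QUAD_WEIGHTS):
            G = pt @ gv  # linear interpolation at the quadrature point
            d = G - grads[t]
            total += wq * (d @ d)
        eta[t] = np.sqrt(areas[t] * total)
    return eta


def erode_brute_force(mask: np.ndarray, iterations: int) -> np.ndarray:
    """All-neighbors-white sliding 3x3 test, border = background."""
    out = mask.astype(bool)
    m, n = out.shape
    for _ in range(iterations):
        padded = np.zeros((m + 2, n + 2), dtype=bool)
        padded[1:-1, 1:-1] = out
        nxt = np.ones((m, n), dtype=bool)
        for di in range(3):
            for dj in range(3):
                nxt &= padded[di : di + m, dj : dj + n]
        out = nxt
    return out.astype(np.uint8)


def rasterize_brute_force(
    nodes: np.ndarray, triangles: np.ndarray, selected, m: int, n: int, eps: float = 1e-9
) -> np.ndarray:
    """Per-pixel scan: white iff the pixel center is inside (inclusively)
    any selected triangle, via full barycentric coordinates."""
    mask = np.zeros((m, n), dtype=np.uint8)
    sel = list(selected)
    for i in range(m):
        for j in range(n):
            px, py = float(j), float(i)
            for t in sel:
                (ax, ay), (bx, by), (cx, cy) = nodes[triangles[t]]
                den = (by - cy) * (ax - cx) + (cx - bx) * (ay - cy)
                if abs(den) < 1e-300:
                    continue
                l1 = ((by - cy) * (px - cx) + (cx - bx) * (py - cy)) / den
                l2 = ((cy - ay) * (px - cx) + (ax - cx) * (py - cy)) / den
                l3 = 1.0 - l1 - l2
                tol = eps * max(1.0, abs(den))
                if l1 >= -tol and l2 >= -tol and l3 >= -tol:
                    mask[i, j] = 1
                    break
    return mask
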