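import numpy as np
import pytest

from zzdetect.mesh import Triangulation


def _orient(nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = nodes[tris]
    signed = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 1, 1] - p[:, 0, 1]
    ) * (p[:, 2, 0] - p[:, 0, 0])
    flip = signed < 0
    tris = tris.copy()
    tris[flip, 1], tris[flip, 2] = tris[flip, 2], tris[flip, 1].copy()
    return tris


@pytest.fixture
def random_mesh():
    """Factory for well-shaped random Delaunay meshes (jittered grid)."""
    from scipy.spatial import Delaunay

    def make(rng: np.random.Generator, side: int = 4, jitter: float = 0.25) -> Triangulation:
        xs, ys = np.meshgrid(np.arange(side, dtype=float), np.arange(side, dtype=float))
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        pts += rng.uniform(-jitter, jitter, pts.shape)
        tris = _orient(pts, Delaunay(pts).simplices.astype(np.int64))
        return Triangulation(pts, tris)

    return make
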