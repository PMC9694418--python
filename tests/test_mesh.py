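import numpy as np
import pytest

from zzdetect.errors import InputError, MeshError
from zzdetect.mesh import (
    ShapeQuality,
    Triangulation,
    audit,
    coarse_mesh,
    minimum_angle,
    pixel_grid_mesh,
    read_mesh,
    refine,
    triangle_areas,
    triangle_diameters,
    write_mesh,
)


class TestPixelGridMesh:
    def test_minimal_two_by_two(self):
        m = pixel_grid_mesh(2, 2)
        assert m.num_nodes == 4
        assert m.num_triangles == 2

    def test_counts_three_by_four(self):
        m = pixel_grid_mesh(3, 4)
        assert m.num_nodes == 12
        assert m.num_triangles == 2 * 2 * 3

    def test_uniform_diameters_and_area_sum(self):
        m = pixel_grid_mesh(5, 8)
        d = triangle_diameters(m)
        assert np.allclose(d, d[0])
        # pixel-center domain: total area (m-1)(n-1)
        assert np.isclose(triangle_areas(m).sum(), 4 * 7)
        audit(m)

    def test_rejects_degenerate_sizes(self):
        with pytest.raises(InputError):
            pixel_grid_mesh(1, 5)


class TestCoarseMesh:
    def test_target_eight_gives_three_by_three_grid(self):
        m = coarse_mesh(100, 100, 8)
        assert m.num_nodes == 9
        assert m.num_triangles == 8

    def test_minimal_target(self):
        m = coarse_mesh(50, 50, 2)
        assert m.num_triangles == 2

    def test_reference_downsampling_count(self):
        # 283x295 slice downsampled to a ~1200-triangle start mesh
        m = coarse_mesh(283, 295, 1200)
        assert m.num_triangles <= 1200
        assert m.num_triangles >= 0.9 * 1200
        assert np.isclose(triangle_areas(m).sum(), 282 * 294)
        audit(m)

    def test_excessive_target_warns_and_returns_pixel_grid(self):
        with pytest.warns(UserWarning):
            m = coarse_mesh(4, 4, 10_000)
        assert m.num_triangles == 2 * 3 * 3


class TestTriangleAreas:
    def test_known_triangles(self):
        t = Triangulation(np.array([[0.0, 0], [1, 0], [0, 1], [2, 0], [0, 2]]), np.array([[0, 1, 2], [0, 3, 4]]))
        assert np.allclose(triangle_areas(t), [0.5, 2.0])

    def test_degenerate_triangle_rejected(self):
        t = Triangulation(np.array([[0.0, 0], [1, 0], [2, 0]]), np.array([[0, 1, 2]]))
        with pytest.raises(MeshError):
            triangle_areas(t)


class TestRefine:
    def test_empty_marked_set_is_identity(self):
        m = pixel_grid_mesh(3, 3)
        assert refine(m, []) is m

    def test_single_marked_triangle_stays_conforming(self):
        m = pixel_grid_mesh(2, 2)
        r = refine(m, [0])
        assert r.num_triangles >= 3
        audit(r)
        assert np.isclose(triangle_areas(r).sum(), 1.0)

    def test_marking_all_strictly_shrinks_every_area(self):
        m = pixel_grid_mesh(3, 4)
        r = refine(m, range(m.num_triangles))
        assert triangle_areas(r).max() < triangle_areas(m).min() + 1e-12
        audit(r)

    def test_quality_bound_enforced(self):
        m = pixel_grid_mesh(3, 3)
        r = refine(m, [0, 1], quality=ShapeQuality(min_angle=44.0))
        assert minimum_angle(r) >= 44.0

    def test_ten_rounds_random_marking_preserves_all_invariants(self):
        # conformity, orientation, area conservation and the bisection
        # minimum-angle bound over repeated refinement
        rng = np.random.default_rng(7)
        mesh = pixel_grid_mesh(5, 5)
        total = triangle_areas(mesh).sum()
        angle0 = minimum_angle(mesh)
        for _ in range(10):
            k = max(1, mesh.num_triangles // 5)
            marked = rng.choice(mesh.num_triangles, size=k, replace=False)
            mesh = refine(mesh, marked)
            audit(mesh)
            assert np.isclose(triangle_areas(mesh).sum(), total)
        assert minimum_angle(mesh) >= angle0 / 2 - 1e-9
        # right isosceles start: bisection actually preserves 45 degrees
        assert minimum_angle(mesh) >= 45.0 - 1e-9

    def test_repeated_refinement_of_one_region_keeps_isotropy(self):
        mesh = pixel_grid_mesh(4, 4)
        angle0 = minimum_angle(mesh)
        for _ in range(10):
            # always refine the triangles nearest the domain corner
            coords = mesh.triangle_coords().mean(axis=1)
            d = np.hypot(coords[:, 0], coords[:, 1])
            marked = np.argsort(d)[: max(1, mesh.num_triangles // 10)]
            mesh = refine(mesh, marked)
        audit(mesh)
        assert minimum_angle(mesh) >= angle0 / 2 - 1e-9

    def test_out_of_range_marked_rejected(self):
        m = pixel_grid_mesh(2, 2)
        with pytest.raises(InputError):
            refine(m, [5])


class TestMeshIO:
    def test_text_round_trip(self, tmp_path):
        m = refine(pixel_grid_mesh(3, 3), [0, 2])
        path = tmp_path / "mesh.txt"
        write_mesh(m, path)
        back = read_mesh(path)
        assert np.array_equal(back.triangles, m.triangles)
        assert np.allclose(back.nodes, m.nodes)
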