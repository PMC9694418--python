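import numpy as np
import pytest

from oracles import z2_brute_force
from zzdetect.errors import ConfigError, InputError
from zzdetect.estimator import (
    MarkingConfig,
    NodalField,
    TriangleField,
    adapt,
    evaluate_pixel_interpolant,
    gradient,
    interpolate_image,
    mark,
    pixel_index,
    recover_gradient,
    resample,
    z2_indicator,
)
from zzdetect.mesh import Triangulation, coarse_mesh, pixel_grid_mesh, triangle_areas
from zzdetect.preprocess import GrayImage


class TestPixelIndex:
    @pytest.mark.parametrize("i,j,m,expected", [(1, 1, 283, 1), (2, 3, 5, 12), (5, 1, 5, 5)])
    def test_column_major_mapping(self, i, j, m, expected):
        assert pixel_index(i, j, m) == expected

    def test_bijection_on_seven_by_nine(self):
        m, n = 7, 9
        seen = set()
        for j in range(1, n + 1):
            for i in range(1, m + 1):
                k = pixel_index(i, j, m)
                # invert: i = ((k-1) mod m)+1, j = (k-1)//m + 1
                assert ((k - 1) % m + 1, (k - 1) // m + 1) == (i, j)
                seen.add(k)
        assert seen == set(range(1, m * n + 1))

    def test_out_of_range(self):
        with pytest.raises(InputError):
            pixel_index(0, 1, 5)
        with pytest.raises(InputError):
            pixel_index(6, 1, 5)


class TestInterpolation:
    def test_nodal_values_reproduce_pixels(self):
        rng = np.random.default_rng(1)
        img = GrayImage(rng.uniform(0, 1, (4, 6)))
        f = interpolate_image(img)
        for i in range(4):
            for j in range(6):
                assert f.values[j * 4 + i] == img.values[i, j]

    def test_evaluation_at_nodes_and_cell_centers(self):
        rng = np.random.default_rng(2)
        img = GrayImage(rng.uniform(0, 1, (5, 5)))
        nodes = pixel_grid_mesh(5, 5).nodes
        assert np.allclose(evaluate_pixel_interpolant(img, nodes), img.values.ravel(order="F"))
        # a cell center lies on the split diagonal: value is the mean of the
        # two diagonal vertex values (barycentric evaluation)
        pt = np.array([[1.5, 2.5]])
        expected = 0.5 * (img.values[2, 1] + img.values[3, 2])
        assert np.allclose(evaluate_pixel_interpolant(img, pt), expected)

    def test_constant_image_constant_field(self):
        img = GrayImage(np.full((4, 4), 0.25))
        pts = np.random.default_rng(0).uniform(0, 3, (20, 2))
        assert np.allclose(evaluate_pixel_interpolant(img, pts), 0.25)


class TestResample:
    def test_identity_on_same_mesh(self):
        mesh = pixel_grid_mesh(4, 5)
        f = NodalField(mesh, np.random.default_rng(3).uniform(0, 1, mesh.num_nodes))
        out = resample(f, mesh)
        assert np.allclose(out.values, f.values)

    def test_linear_field_reproduced_exactly(self):
        fine = pixel_grid_mesh(8, 8)
        f = NodalField(fine, fine.nodes[:, 0] + 2 * fine.nodes[:, 1])
        coarse = coarse_mesh(8, 8, 8)
        out = resample(f, coarse)
        assert np.allclose(out.values, coarse.nodes[:, 0] + 2 * coarse.nodes[:, 1])

    def test_constant_field_and_range_bound(self):
        fine = pixel_grid_mesh(6, 6)
        rng = np.random.default_rng(4)
        f = NodalField(fine, rng.uniform(0.2, 0.8, fine.num_nodes))
        coarse = coarse_mesh(6, 6, 18)
        out = resample(f, coarse)
        assert out.values.min() >= f.values.min() - 1e-12
        assert out.values.max() <= f.values.max() + 1e-12
        const = resample(NodalField(fine, np.full(fine.num_nodes, 0.7)), coarse)
        assert np.allclose(const.values, 0.7)


class TestGradient:
    def test_unit_slope_triangle(self):
        t = Triangulation(np.array([[0.0, 0], [1, 0], [0, 1]]), np.array([[0, 1, 2]]))
        g = gradient(NodalField(t, np.array([0.0, 1.0, 0.0])))
        assert np.allclose(g.values, [[1.0, 0.0]])

    def test_linear_reproduction_on_random_mesh(self, random_mesh):
        mesh = random_mesh(np.random.default_rng(5))
        f = NodalField(mesh, 3.0 * mesh.nodes[:, 0] - 1.5 * mesh.nodes[:, 1] + 0.25)
        g = gradient(f)
        assert np.allclose(g.values, [3.0, -1.5])

    def test_matches_directional_finite_differences(self, random_mesh):
        # differentiate the interpolant directly inside each triangle
        rng = np.random.default_rng(6)
        mesh = random_mesh(rng)
        f = NodalField(mesh, rng.uniform(0, 1, mesh.num_nodes))
        g = gradient(f)
        p = mesh.triangle_coords()
        v = f.values[mesh.triangles]
        bary = p.mean(axis=1)
        h = 1e-6
        for t in range(mesh.num_triangles):
            A = np.column_stack([p[t], np.ones(3)])
            coef = np.linalg.solve(A, v[t])  # plane z = ax + by + c

            def interp(q):
                return coef[0] * q[0] + coef[1] * q[1] + coef[2]

            fd_x = (interp(bary[t] + [h, 0]) - interp(bary[t] - [h, 0])) / (2 * h)
            fd_y = (interp(bary[t] + [0, h]) - interp(bary[t] - [0, h])) / (2 * h)
            assert np.allclose(g.values[t], [fd_x, fd_y], atol=1e-6)


class TestRecovery:
    def test_identical_gradients_pass_through(self, random_mesh):
        mesh = random_mesh(np.random.default_rng(7))
        tf = TriangleField(mesh, np.tile([2.5, -1.0], (mesh.num_triangles, 1)))
        G = recover_gradient(tf)
        assert np.allclose(G.vectors, [2.5, -1.0])

    def test_two_triangle_square_hand_weights(self):
        # unit square split along (0,0)-(1,1); both areas 0.5, so the two
        # diagonal nodes average the gradients and the off-diagonal nodes
        # keep their single triangle's gradient
        t = Triangulation(
            np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]]), np.array([[2, 0, 1], [0, 2, 3]])
        )
        tf = TriangleField(t, np.array([[1.0, 0.0], [0.0, 1.0]]))
        G = recover_gradient(tf)
        assert np.allclose(G.vectors[0], [0.5, 0.5])
        assert np.allclose(G.vectors[2], [0.5, 0.5])
        assert np.allclose(G.vectors[1], [1.0, 0.0])
        assert np.allclose(G.vectors[3], [0.0, 1.0])

    def test_weights_sum_to_one_and_hull_membership(self, random_mesh):
        rng = np.random.default_rng(8)
        for _ in range(5):
            mesh = random_mesh(rng)
            # weights summing to one <=> constant gradients reproduced to
            # machine precision
            const = TriangleField(mesh, np.tile([1.0, 1.0], (mesh.num_triangles, 1)))
            assert np.allclose(recover_gradient(const).vectors, 1.0, atol=1e-12)
            tf = TriangleField(mesh, rng.normal(size=(mesh.num_triangles, 2)))
            G = recover_gradient(tf)
            for k in range(mesh.num_nodes):
                inc = np.any(mesh.triangles == k, axis=1)
                gs = tf.values[inc]
                lo = gs.min(axis=0) - 1e-10
                hi = gs.max(axis=0) + 1e-10
                assert (G.vectors[k] >= lo).all() and (G.vectors[k] <= hi).all()


class TestZ2Indicator:
    def test_zero_for_linear_and_constant_fields(self, random_mesh):
        rng = np.random.default_rng(9)
        for _ in range(5):
            mesh = random_mesh(rng)
            lin = NodalField(mesh, mesh.nodes[:, 0] + 2 * mesh.nodes[:, 1])
            assert np.allclose(z2_indicator(lin).values, 0.0, atol=1e-12)
            const = NodalField(mesh, np.full(mesh.num_nodes, 0.3))
            assert np.allclose(z2_indicator(const).values, 0.0, atol=1e-14)

    def test_nonzero_on_nonlinear_catalog(self, random_mesh):
        # the converse direction: genuinely curved fields must trigger eta
        rng = np.random.default_rng(10)
        mesh = random_mesh(rng)
        x, y = mesh.nodes[:, 0], mesh.nodes[:, 1]
        for values in (x**2, x * y, np.sin(x), np.abs(x - 1.5)):
            eta = z2_indicator(NodalField(mesh, values))
            assert eta.values.max() > 1e-6

    def test_homogeneity_in_the_field(self, random_mesh):
        rng = np.random.default_rng(11)
        mesh = random_mesh(rng)
        f = rng.uniform(0, 1, mesh.num_nodes)
        eta1 = z2_indicator(NodalField(mesh, f)).values
        eta2 = z2_indicator(NodalField(mesh, -3.5 * f)).values
        assert np.allclose(eta2, 3.5 * eta1, rtol=1e-12)

    def test_spike_support_is_one_ring_of_its_star(self):
        mesh = pixel_grid_mesh(7, 7)
        spike = 3 * 7 + 3  # interior node
        values = np.zeros(mesh.num_nodes)
        values[spike] = 1.0
        eta = z2_indicator(NodalField(mesh, values)).values
        star = np.any(mesh.triangles == spike, axis=1)
        star_nodes = np.unique(mesh.triangles[star])
        ring = np.any(np.isin(mesh.triangles, star_nodes), axis=1)
        assert (eta[star] > 0).all()
        assert np.allclose(eta[~ring], 0.0, atol=1e-14)

    def test_matches_brute_force_oracle_on_random_meshes(self, random_mesh):
        rng = np.random.default_rng(12)
        for _ in range(20):
            mesh = random_mesh(rng)
            assert mesh.num_triangles <= 50
            f = rng.uniform(0, 1, mesh.num_nodes)
            eta = z2_indicator(NodalField(mesh, f)).values
            ref = z2_brute_force(mesh.nodes, mesh.triangles, f)
            scale = max(ref.max(), 1e-30)
            assert np.allclose(eta, ref, rtol=1e-10, atol=1e-10 * scale)


class TestMark:
    def test_literal_ascending_example(self):
        eta = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        cfg = MarkingConfig(p=0.25, cref=0.6, anchor="smallest")
        # t = 2, threshold 0.6 * 2 = 1.2 -> seven triangles at or above it
        marked = mark(eta, cfg)
        assert set(marked) == set(range(1, 8))

    def test_top_quantile_anchor(self):
        eta = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        cfg = MarkingConfig(p=0.25, cref=0.6, anchor="largest")
        # t = 2, pivot = second largest = 7, threshold 4.2
        marked = mark(eta, cfg)
        assert set(marked) == {4, 5, 6, 7}

    def test_full_quantile_marks_relative_to_max(self):
        rng = np.random.default_rng(13)
        eta = rng.uniform(0, 1, 40)
        cfg = MarkingConfig(p=1.0, cref=0.6, anchor="smallest")
        marked = mark(eta, cfg)
        assert set(marked) == set(np.flatnonzero(eta >= 0.6 * eta.max()))

    def test_degenerate_uniform_and_empty(self):
        assert len(mark(np.zeros(6), MarkingConfig())) == 6
        assert len(mark(np.full(5, 2.0), MarkingConfig())) == 5
        assert len(mark(np.empty(0), MarkingConfig())) == 0

    def test_invalid_parameters(self):
        with pytest.raises(ConfigError):
            MarkingConfig(p=0.0)
        with pytest.raises(ConfigError):
            MarkingConfig(cref=1.0)
        with pytest.raises(ConfigError):
            MarkingConfig(max_iter=0)


def _blob_image(m=64, n=64, center=(32, 32), radius=9):
    rows = np.arange(m)[:, None]
    cols = np.arange(n)[None, :]
    img = np.full((m, n), 0.05)
    img[(rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2] = 0.95
    return GrayImage(img)


class TestAdapt:
    def test_constant_image_exits_without_refining(self):
        img = GrayImage(np.full((20, 20), 0.4))
        res = adapt(img, nt=50)
        assert res.history == []
        assert res.mesh.num_triangles == coarse_mesh(20, 20, 50).num_triangles

    def test_single_iteration_cap(self):
        img = _blob_image()
        res = adapt(img, nt=100, cfg=MarkingConfig(max_iter=1))
        assert len(res.history) == 1

    def test_triangle_count_nondecreasing(self):
        img = _blob_image()
        res = adapt(img, nt=100, cfg=MarkingConfig(max_iter=4))
        counts = [h["triangles"] for h in res.history] + [res.mesh.num_triangles]
        assert (np.diff(counts) >= 0).all()

    def test_refinement_concentrates_on_the_blob(self):
        img = _blob_image()
        res = adapt(img, nt=100, cfg=MarkingConfig(max_iter=5))
        areas = res.areas.values
        bary = res.mesh.triangle_coords().mean(axis=1)
        # dilated bounding box of the blob (center 32, radius 9, +6 slack)
        inside = (np.abs(bary[:, 0] - 32) <= 15) & (np.abs(bary[:, 1] - 32) <= 15)
        quartile = areas <= np.quantile(areas, 0.25)
        assert quartile.sum() > 0
        assert inside[quartile].mean() >= 0.6
        assert areas[inside].mean() < areas[~inside].mean()
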