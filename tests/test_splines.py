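import numpy as np
import pytest
from scipy.interpolate import CubicSpline

from necrovol.geometry import ApplicatorAxis, VoxelGrid
from necrovol.splines import (
    ClosedContour,
    closed_spline,
    contour_voxels,
    cylindrical_order,
    deboor_periodic,
    spline_reconstruct,
    winding_inside,
    winding_number,
)


def naive_uniform_bspline_basis(j, p, x, n):
    """Textbook Cox–de Boor recursion on the uniform periodic knot grid."""
    if p == 0:
        return np.where((x >= j) & (x < j + 1), 1.0, 0.0)
    left = (x - j) / p * naive_uniform_bspline_basis(j, p - 1, x, n)
    right = (j + p + 1 - x) / p * naive_uniform_bspline_basis(j + 1, p - 1, x, n)
    return left + right


def naive_periodic_eval(control, x, p=3):
    """Σ_j c_j B_j(x) with cyclic controls — the basis-summation oracle."""
    n = len(control)
    x = np.asarray(x, dtype=float) % n
    out = np.zeros(x.shape + control.shape[1:])
    for j in range(-p, n):
        b = naive_uniform_bspline_basis(j, p, x, n)
        out += b[..., None] * control[j % n]
    return out


def random_star_polygon(rng, n=20):
    ang = np.sort(rng.uniform(0, 2 * np.pi, n))
    rad = rng.uniform(1.0, 5.0, n)
    return np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])


def ray_cast_inside(p, poly):
    """Independent even–odd ray-casting point-in-polygon oracle."""
    x, y = p
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xi = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xi:
                inside = not inside
    return inside


class TestContourVoxels:
    def test_max_radius_rule(self, axis):
        # one half-plane with a necrotic run: only the outermost point kept
        r = np.arange(11.0)
        pts = np.column_stack([axis.x + r, np.full(11, axis.y)])
        out = contour_voxels(pts, axis, 22.5)
        assert out.shape == (1, 2)
        assert np.allclose(out[0], [axis.x + 10.0, axis.y])

    def test_one_point_per_half_plane(self, axis):
        angs = np.arange(16) * 22.5
        pts = []
        for a in angs:
            for r in (3.0, 6.0):
                th = np.deg2rad(a)
                pts.append([axis.x + r * np.cos(th), axis.y + r * np.sin(th)])
        out = contour_voxels(np.array(pts), axis, 22.5)
        assert len(out) == 16

    def test_circle_mask_contour_radius(self, axis):
        rng = np.random.default_rng(0)
        angs = np.arange(16) * 22.5
        pts = []
        for a in angs:
            th = np.deg2rad(a)
            for r in np.arange(0.5, 10.0, 1.0):
                pts.append([axis.x + r * np.cos(th), axis.y + r * np.sin(th)])
        out = contour_voxels(np.array(pts), axis, 22.5)
        rr = np.hypot(out[:, 0] - axis.x, out[:, 1] - axis.y)
        assert np.allclose(rr, 9.5)

    def test_empty_input(self, axis):
        assert contour_voxels(np.empty((0, 2)), axis, 22.5).size == 0


class TestCylindricalOrder:
    def test_sorts_by_angle(self):
        axis = ApplicatorAxis((0.0, 0.0))
        pts = np.array(
            [
                [np.cos(np.deg2rad(200)), np.sin(np.deg2rad(200))],
                [np.cos(np.deg2rad(10)), np.sin(np.deg2rad(10))],
                [np.cos(np.deg2rad(90)), np.sin(np.deg2rad(90))],
            ]
        )
        out = cylindrical_order(pts, axis)
        assert np.allclose(out[0], pts[1]) and np.allclose(out[2], pts[0])

    def test_idempotent_on_sorted_input(self):
        axis = ApplicatorAxis((0.0, 0.0))
        ang = np.deg2rad([10, 40, 200, 300])
        pts = np.column_stack([np.cos(ang), np.sin(ang)])
        once = cylindrical_order(pts, axis)
        assert np.array_equal(once, cylindrical_order(once, axis))

    def test_tie_break_by_radius(self):
        axis = ApplicatorAxis((0.0, 0.0))
        pts = np.array([[8.0, 0.0], [5.0, 0.0], [0.0, 3.0]])
        out = cylindrical_order(pts, axis)
        # equal angle 0°: inner radius first
        assert np.allclose(out[0], [5.0, 0.0]) and np.allclose(out[1], [8.0, 0.0])

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            cylindrical_order(np.array([[1.0, 0], [0, 1]]), ApplicatorAxis())


class TestClosedSpline:
    def test_square_corners_interpolated_and_closed(self):
        verts = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
        c = closed_spline(verts)
        at = c.evaluate(np.arange(4) / 4.0)
        assert np.abs(at - verts).max() < 1e-9
        seam = np.linalg.norm(c.evaluate(0.0) - c.evaluate(1.0 - 1e-12))
        assert seam < 1e-9

    def test_circle_16_points_radial_deviation(self):
        ang = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        verts = np.column_stack([np.cos(ang), np.sin(ang)])
        c = closed_spline(verts)
        poly = c.polygon(0.01)
        dev = np.abs(np.linalg.norm(poly, axis=1) - 1.0).max()
        assert dev < 0.02  # < 2% of the radius

    def test_deboor_matches_naive_basis_summation(self, rng):
        control = rng.normal(size=(9, 2))
        x = rng.uniform(0, 9, 100)
        got = deboor_periodic(control, x)
        want = naive_periodic_eval(control, x)
        assert np.abs(got - want).max() < 1e-9

    def test_matches_scipy_periodic_cubic_interpolant(self, rng):
        # the C² periodic cubic interpolant is unique: an independent
        # construction must produce the same curve
        n = 12
        verts = rng.normal(size=(n, 2)) + 10 * np.column_stack(
            [np.cos(np.arange(n) * 2 * np.pi / n), np.sin(np.arange(n) * 2 * np.pi / n)]
        )
        c = closed_spline(verts)
        t = np.arange(n + 1, dtype=float)
        ref = CubicSpline(
            t, np.vstack([verts, verts[:1]]), bc_type="periodic", axis=0
        )
        s = rng.uniform(0, 1, 50)
        assert np.abs(c.evaluate(s) - ref(s * n)).max() < 1e-8

    def test_coincident_vertices_merged(self):
        verts = np.array([[0.0, 0], [0, 0], [1, 0], [1, 1], [0, 1], [0, 0]])
        c = closed_spline(verts)
        assert len(c.vertices) == 4


class TestWindingNumber:
    def test_square_center_inside(self):
        sq = np.array([[0.0, 0], [2, 0], [2, 2], [0, 2]])
        assert winding_inside((1.0, 1.0), sq)

    def test_far_point_outside(self):
        sq = np.array([[0.0, 0], [2, 0], [2, 2], [0, 2]])
        assert not winding_inside((10.0, 10.0), sq)

    def test_on_edge_counts_inside(self):
        sq = np.array([[0.0, 0], [2, 0], [2, 2], [0, 2]])
        assert winding_inside((1.0, 0.0), sq)

    def test_agrees_with_ray_casting_oracle(self, rng):
        hits = 0
        for _ in range(10):
            poly = random_star_polygon(rng)
            pts = rng.uniform(-6, 6, size=(20, 2))
            for p in pts:
                # skip near-boundary points: the oracles may differ there
                d = np.abs(winding_number(p[None], poly))
                mine = winding_inside(p, poly, include_boundary=False)
                assert mine == ray_cast_inside(p, poly)
                hits += 1
        assert hits == 200


class TestSplineReconstruct:
    def test_ellipsoid_levels_match_analytic_sections(self, small_spec):
        from necrovol.phantom import generate_ground_truth, reslice_ground_truth
        from necrovol.pipeline import points_by_level

        gt = generate_ground_truth(small_spec, small_spec.duration_s)
        series = reslice_ground_truth(gt, small_spec.axis, 8)
        grid = small_spec.make_grid(np.uint8)
        pbl = points_by_level(list(series), grid, small_spec.axis)
        out = spline_reconstruct(pbl, grid, small_spec.axis, 22.5)
        for zi in (26, 32, 38):
            got = out.values[:, :, zi].astype(bool)
            ref = gt.values[:, :, zi].astype(bool)
            d = 2 * (got & ref).sum() / (got.sum() + ref.sum())
            assert d > 0.9

    def test_start_vertex_invariance(self, axis):
        ang = np.arange(16) * 22.5
        th = np.deg2rad(ang)
        verts = np.column_stack(
            [axis.x + 10 * np.cos(th), axis.y + 8 * np.sin(th)]
        )
        grid = VoxelGrid(np.zeros((64, 64, 1), np.uint8))
        a = spline_reconstruct({0: verts}, grid, axis, 22.5)
        b = spline_reconstruct({0: np.roll(verts, 5, axis=0)}, grid, axis, 22.5)
        assert np.array_equal(a.values, b.values)

    def test_reflection_equivariance(self, axis):
        rng = np.random.default_rng(1)
        ang = np.arange(16) * 22.5
        th = np.deg2rad(ang)
        rad = 6 + 3 * rng.random(16)
        verts = np.column_stack(
            [axis.x + rad * np.cos(th), axis.y + rad * np.sin(th)]
        )
        mirrored = verts.copy()
        mirrored[:, 1] = 2 * axis.y - mirrored[:, 1]
        grid = VoxelGrid(np.zeros((64, 64, 1), np.uint8))
        a = spline_reconstruct({0: verts}, grid, axis, 22.5)
        b = spline_reconstruct({0: mirrored}, grid, axis, 22.5)
        # mirroring the inputs mirrors the mask about the axis row y = 32:
        # pixel y-index j maps to 64 − j (j = 0 has no partner on this grid)
        assert np.array_equal(
            a.values[:, 1:, 0], b.values[:, 1:, 0][:, ::-1]
        )

    def test_convex_fill_within_dilated_hull(self, axis):
        from scipy import ndimage
        from necrovol.delaunay import delaunay_3d, hull_and_fill

        ang = np.arange(16) * 22.5
        th = np.deg2rad(ang)
        verts = np.column_stack(
            [axis.x + 11 * np.cos(th), axis.y + 7 * np.sin(th)]
        )
        grid = VoxelGrid(np.zeros((64, 64, 1), np.uint8))
        spl = spline_reconstruct({0: verts}, grid, axis, 22.5).values[:, :, 0]
        # convex-hull fill of the same vertices, dilated by one voxel
        from necrovol.mvee import mvee_fit
        import matplotlib

        matplotlib.use("Agg")
        from matplotlib.path import Path

        hull_pts = verts[np.argsort(np.arctan2(verts[:, 1] - axis.y, verts[:, 0] - axis.x))]
        path = Path(hull_pts)
        xs, ys = np.meshgrid(np.arange(64.0), np.arange(64.0), indexing="ij")
        hull = path.contains_points(
            np.column_stack([xs.ravel(), ys.ravel()]), radius=1e-9
        ).reshape(64, 64)
        dilated = ndimage.binary_dilation(hull, iterations=1)
        assert np.all(spl.astype(bool) <= dilated)

    def test_outlier_vertex_impact_is_local(self, axis):
        ang = np.arange(16) * 22.5
        th = np.deg2rad(ang)
        verts = np.column_stack(
            [axis.x + 10 * np.cos(th), axis.y + 10 * np.sin(th)]
        )
        inflated = verts.copy()
        inflated[0] = [axis.x + 20.0, axis.y]  # one corrupted half-plane
        grid = VoxelGrid(np.zeros((64, 64, 1), np.uint8))
        a = spline_reconstruct({0: verts}, grid, axis, 22.5).values[:, :, 0]
        b = spline_reconstruct({0: inflated}, grid, axis, 22.5).values[:, :, 0]
        diff = np.argwhere(a.astype(bool) ^ b.astype(bool))
        # all changed pixels sit in the angular sector around the bad vertex
        theta = np.degrees(
            np.arctan2(diff[:, 1] - axis.y, diff[:, 0] - axis.x)
        )
        assert np.all(np.abs(((theta + 180) % 360) - 180) <= 60.0)
        # the opposite side of the contour is untouched
        assert np.array_equal(a[:20, :], b[:20, :])
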