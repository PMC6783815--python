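import math

import numpy as np
import pytest

from oracles import brute_hull, monte_carlo_volume

from morphoct.exceptions import DegenerateGeometryError
from morphoct.hull_descriptors import (
    ConvexHull3D,
    SurfaceMesh,
    convex_hull,
    convexity,
    hull_area,
    hull_volume,
    measure,
    mesh_area,
    mesh_surface,
    mesh_volume,
    solidity,
    write_ply,
)
from morphoct.phantoms import PhantomSpec, make_body, make_twisted_slab
from morphoct.volume_io import BinaryVolume


def unit_cube_mesh(offset=(0.0, 0.0, 0.0)):
    """Hand-built unit cube: 8 vertices, 12 outward triangles."""
    v = np.array([[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)],
                 dtype=float) + np.asarray(offset, dtype=float)
    f = np.array([
        [0, 1, 3], [0, 3, 2],        # x = 0, outward -x
        [4, 6, 7], [4, 7, 5],        # x = 1
        [0, 4, 5], [0, 5, 1],        # y = 0
        [2, 3, 7], [2, 7, 6],        # y = 1
        [0, 2, 6], [0, 6, 4],        # z = 0
        [1, 5, 7], [1, 7, 3],        # z = 1
    ])
    return SurfaceMesh(vertices=v, faces=f)


class TestMeshSurface:
    def test_single_voxel_octahedron(self):
        # the 0.5 iso-surface of one voxel is the octahedron spanned by the
        # face-neighbour midpoints: volume 4/3 * (1/2)^3 = 1/6
        b = BinaryVolume(np.pad(np.ones((1, 1, 1), dtype=bool), 1))
        m = mesh_surface(b)
        assert mesh_volume(m) == pytest.approx(1.0 / 6.0, rel=1e-6)

    def test_cube10(self):
        b = BinaryVolume(np.pad(np.ones((10, 10, 10), dtype=bool), 1))
        m = mesh_surface(b)
        assert mesh_volume(m) == pytest.approx(1000, rel=0.05)
        assert mesh_area(m) == pytest.approx(600, rel=0.10)

    def test_sphere_r20(self):
        body, truth = make_body(PhantomSpec("sphere", radius=20))
        m = mesh_surface(body, smoothing_sigma=1.0)
        assert mesh_volume(m) == pytest.approx(truth["V"], rel=0.02)
        assert mesh_area(m) == pytest.approx(truth["A"], rel=0.03)

    def test_empty_mask_fails(self):
        with pytest.raises(DegenerateGeometryError, match="empty"):
            mesh_surface(BinaryVolume(np.zeros((3, 3, 3), dtype=bool)))

    def test_boundary_touching_mask_is_padded(self):
        b = BinaryVolume(np.ones((4, 4, 4), dtype=bool))
        m = mesh_surface(b)  # must not fail; closed mesh
        assert mesh_volume(m) > 0

    def test_spacing_scales_geometry(self):
        grid = np.pad(np.ones((6, 6, 6), dtype=bool), 1)
        v1 = mesh_volume(mesh_surface(BinaryVolume(grid, spacing=1.0)))
        v2 = mesh_volume(mesh_surface(BinaryVolume(grid, spacing=2.0)))
        assert v2 == pytest.approx(8 * v1, rel=1e-9)

    def test_oversmoothing_falls_back_to_raw(self, caplog):
        b = BinaryVolume(np.pad(np.ones((1, 1, 1), dtype=bool), 2))
        with caplog.at_level("WARNING", logger="morphoct.hull_descriptors"):
            m = mesh_surface(b, smoothing_sigma=2.0)
        assert mesh_volume(m) == pytest.approx(1.0 / 6.0, rel=1e-6)
        assert any("falling back" in r.message for r in caplog.records)


class TestMeshMetrics:
    def test_unit_cube_exact(self):
        m = unit_cube_mesh()
        assert mesh_volume(m) == pytest.approx(1.0, abs=1e-12)
        assert mesh_area(m) == pytest.approx(6.0, abs=1e-12)

    def test_translation_invariance(self):
        far = unit_cube_mesh(offset=(100, 100, 100))
        assert mesh_volume(far) == pytest.approx(1.0, abs=1e-9)
        assert mesh_area(far) == pytest.approx(6.0, abs=1e-9)

    def test_open_mesh_rejected(self):
        m = unit_cube_mesh()
        broken = SurfaceMesh(vertices=m.vertices, faces=m.faces[:-1])
        with pytest.raises(DegenerateGeometryError, match="not closed"):
            mesh_volume(broken)

    def test_volume_matches_monte_carlo(self, rng):
        pts = rng.random((30, 3)) * 10
        hull = convex_hull(pts)
        v_impl = hull_volume(hull)
        _, normals, offsets = brute_hull(pts)
        est, se = monte_carlo_volume(normals, offsets, pts.min(0), pts.max(0),
                                     1_000_000, np.random.default_rng(99))
        assert abs(v_impl - est) <= 3 * se


class TestConvexHull:
    def test_cube_corners_with_interior_point(self):
        pts = np.array([[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)]
                       + [[0.5, 0.5, 0.5]], dtype=float)
        hull = convex_hull(pts)
        assert len(hull.vertices) == 8
        assert hull_volume(hull) == pytest.approx(1.0, abs=1e-12)
        assert hull_area(hull) == pytest.approx(6.0, abs=1e-12)

    def test_unit_tetrahedron(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        assert hull_volume(convex_hull(pts)) == pytest.approx(1 / 6, abs=1e-12)

    def test_octahedron(self):
        pts = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                        [0, 0, 1], [0, 0, -1]], dtype=float)
        hull = convex_hull(pts)
        assert hull_volume(hull) == pytest.approx(4 / 3, abs=1e-12)
        assert hull_area(hull) == pytest.approx(4 * math.sqrt(3), abs=1e-12)

    def test_too_few_points(self):
        with pytest.raises(DegenerateGeometryError):
            convex_hull(np.zeros((3, 3)))

    def test_coplanar_points_fail(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [2, 3, 0]],
                       dtype=float)
        with pytest.raises(DegenerateGeometryError, match="degenerate"):
            convex_hull(pts)

    def test_matches_brute_force_oracle_200_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(4, 51))
            pts = rng.random((n, 3))
            hull = convex_hull(pts)
            oracle_idx, _, _ = brute_hull(pts)
            ours = {tuple(np.round(v, 9)) for v in hull.vertices}
            theirs = {tuple(np.round(pts[i], 9)) for i in oracle_idx}
            assert ours == theirs

    def test_idempotence(self, rng):
        pts = rng.random((40, 3))
        h1 = convex_hull(pts)
        h2 = convex_hull(h1.vertices)
        assert hull_volume(h2) == pytest.approx(hull_volume(h1), rel=1e-12)
        assert len(h2.vertices) == len(h1.vertices)

    def test_containment_invariant(self, rng):
        pts = rng.normal(size=(60, 3))
        hull = convex_hull(pts)
        assert hull.contains(pts).all()

    def test_hull_area_below_bounding_box(self, rng):
        pts = rng.random((25, 3))
        hull = convex_hull(pts)
        lo, hi = pts.min(0), pts.max(0)
        d = hi - lo
        box_area = 2 * (d[0] * d[1] + d[1] * d[2] + d[0] * d[2])
        assert hull_area(hull) <= box_area + 1e-12


class TestDescriptorFormulas:
    def test_convexity_direct(self):
        assert convexity(6, 6) == 1.0
        assert convexity(8, 10) == pytest.approx(0.8)

    def test_convexity_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            convexity(0, 1)

    def test_solidity_direct(self):
        assert solidity(1, 1) == 1.0

    def test_solidity_rejects_v_above_vc(self):
        with pytest.raises(ValueError, match="exceeds hull volume"):
            solidity(2.0, 1.0)

    def test_solidity_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            solidity(-1, 1)


class TestMeasure:
    def test_l_prism_solidity(self):
        body, truth = make_body(PhantomSpec("l_prism", cell=40))
        d = measure(body)
        assert truth["S"] == pytest.approx(6 / 7, abs=1e-12)
        assert d.S == pytest.approx(6 / 7, rel=0.02)

    def test_plus_prism_convexity(self):
        body, truth = make_body(PhantomSpec("plus_prism", cell=40))
        d = measure(body)
        assert truth["C"] == pytest.approx((18 + 4 * math.sqrt(2)) / 22, abs=1e-12)
        assert truth["C"] == pytest.approx(1.0753, abs=5e-5)
        assert d.C == pytest.approx(truth["C"], rel=0.02)

    def test_shell_solidity(self):
        # hemispherical shell, outer r, thickness 0.1 r: S = 1 - 0.9^3
        body, truth = make_body(PhantomSpec("shell", radius=30, thickness=3))
        assert truth["S"] == pytest.approx(1 - 0.9**3, abs=1e-12)
        d = measure(body)
        assert d.S == pytest.approx(truth["S"], rel=0.05)

    def test_sphere_near_convex_limit(self):
        body, _ = make_body(PhantomSpec("sphere", radius=20))
        d = measure(body)
        assert 0.97 <= d.C <= 1.03
        assert 0.95 <= d.S <= 1.0

    def test_flat_slab(self, flat_slab_spec):
        body, truth = make_body(flat_slab_spec)
        d = measure(body)
        assert d.S == pytest.approx(1.0, rel=0.05)
        assert 0.9 < d.C < 1.1

    def test_twisted_below_flat(self, flat_slab_spec, twisted_slab_spec):
        flat = measure(make_body(flat_slab_spec)[0])
        twisted = measure(make_body(twisted_slab_spec)[0])
        assert twisted.C < flat.C
        assert twisted.S < flat.S

    def test_convex_limit_improves_with_radius(self):
        # proper convergence study: hold the smoothing length fixed
        # relative to the object (sigma = r/20) while the voxel shrinks
        errs = []
        for r in (10, 20, 40):
            d = measure(make_body(PhantomSpec("sphere", radius=r))[0],
                        smoothing_sigma=r / 20)
            errs.append((abs(d.C - 1), abs(d.S - 1)))
        assert errs[0][0] > errs[1][0] > errs[2][0]
        assert errs[0][1] > errs[1][1] > errs[2][1]

    def test_twist_sweep_strictly_decreasing(self):
        cs, ss = [], []
        for twist in (0, 90, 180, 270):
            d = measure(make_twisted_slab(60, 30, 5, twist=twist))
            cs.append(d.C)
            ss.append(d.S)
        assert all(a > b for a, b in zip(cs, cs[1:]))
        assert all(a > b for a, b in zip(ss, ss[1:]))

    def test_solidity_bound_on_phantoms(self):
        specs = [
            PhantomSpec("sphere", radius=12),
            PhantomSpec("cuboid", length=20, width=12, thickness=6),
            PhantomSpec("l_prism", cell=15),
            PhantomSpec("plus_prism", cell=12),
            PhantomSpec("shell", radius=18, thickness=3),
            PhantomSpec("twisted_slab", length=50, width=24, thickness=5, twist=270),
        ]
        for spec in specs:
            d = measure(make_body(spec)[0])
            assert d.S <= 1 + 1e-9

    def test_scale_invariance(self):
        grid_spec = PhantomSpec("twisted_slab", length=40, width=20, thickness=5,
                                twist=90)
        body, _ = make_body(grid_spec)
        d1 = measure(body)
        d2 = measure(BinaryVolume(body.data, spacing=2.0))
        assert d2.C == pytest.approx(d1.C, abs=1e-9)
        assert d2.S == pytest.approx(d1.S, abs=1e-9)
        assert d2.V == pytest.approx(8 * d1.V, rel=1e-9)
        assert d2.Vc == pytest.approx(8 * d1.Vc, rel=1e-9)
        assert d2.A == pytest.approx(4 * d1.A, rel=1e-9)
        assert d2.Ac == pytest.approx(4 * d1.Ac, rel=1e-9)


class TestPlyExport:
    def test_writes_valid_header_and_counts(self, tmp_path):
        m = unit_cube_mesh()
        path = tmp_path / "cube.ply"
        write_ply(m, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "ply"
        assert "element vertex 8" in lines
        assert "element face 12" in lines
        assert len(lines) == lines.index("end_header") + 1 + 8 + 12
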