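import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st

from tkrfem.geometry import (
    AlignmentPerturbation,
    GeometryError,
    TriSurface,
    apply_alignment,
    load_surface,
    points_inside,
    reflection_residual,
    save_surface,
    tetrahedralize,
    validate_surface,
)
from tkrfem.synthetic import SyntheticGeomParams, make_synthetic_tkr


class TestLoadValidate:
    def test_cube_stl_roundtrip(self, unit_cube, tmp_path):
        path = tmp_path / "cube.stl"
        save_surface(unit_cube, path)
        s = load_surface(path)
        assert s.n_vertices == 8  # STL stores per-face vertices; dedup recovers 8
        assert s.n_faces == 12
        assert s.is_watertight
        assert s.volume() == pytest.approx(1.0, abs=1e-9)

    def test_ascii_stl(self, unit_cube, tmp_path):
        path = tmp_path / "cube_ascii.stl"
        unit_cube.to_trimesh().export(path, file_type="stl_ascii")
        s = load_surface(path)
        assert (s.n_vertices, s.n_faces) == (8, 12)

    def test_unreadable_file(self, tmp_path):
        path = tmp_path / "junk.stl"
        path.write_text("not a mesh")
        with pytest.raises(GeometryError):
            load_surface(path)

    def test_degenerate_face_reported_and_removed(self, unit_cube, tmp_path):
        v = np.vstack([unit_cube.vertices, unit_cube.vertices[:1] + [5, 5, 5]])
        f = np.vstack([unit_cube.faces, [8, 8, 8]])
        bad = TriSurface(v, f)
        rep = validate_surface(bad)
        assert rep.n_degenerate_faces == 1
        path = tmp_path / "bad.stl"
        save_surface(bad, path)
        cleaned = load_surface(path, drop_degenerate=True)
        assert cleaned.validation.n_degenerate_faces == 0

    def test_closed_icosphere_watertight(self, icosphere):
        rep = validate_surface(icosphere)
        assert rep.boundary_edges == 0
        assert rep.watertight

    def test_deleted_face_opens_three_boundary_edges(self, icosphere):
        holed = TriSurface(icosphere.vertices, icosphere.faces[1:])
        rep = validate_surface(holed)
        assert rep.boundary_edges == 3
        assert not rep.watertight

    def test_coincident_vertices_counted(self, unit_cube):
        v = np.vstack([unit_cube.vertices, unit_cube.vertices[:1]])
        rep = validate_surface(TriSurface(v, unit_cube.faces))
        assert rep.duplicate_vertices == 1


class TestSyntheticAssembly:
    def test_default_assembly_watertight(self, synthetic_parts):
        assert set(synthetic_parts) == {
            "femoral_component", "tibial_insert", "tibial_tray",
            "femur", "tibia", "fibula",
        }
        for surf in synthetic_parts.values():
            assert validate_surface(surf).watertight, surf.name

    def test_condyle_apexes_over_dish_centers(self, default_params, synthetic_parts):
        fem = synthetic_parts["femoral_component"]
        # the two lowest vertex clusters sit above x = +-d_ml/2, y = 0
        lows = fem.vertices[fem.vertices[:, 2] < fem.vertices[:, 2].min() + 0.1]
        d = default_params.condyle_spacing / 2
        assert sorted(np.round(np.abs(lows[:, 0]), 1)) == pytest.approx([d, d], abs=0.5)
        assert np.allclose(lows[:, 1], 0.0, atol=0.5)
        # apex gap equals the configured initial gap
        dish_bottom = -default_params.dish_depth
        assert fem.vertices[:, 2].min() - dish_bottom == pytest.approx(
            default_params.initial_gap, abs=1e-6
        )

    def test_sagittal_mirror_symmetry(self, synthetic_parts):
        for surf in synthetic_parts.values():
            assert reflection_residual(surf) < 1e-9, surf.name

    def test_merged_condyles_degenerate_limit(self):
        parts = make_synthetic_tkr(SyntheticGeomParams(condyle_spacing=0.0))
        for surf in parts.values():
            assert validate_surface(surf).watertight

    def test_conforming_radius_rejected(self):
        with pytest.raises(GeometryError):
            SyntheticGeomParams(condyle_radius=24.0, dish_radius=24.0)


class TestTetrahedralize:
    def test_cube_volume_conserved(self, unit_cube):
        m = tetrahedralize(unit_cube)
        assert np.all(m.tet_volumes() > 0)
        assert m.volume() == pytest.approx(1.0, abs=1e-6)

    def test_cube_refined(self, unit_cube):
        m = tetrahedralize(unit_cube, max_cell_volume=0.01)
        assert m.n_tets >= 100
        assert m.volume() == pytest.approx(1.0, rel=0.02)

    def test_open_surface_rejected(self, icosphere):
        holed = TriSurface(icosphere.vertices, icosphere.faces[1:])
        with pytest.raises(GeometryError, match="boundary"):
            tetrahedralize(holed)

    def test_volume_conservation_on_random_convex_hulls(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            pts = rng.normal(size=(25, 3)) * rng.uniform(0.5, 3.0)
            hull = trimesh.convex.convex_hull(pts)
            s = TriSurface(np.asarray(hull.vertices), np.asarray(hull.faces))
            m = tetrahedralize(s)
            assert abs(m.volume() - s.volume()) <= 0.02 * s.volume()

    def test_nonconvex_insert_volume(self, coarse_params):
        insert = make_synthetic_tkr(coarse_params)["tibial_insert"]
        m = tetrahedralize(insert)
        assert abs(m.volume() - insert.volume()) <= 0.02 * insert.volume()


class TestPointsInside:
    def test_cube_classification(self, unit_cube):
        pts = np.array([[0, 0, 0], [0.49, 0.49, 0.49], [0.51, 0, 0], [2, 2, 2]])
        assert points_inside(unit_cube, pts).tolist() == [True, True, False, False]


class TestAlignment:
    def test_zero_magnitude_is_identity(self, icosphere):
        p = AlignmentPerturbation("varus", 0.0, pivot=(0, 0, 0))
        out = apply_alignment(icosphere, p)
        assert np.allclose(out.vertices, icosphere.vertices)

    def test_internal_rotation_worked_example(self):
        s = TriSurface(np.array([[10.0, 0.0, 0.0], [0, 0, 0], [0, 0, 1]]), np.array([[0, 1, 2]]))
        p = AlignmentPerturbation("internal_rotation", 5.0, pivot=(0.0, 0.0, 0.0))
        out = apply_alignment(s, p)
        assert out.vertices[0] == pytest.approx([9.96195, 0.87156, 0.0], abs=1e-5)

    def test_roundtrip_through_inverse(self, icosphere):
        p = AlignmentPerturbation("valgus", 3.7, pivot=(1.0, -2.0, 3.0))
        out = apply_alignment(apply_alignment(icosphere, p), p.inverse())
        assert np.allclose(out.vertices, icosphere.vertices, atol=1e-9)

    def test_mode_axis_conventions(self):
        assert AlignmentPerturbation("varus", 1, pivot=(0, 0, 0)).axis.tolist() == [0, -1, 0]
        assert AlignmentPerturbation("valgus", 1, pivot=(0, 0, 0)).axis.tolist() == [0, 1, 0]
        assert AlignmentPerturbation("internal_rotation", 1, pivot=(0, 0, 0)).axis.tolist() == [0, 0, 1]
        assert AlignmentPerturbation("flexion", 1, pivot=(0, 0, 0)).axis.tolist() == [1, 0, 0]

    def test_zero_axis_rejected(self):
        with pytest.raises(GeometryError):
            AlignmentPerturbation("translation", 1.0, axis=(0, 0, 0))

    @settings(max_examples=25, deadline=None)
    @given(
        angle=st.floats(-180, 180),
        axis_seed=st.integers(0, 2**31 - 1),
    )
    def test_rigid_transforms_preserve_edge_lengths(self, angle, axis_seed):
        rng = np.random.default_rng(axis_seed)
        verts = rng.normal(size=(20, 3)) * 10
        faces = rng.integers(0, 20, size=(15, 3))
        s = TriSurface(verts, faces)
        axis = rng.normal(size=3)
        if np.linalg.norm(axis) < 1e-6:
            axis = np.array([1.0, 0, 0])
        p = AlignmentPerturbation(
            "varus", abs(angle), pivot=rng.normal(size=3), axis=axis
        )
        out = apply_alignment(s, p)

        def edge_lengths(surf):
            e = surf.edges()
            return np.linalg.norm(surf.vertices[e[:, 0]] - surf.vertices[e[:, 1]], axis=1)

        np.testing.assert_allclose(
            edge_lengths(out), edge_lengths(s), rtol=1e-9, atol=1e-12
        )
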